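"""Per-nucleotide depth of coverage and three-class coverage QC.

Depth follows the standard pileup conventions for paired-end panel data:
minimum mapping quality 0, minimum base quality 12, anomalous read pairs
(records without the proper-pair flag) discarded, and overlapping bases of
the two mates of one pair counted as depth 1.

Nucleotides are classified as poorly covered (<=10 reads), moderately
covered (11-49), or well covered (>=50).  Per-gene summaries can split
out a problematic terminal exon (the repetitive RPGR ORF15 exon) so its
depth is reported independently of its gene's mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from ._util import ValidationError, percent, round_half_away
from .panel import TargetRegion

WELL_MIN_DEPTH = 50      # >= this: well covered
MODERATE_MIN_DEPTH = 11  # 11..49: moderately covered; <=10: poorly covered


class CoverageError(ValueError):
    """Raised for region/alignment mismatches."""


@dataclass
class DepthProfile:
    """Per-nucleotide read depth over one region for one sample (or mean)."""

    chrom: str
    start: int                 # 0-based position of depths[0]
    depths: np.ndarray         # non-negative ints, one per nucleotide
    sample_id: str = "mean"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.size == 0:
            raise ValidationError("depth profile must cover at least one nt")
        if (self.depths < 0).any():
            raise ValidationError("depths must be non-negative")

    @property
    def end(self) -> int:
        return self.start + self.depths.size

    def same_region(self, other: "DepthProfile") -> bool:
        return (self.chrom == other.chrom and self.start == other.start
                and self.depths.size == other.depths.size)


@dataclass(frozen=True)
class CoverageClassCounts:
    """Counts of nucleotides in the three coverage classes."""

    well: int
    moderate: int
    poor: int

    @property
    def total(self) -> int:
        return self.well + self.moderate + self.poor


def pileup_depth(alignments: Union[str, Path, pysam.AlignmentFile],
                 region: TargetRegion,
                 min_base_quality: int = 12,
                 min_mapq: int = 0) -> DepthProfile:
    """Per-base depth over ``region`` from SAM/BAM alignments.

    A read pair contributes at most 1 to each position (mate overlaps
    collapsed by read name); bases below ``min_base_quality`` do not
    count; reads lacking the proper-pair flag, or that are secondary,
    supplementary, duplicate or QC-fail, are discarded.
    """
    own = not isinstance(alignments, pysam.AlignmentFile)
    af = (pysam.AlignmentFile(str(alignments), "r")
          if own else alignments)
    try:
        if region.chrom not in (af.references or ()):
            raise CoverageError(
                f"region chromosome {region.chrom!r} not present in "
                f"alignment header (contigs: {list(af.references or ())})"
            )
        n = region.end - region.start
        covering: list[set[str]] = [set() for _ in range(n)]
        for read in af:
            if (read.is_unmapped or read.is_secondary
                    or read.is_supplementary or read.is_duplicate
                    or read.is_qcfail):
                continue
            if not read.is_proper_pair:   # anomalous pairs discarded
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.reference_name != region.chrom:
                continue
            if read.reference_end <= region.start or \
                    read.reference_start >= region.end:
                continue
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos < region.start or rpos >= region.end:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                covering[rpos - region.start].add(read.query_name)
        depths = np.fromiter((len(s) for s in covering), dtype=np.int64,
                             count=n)
    finally:
        if own:
            af.close()
    return DepthProfile(chrom=region.chrom, start=region.start,
                        depths=depths, sample_id="sample")


def mean_profile(profiles: Sequence[DepthProfile]) -> DepthProfile:
    """Element-wise mean depth across samples, rounded to whole reads."""
    if not profiles:
        raise ValidationError("need at least one profile")
    head = profiles[0]
    for p in profiles[1:]:
        if not head.same_region(p):
            raise CoverageError("profiles cover different regions")
    stacked = np.stack([p.depths for p in profiles]).astype(float)
    mean = stacked.mean(axis=0)
    rounded = np.array([round_half_away(v) for v in mean], dtype=np.int64)
    return DepthProfile(chrom=head.chrom, start=head.start,
                        depths=rounded, sample_id="mean")


def classify_coverage(profile: DepthProfile) -> CoverageClassCounts:
    """Assign every nucleotide to exactly one coverage class."""
    d = profile.depths
    well = int((d >= WELL_MIN_DEPTH).sum())
    poor = int((d < MODERATE_MIN_DEPTH).sum())
    moderate = int(d.size - well - poor)
    return CoverageClassCounts(well=well, moderate=moderate, poor=poor)


def coverage_fractions(counts: CoverageClassCounts) -> tuple[float, float, float]:
    """(well, moderate, poor) percentages of nt assessed, one decimal."""
    if counts.total == 0:
        raise ValidationError("no nucleotides assessed")
    return (percent(counts.well, counts.total),
            percent(counts.moderate, counts.total),
            percent(counts.poor, counts.total))


def gene_summary(profiles: Mapping[str, DepthProfile],
                 orf15_region: Optional[TargetRegion] = None) -> pd.DataFrame:
    """Mean depth per gene, optionally splitting out the ORF15 exon.

    When ``orf15_region`` is given and lies inside a gene's profile, that
    gene's mean excludes the ORF15 positions and a separate ``ORF15`` row
    reports them, mirroring how the repetitive RPGR terminal exon is
    summarised independently.
    """
    rows = []
    for gene in sorted(profiles):
        prof = profiles[gene]
        mask = np.ones(prof.depths.size, dtype=bool)
        orf15_depths = None
        if orf15_region is not None and orf15_region.chrom == prof.chrom:
            lo = max(orf15_region.start, prof.start) - prof.start
            hi = min(orf15_region.end, prof.end) - prof.start
            if hi > lo:
                mask[lo:hi] = False
                orf15_depths = prof.depths[lo:hi]
        body = prof.depths[mask]
        if body.size:
            rows.append({"gene": gene, "n_positions": int(body.size),
                         "mean_depth": int(round_half_away(body.mean()))})
        if orf15_depths is not None and orf15_depths.size:
            rows.append({"gene": "ORF15",
                         "n_positions": int(orf15_depths.size),
                         "mean_depth":
                             int(round_half_away(orf15_depths.mean()))})
    return pd.DataFrame(rows, columns=["gene", "n_positions", "mean_depth"])


def plot_gene_coverage(profiles: Mapping[str, DepthProfile], path=None):
    """Box plot of per-nucleotide depth by gene (one box per gene).

    The dashed line marks the overall mean depth.  Returns the figure;
    when ``path`` is given the figure is also saved there.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = sorted(profiles)
    data = [profiles[g].depths for g in genes]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(genes)), 4))
    ax.boxplot(data, tick_labels=genes)
    overall = float(np.concatenate(data).mean()) if data else 0.0
    ax.axhline(overall, linestyle="--", color="grey",
               label=f"overall mean {overall:.0f}x")
    ax.set_ylabel("reads per nucleotide")
    ax.tick_params(axis="x", rotation=90)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
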