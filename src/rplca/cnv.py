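"""Coverage-based CNV calling on the probe panel.

Within a sequencing run, each probe's counts are normalized by the
per-probe median across non-NTC samples, so an unaffected diploid sample
sits near 1.0 at every probe.  A deletion is called when six or more
consecutive probes (in panel order, never crossing a chromosome) drop to
a normalized coverage <= 0.65, a duplication when six or more consecutive
probes rise to >= 1.20.  Deletions with a mean normalized coverage <= 0.15
over the run are reported as homozygous-or-hemizygous, otherwise as
heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import ValidationError
from .panel import SmMipRecord
from .reads import CoverageMatrix

DELETION_THRESHOLD = 0.65     # inclusive: <= calls
DUPLICATION_THRESHOLD = 1.20  # inclusive: >= calls
MIN_CONSECUTIVE_PROBES = 6
HOM_DELETION_BOUNDARY = 0.15  # mean norm. coverage at/below: hom or hemi
MIN_SAMPLES_FOR_NORMALIZATION = 8


@dataclass
class NormalizedMatrix:
    """Per-run normalized coverage with the per-probe reference statistic.

    ``values`` has the shape of the count matrix; probes whose median
    count across non-NTC samples is zero carry NaN and are excluded from
    calling (listed in ``excluded_probes``).
    """

    values: pd.DataFrame
    reference_stat: pd.Series        # per-probe median over non-NTC samples
    roles: dict[str, str]
    excluded_probes: list[str]

    def non_ntc_samples(self) -> list[str]:
        return [s for s in self.values.index if self.roles[s] != "NTC"]


@dataclass(frozen=True)
class CnvCall:
    """One detected copy-number event.

    ``first_probe_index`` / ``last_probe_index`` are inclusive panel
    indices on ``chrom``; ``genes`` lists the gene(s) the run of probes
    spans, in panel order.
    """

    sample_id: str
    chrom: str
    genes: tuple[str, ...]
    first_probe_index: int
    last_probe_index: int
    probe_ids: tuple[str, ...]
    type: str                       # "deletion" | "duplication"
    zygosity: Optional[str]         # del: heterozygous | homozygous_or_hemizygous
    mean_normalized_coverage: float

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def normalize(matrix: CoverageMatrix,
              min_samples: int = MIN_SAMPLES_FOR_NORMALIZATION
              ) -> NormalizedMatrix:
    """Divide each count by the probe's median over non-NTC samples.

    The median is robust to the very events being sought: a deletion in
    one sample barely moves the probe's reference statistic.  Runs with
    fewer than ``min_samples`` non-NTC samples are rejected because the
    reference statistic becomes unstable.
    """
    keep = matrix.non_ntc_samples()
    if len(keep) < min_samples:
        raise ValidationError(
            f"only {len(keep)} non-NTC samples; normalization needs at "
            f"least {min_samples} — sequence more samples per run"
        )
    ref = matrix.counts.loc[keep].median(axis=0)
    excluded = list(ref.index[ref == 0])
    safe_ref = ref.replace(0, np.nan)
    values = matrix.counts.divide(safe_ref, axis=1)
    return NormalizedMatrix(values=values, reference_stat=ref,
                            roles=dict(matrix.roles),
                            excluded_probes=excluded)


def _maximal_runs(flags: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Start/end (inclusive) of maximal True runs of length >= min_run."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if start is not None and flags.size - start >= min_run:
        runs.append((start, flags.size - 1))
    return runs


def call_cnvs(norm: NormalizedMatrix,
              panel: Sequence[SmMipRecord],
              del_threshold: float = DELETION_THRESHOLD,
              dup_threshold: float = DUPLICATION_THRESHOLD,
              min_run: int = MIN_CONSECUTIVE_PROBES,
              hom_del_boundary: float = HOM_DELETION_BOUNDARY,
              include_ntc: bool = False) -> list[CnvCall]:
    """Call deletions and duplications from runs of consecutive probes.

    Probes are taken in (chromosome, panel_index) order; a run never
    crosses a chromosome.  Overlapping qualifying windows merge into one
    maximal call.  Probes excluded from normalization (zero median) break
    runs.  Thresholds are inclusive: a probe exactly at 0.65 supports a
    deletion, exactly at 1.20 a duplication.
    """
    by_id = {p.probe_id: p for p in panel}
    missing = [pid for pid in norm.values.columns if pid not in by_id]
    if missing:
        raise ValidationError(f"probes absent from panel: {missing}")
    ordered = sorted((by_id[pid] for pid in norm.values.columns),
                     key=lambda p: (p.chrom, p.panel_index))
    samples = (list(norm.values.index) if include_ntc
               else norm.non_ntc_samples())

    calls: list[CnvCall] = []
    # group probes per chromosome, in panel order
    chrom_groups: dict[str, list[SmMipRecord]] = {}
    for p in ordered:
        chrom_groups.setdefault(p.chrom, []).append(p)

    for sample in samples:
        for chrom, probes in chrom_groups.items():
            pids = [p.probe_id for p in probes]
            vals = norm.values.loc[sample, pids].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            for kind, flags in (
                ("deletion", ok & (vals <= del_threshold)),
                ("duplication", ok & (vals >= dup_threshold)),
            ):
                for start, end in _maximal_runs(flags, min_run):
                    span = probes[start:end + 1]
                    mean_cov = float(vals[start:end + 1].mean())
                    zygosity = None
                    if kind == "deletion":
                        zygosity = ("homozygous_or_hemizygous"
                                    if mean_cov <= hom_del_boundary
                                    else "heterozygous")
                    genes: list[str] = []
                    for p in span:
                        if not genes or genes[-1] != p.gene:
                            genes.append(p.gene)
                    calls.append(CnvCall(
                        sample_id=sample,
                        chrom=chrom,
                        genes=tuple(genes),
                        first_probe_index=span[0].panel_index,
                        last_probe_index=span[-1].panel_index,
                        probe_ids=tuple(pids[start:end + 1]),
                        type=kind,
                        zygosity=zygosity,
                        mean_normalized_coverage=mean_cov,
                    ))
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.first_probe_index,
                              c.type))
    return calls


def call_span(call: CnvCall, panel: Sequence[SmMipRecord]) -> tuple[str, int, int]:
    """Genomic (chrom, start, end) half-open span covered by a call."""
    by_id = {p.probe_id: p for p in panel}
    probes = [by_id[pid] for pid in call.probe_ids]
    return (call.chrom, min(p.capture_start for p in probes),
            max(p.capture_end for p in probes))


def overlay_deletion_check(calls: Iterable[CnvCall],
                           panel: Sequence[SmMipRecord],
                           sample_id: str,
                           chrom: str,
                           pos: int) -> bool:
    """Whether a heterozygous deletion overlaps a homozygous variant.

    An apparently homozygous SNV can in truth be hemizygous — a
    heterozygous point variant uncovered by a deletion of the other
    allele.  Given a 1-based variant position, returns True when any
    heterozygous deletion call of the same sample spans it.
    """
    pos0 = pos - 1
    for call in calls:
        if call.sample_id != sample_id or call.type != "deletion":
            continue
        if call.zygosity != "heterozygous":
            continue
        c_chrom, start, end = call_span(call, panel)
        if c_chrom == chrom and start <= pos0 < end:
            return True
    return False


def write_calls(calls: Sequence[CnvCall], path: Union[str, Path]) -> None:
    rows = [{
        "sample_id": c.sample_id, "chrom": c.chrom,
        "genes": ",".join(c.genes),
        "first_probe_index": c.first_probe_index,
        "last_probe_index": c.last_probe_index,
        "n_probes": c.n_probes, "type": c.type,
        "zygosity": c.zygosity if c.zygosity else ".",
        "mean_norm_cov": round(c.mean_normalized_coverage, 4),
    } for c in calls]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "genes",
                                "first_probe_index", "last_probe_index",
                                "n_probes", "type", "zygosity",
                                "mean_norm_cov"]).to_csv(
        path, sep="\t", index=False)
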