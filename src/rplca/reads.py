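"""UMI deduplication and the sample x smMIP coverage matrix.

Each smMIP read pair carries two 5-nt unique molecular identifiers (UMIs)
adjacent to the probe arms; reads sharing sample, probe and UMI pair are
PCR duplicates of one captured molecule and are collapsed to a single
pair.  The per-sample, per-probe coverage is the deduplicated forward +
reverse read count divided by two (floored), i.e. the number of unique
read pairs supporting that probe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from ._util import ValidationError, round_half_away
from .panel import SmMipRecord

ROLES = ("proband", "positive_control", "NTC")
_UMI_RE = re.compile(r"^[ACGT]{5}$")


@dataclass(frozen=True)
class TaggedRead:
    """One sequencing read tagged with sample, probe, and UMI pair."""

    read_id: str
    sample_id: str
    probe_id: str
    umi_pair: tuple[str, str]
    mate: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        for umi in self.umi_pair:
            if not _UMI_RE.match(umi):
                raise ValidationError(
                    f"read {self.read_id}: UMI {umi!r} is not 5 nt over ACGT"
                )
        if self.mate not in ("forward", "reverse"):
            raise ValidationError(
                f"read {self.read_id}: mate must be forward/reverse"
            )

    @property
    def molecule_key(self) -> tuple[str, str, tuple[str, str]]:
        return (self.sample_id, self.probe_id, self.umi_pair)


def dedup_reads(reads: Iterable[TaggedRead]) -> list[TaggedRead]:
    """Collapse PCR duplicates to one read pair per molecule.

    The molecule key is (sample, probe, UMI pair); the retained pair is
    the one with the lexicographically smallest read_id, which makes the
    operation deterministic and idempotent.  Both mates of the retained
    pair are kept, in input order.
    """
    reads = list(reads)
    chosen: dict[tuple, str] = {}
    for r in reads:
        key = r.molecule_key
        if key not in chosen or r.read_id < chosen[key]:
            chosen[key] = r.read_id
    return [r for r in reads if chosen[r.molecule_key] == r.read_id]


class CoverageMatrix:
    """Deduplicated read-pair counts per sample x smMIP, with sample roles.

    ``counts`` is a pandas DataFrame indexed by sample_id with probe_id
    columns; ``roles`` maps each sample to proband / positive_control /
    NTC.  The no-template control (NTC) is a contamination control, not a
    specimen: it is carried in the matrix but excluded from run statistics
    and CNV normalization by default.
    """

    def __init__(self, counts: pd.DataFrame, roles: Mapping[str, str]):
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("coverage counts must be non-negative")
        missing = [s for s in counts.index if s not in roles]
        if missing:
            raise ValidationError(f"samples without a role: {missing}")
        bad = {s: r for s, r in roles.items() if r not in ROLES}
        if bad:
            raise ValidationError(f"unknown sample roles: {bad}")
        self.counts = counts
        self.roles = dict(roles)

    # -- basic accessors ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.columns)

    def non_ntc_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] != "NTC"]

    def proband_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == "proband"]

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.counts.copy()
        out.insert(0, "role", [self.roles[s] for s in out.index])
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        roles = df["role"].to_dict()
        return cls(df.drop(columns=["role"]), roles)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, CoverageMatrix)
                and self.counts.equals(other.counts)
                and self.roles == other.roles)


def build_matrix(reads: Sequence[TaggedRead],
                 panel: Sequence[SmMipRecord],
                 roles: Mapping[str, str]) -> CoverageMatrix:
    """Count deduplicated read pairs per sample x probe.

    Forward and reverse reads are combined and divided by two (floored),
    so a cell counts unique pairs.  Every probe_id in the reads must be
    known to the panel.
    """
    known = {p.probe_id for p in panel}
    unknown = sorted({r.probe_id for r in reads} - known)
    if unknown:
        raise ValidationError(f"reads reference unknown probe_ids: {unknown}")
    probe_order = [p.probe_id for p in
                   sorted(panel, key=lambda p: (p.chrom, p.panel_index))]
    sample_order = sorted(roles)
    if reads:
        tab = pd.crosstab(pd.Series([r.sample_id for r in reads], name="s"),
                          pd.Series([r.probe_id for r in reads], name="p"))
        raw = tab.reindex(index=sample_order, columns=probe_order,
                          fill_value=0).astype(np.int64)
    else:
        raw = pd.DataFrame(0, index=sample_order, columns=probe_order,
                           dtype=np.int64)
    counts = raw // 2
    counts.index.name = "sample_id"
    return CoverageMatrix(counts, roles)


# ---------------------------------------------------------------------------
# run-level summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunStats:
    """Run summary: totals and per-sample / per-probe means (rounded)."""

    total_reads: int
    n_samples: int
    n_probes: int
    mean_reads_per_sample: int
    mean_reads_per_smmip: int


def run_stats_from_totals(total_reads: int, n_samples: int,
                          n_probes: int) -> RunStats:
    """Summary arithmetic from run totals.

    Means round half away from zero to whole reads, the precision at
    which such run summaries are reported.
    """
    if n_samples <= 0:
        raise ValidationError("run must contain at least one sample")
    if n_probes <= 0:
        raise ValidationError("panel must contain at least one probe")
    return RunStats(
        total_reads=int(total_reads),
        n_samples=n_samples,
        n_probes=n_probes,
        mean_reads_per_sample=int(round_half_away(total_reads / n_samples)),
        mean_reads_per_smmip=int(
            round_half_away(total_reads / (n_samples * n_probes))),
    )


def run_stats(matrix: CoverageMatrix, include_ntc: bool = False) -> RunStats:
    """Run summary from a coverage matrix (units: deduplicated read pairs).

    NTC wells are excluded from the sample count and the totals unless
    ``include_ntc`` is set.
    """
    samples = matrix.sample_ids if include_ntc else matrix.non_ntc_samples()
    if not samples:
        raise ValidationError("run must contain at least one sample")
    sub = matrix.counts.loc[samples]
    total = int(sub.to_numpy().sum())
    if total == 0:
        return RunStats(0, len(samples), len(matrix.probe_ids), 0, 0)
    return run_stats_from_totals(total, len(samples), len(matrix.probe_ids))
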