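"""Panel data model: smMIP probes, target regions, and transcript arithmetic.

A single-molecule molecular inversion probe (smMIP) captures a fixed-length
genomic region (225 nt in the panel design modelled here) flanked by two
probe arms.  A panel is an ordered set of such probes tiling the exons,
UTRs, published pseudo-exons and selected loci of the disease genes.

Coordinates are 0-based half-open throughout the in-memory model.  The
BED-like target file on disk is likewise 0-based half-open; variant tables
(VCF convention) are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from ._util import ValidationError

#: Captured-region length of a standard probe in this panel design.
CAPTURE_LENGTH = 225

#: Closed set of target-region categories.  ``locus`` covers plain regional
#: targets (e.g. an adRP-associated locus or full-gene intronic tiling) that
#: need no handling beyond membership.
TARGET_CATEGORIES = frozenset(
    {"exon", "UTR", "pseudo_exon", "intron", "locus"}
)


class PanelParseError(ValueError):
    """Raised for malformed panel / target files, naming the line."""


@dataclass(frozen=True)
class SmMipRecord:
    """One smMIP probe: gene, captured interval, and panel rank."""

    probe_id: str
    gene: str
    chrom: str
    capture_start: int
    capture_end: int
    panel_index: int

    def __post_init__(self) -> None:
        if self.capture_end <= self.capture_start:
            raise ValidationError(
                f"probe {self.probe_id}: capture_end must exceed capture_start"
            )

    @property
    def capture_length(self) -> int:
        return self.capture_end - self.capture_start


@dataclass(frozen=True)
class TargetRegion:
    """One targeted interval with its design category."""

    gene: str
    chrom: str
    start: int
    end: int
    category: str = "exon"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"target {self.gene} {self.chrom}:{self.start}-{self.end}: "
                "end must exceed start"
            )
        if self.category not in TARGET_CATEGORIES:
            raise ValidationError(
                f"unknown target category {self.category!r}; "
                f"expected one of {sorted(TARGET_CATEGORIES)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, pos0: int) -> bool:
        """Whether the 0-based position ``pos0`` lies in this region."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal exon-structure model for splice-product arithmetic.

    ``flank_lengths`` are the two vector-exon flanks of a minigene
    construct; a wild-type RT-PCR fragment spans the flanks plus all exons.
    """

    gene: str
    exon_lengths: Sequence[int]
    flank_lengths: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not all(n > 0 for n in self.exon_lengths):
            raise ValidationError("exon lengths must be positive")
        if any(n < 0 for n in self.flank_lengths):
            raise ValidationError("flank lengths must be non-negative")

    @property
    def wildtype_fragment_nt(self) -> int:
        return sum(self.exon_lengths) + sum(self.flank_lengths)

    def skip_product_nt(self, exon_index: int) -> int:
        """Fragment size after skipping the ``exon_index``-th exon (0-based)."""
        return predict_skip_product(
            self.wildtype_fragment_nt, self.exon_lengths[exon_index]
        )


def predict_skip_product(wildtype_fragment_nt: int, skipped_exon_nt: int) -> int:
    """Size of the exon-skipping RT-PCR product.

    Skipping an internal exon removes exactly its length from the
    wild-type fragment, e.g. a 907-nt fragment losing an 82-nt exon
    yields an 825-nt product.
    """
    if skipped_exon_nt < 0:
        raise ValidationError("skipped exon length must be non-negative")
    result = wildtype_fragment_nt - skipped_exon_nt
    if result <= 0:
        raise ValidationError(
            "skipped exon length must be smaller than the wild-type fragment"
        )
    return result


# ---------------------------------------------------------------------------
# target file I/O (BED-like TSV: chrom  start  end  gene  category)
# ---------------------------------------------------------------------------

def load_targets(path: Union[str, Path, io.TextIOBase]) -> list[TargetRegion]:
    """Read target regions from a BED-like TSV.

    Columns: chrom, start, end, gene, category.  Lines starting with ``#``
    are comments.  Records are returned in genomic sort order.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        name = str(path)
        lines = Path(path).read_text().splitlines()
    targets: list[TargetRegion] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise PanelParseError(
                f"{name}:{lineno}: expected 5 tab-separated columns "
                f"(chrom, start, end, gene, category), got {len(fields)}"
            )
        chrom, start_s, end_s, gene, category = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise PanelParseError(
                f"{name}:{lineno}: non-integer coordinate"
            ) from exc
        try:
            targets.append(
                TargetRegion(gene=gene, chrom=chrom, start=start, end=end,
                             category=category)
            )
        except ValidationError as exc:
            raise ValidationError(f"{name}:{lineno}: {exc}") from exc
    targets.sort(key=lambda t: (t.chrom, t.start, t.end, t.gene))
    return targets


def write_targets(targets: Iterable[TargetRegion],
                  path: Union[str, Path]) -> None:
    """Write target regions as BED-like TSV (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene\tcategory\n")
        for t in sorted(targets, key=lambda t: (t.chrom, t.start, t.end, t.gene)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t{t.category}\n")


# ---------------------------------------------------------------------------
# probe table I/O (TSV: probe_id  gene  chrom  start  end  panel_index)
# ---------------------------------------------------------------------------

def load_panel(path: Union[str, Path]) -> list[SmMipRecord]:
    """Read smMIP probe records from TSV, sorted by (chrom, panel_index)."""
    probes: list[SmMipRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PanelParseError(
                f"{path}:{lineno}: expected 6 columns "
                "(probe_id, gene, chrom, start, end, panel_index)"
            )
        probe_id, gene, chrom = fields[0], fields[1], fields[2]
        if probe_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate probe_id {probe_id}")
        seen.add(probe_id)
        try:
            probes.append(
                SmMipRecord(probe_id, gene, chrom,
                            int(fields[3]), int(fields[4]), int(fields[5]))
            )
        except ValueError as exc:
            raise PanelParseError(f"{path}:{lineno}: {exc}") from exc
    probes.sort(key=lambda p: (p.chrom, p.panel_index))
    _check_panel_order(probes)
    return probes


def write_panel(probes: Iterable[SmMipRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#probe_id\tgene\tchrom\tstart\tend\tpanel_index\n")
        for p in sorted(probes, key=lambda p: (p.chrom, p.panel_index)):
            fh.write(f"{p.probe_id}\t{p.gene}\t{p.chrom}\t"
                     f"{p.capture_start}\t{p.capture_end}\t{p.panel_index}\n")


def _check_panel_order(probes: Sequence[SmMipRecord]) -> None:
    """panel_index must be strictly increasing within each chromosome."""
    last: dict[str, int] = {}
    for p in probes:
        if p.chrom in last and p.panel_index <= last[p.chrom]:
            raise ValidationError(
                f"panel_index not strictly increasing on {p.chrom} "
                f"at probe {p.probe_id}"
            )
        last[p.chrom] = p.panel_index


# ---------------------------------------------------------------------------
# footprint
# ---------------------------------------------------------------------------

@dataclass
class FootprintSummary:
    """Union size of the targeted intervals, total and per gene (nt)."""

    total: int
    per_gene: Mapping[str, int] = field(default_factory=dict)


def _union_size(intervals: Iterable[tuple[str, int, int]]) -> int:
    """Total length of the union of (chrom, start, end) half-open intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_start, cur_end = ivs[0]
        for start, end in ivs[1:]:
            if start > cur_end:          # half-open: abutting intervals merge
                total += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        total += cur_end - cur_start
    return total


def panel_footprint(targets: Sequence[TargetRegion]) -> FootprintSummary:
    """Number of distinct nucleotides covered by the targets.

    Overlapping and abutting intervals are merged; the per-gene breakdown
    merges within each gene independently, so shared nucleotides between
    genes count once in ``total`` but once per gene in ``per_gene``.
    """
    total = _union_size((t.chrom, t.start, t.end) for t in targets)
    genes = sorted({t.gene for t in targets})
    per_gene = {
        g: _union_size((t.chrom, t.start, t.end) for t in targets if t.gene == g)
        for g in genes
    }
    return FootprintSummary(total=total, per_gene=per_gene)
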