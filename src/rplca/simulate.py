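"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a probe-capture sequencing run at desk scale:

* coverage matrices — per-probe base efficiency drawn from a Gamma
  distribution (capture efficiency varies strongly between probes),
  multiplied per cell by log-normal noise and by the copy-number factor
  of any planted event (0.5 het deletion, 0.0 hom deletion, 1.5 dup);
* annotated variant tables — planted causal genotypes whose annotations
  place them in tiers 1-3 with configurable ACMG classes, against
  background variants designed to fail exactly one cascade filter each,
  plus recurrent injections carried by >=10% of probands to exercise
  the run-frequency filter;
* SAM-text alignment fixtures whose per-base depth equals a requested
  profile by construction (proper pairs, optional mate overlap and
  sub-threshold base qualities).

Every generator is a pure function of the seed in its config, and every
dataset is returned together with its ground truth so recovery tests
never re-derive expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from ._util import ValidationError
from .panel import CAPTURE_LENGTH, SmMipRecord, TargetRegion
from .reads import CoverageMatrix
from .variants import VariantRecord

#: Synthetic gene table: (gene, chromosome, inheritance mode).  Real
#: disease-gene symbols with their modes, laid out on synthetic
#: coordinates.
GENE_TABLE: tuple[tuple[str, str, str], ...] = (
    ("USH2A", "chr1", "AR"), ("EYS", "chr6", "AR"), ("CRB1", "chr1", "AR"),
    ("ABCA4", "chr1", "AR"), ("RPE65", "chr1", "AR"), ("CEP290", "chr12", "AR"),
    ("RPGRIP1", "chr14", "AR"), ("PDE6A", "chr5", "AR"),
    ("RHO", "chr3", "AD"), ("PRPF31", "chr19", "AD"), ("PRPH2", "chr6", "AD"),
    ("RP1", "chr8", "AD"), ("ROM1", "chr11", "AD"),
    ("RPGR", "chrX", "XL"), ("RP2", "chrX", "XL"),
)

GENE_MODES = {g: mode for g, _, mode in GENE_TABLE}


@dataclass(frozen=True)
class PlantedCnv:
    """A planted copy-number event: probe span and copy factor."""

    sample_index: int
    first_probe: int           # position in panel order (0-based)
    n_probes: int
    factor: float              # 0.5 het del, 0.0 hom del, 1.5 dup

    def __post_init__(self) -> None:
        if self.factor not in (0.5, 0.0, 1.5):
            raise ValidationError(
                f"planted CNV factor must be one of 0.5/0.0/1.5, "
                f"got {self.factor}")
        if self.n_probes < 1:
            raise ValidationError("planted CNV must span >= 1 probe")


@dataclass(frozen=True)
class PlantedVariant:
    """A planted causal genotype for one proband.

    ``genotype`` is homozygous / compound_het / heterozygous /
    hemizygous; ``classes`` holds one ACMG class per allele.
    """

    sample_index: int
    gene: str
    genotype: str
    classes: tuple[int, ...]
    severities: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.genotype not in ("homozygous", "compound_het",
                                 "heterozygous", "hemizygous"):
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        n_alleles = 2 if self.genotype == "compound_het" else 1
        if len(self.classes) != n_alleles:
            raise ValidationError(
                f"{self.genotype} genotype needs {n_alleles} class(es)")


@dataclass
class SimConfig:
    """Study conditions of a simulated sequencing run.

    Defaults mirror a full production run: 380 samples (373 probands,
    6 positive controls, 1 no-template control) against the full
    16,812-probe panel, probe efficiencies averaging 93 read pairs per
    probe, and multiplicative log-normal noise with sigma 0.1.
    """

    seed: int = 0
    n_samples: int = 380
    n_probes: int = 16812
    n_controls: int = 6
    n_ntc: int = 1
    mean_probe_count: float = 93.0
    gamma_shape: float = 4.0
    noise_sigma: float = 0.1
    planted_cnvs: list[PlantedCnv] = field(default_factory=list)
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    background_variant_rate: float = 8.0
    recurrence_injections: int = 0
    recurrence_fraction: float = 0.12

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(1, self.n_samples + 1)]

    def roles(self) -> dict[str, str]:
        ids = self.sample_ids()
        roles = {s: "proband" for s in ids}
        n_special = self.n_controls + self.n_ntc
        if self.n_controls:
            for s in ids[len(ids) - n_special:len(ids) - self.n_ntc]:
                roles[s] = "positive_control"
        if self.n_ntc:
            for s in ids[len(ids) - self.n_ntc:]:
                roles[s] = "NTC"
        return roles


def gen_panel(n_probes: int, probe_spacing: int = CAPTURE_LENGTH
              ) -> list[SmMipRecord]:
    """Synthetic probe panel tiling the gene table.

    Probes are distributed round-robin-in-blocks over the genes, abutting
    225-nt captured regions per gene, panel_index increasing within each
    chromosome.
    """
    per_gene = [n_probes // len(GENE_TABLE)] * len(GENE_TABLE)
    for i in range(n_probes % len(GENE_TABLE)):
        per_gene[i] += 1
    probes: list[SmMipRecord] = []
    next_index: dict[str, int] = {}
    gene_start: dict[str, int] = {}
    offset = 1_000_000
    for (gene, chrom, _), count in zip(GENE_TABLE, per_gene):
        gene_start[gene] = offset
        for k in range(count):
            idx = next_index.get(chrom, 0)
            start = offset + k * probe_spacing
            probes.append(SmMipRecord(
                probe_id=f"MIP_{gene}_{k:05d}", gene=gene, chrom=chrom,
                capture_start=start, capture_end=start + CAPTURE_LENGTH,
                panel_index=idx))
            next_index[chrom] = idx + 1
        offset += count * probe_spacing + 1_000_000
    probes.sort(key=lambda p: (p.chrom, p.panel_index))
    return probes


def chromosome_blocks(panel: Sequence[SmMipRecord]
                      ) -> list[tuple[str, int, int]]:
    """(chrom, offset, n_probes) runs of the panel in panel-sort order.

    Offsets index the panel sorted by (chrom, panel_index) — the same
    order ``gen_coverage`` uses — so planted CNV spans can be placed
    inside a single chromosome.
    """
    ordered = sorted(panel, key=lambda p: (p.chrom, p.panel_index))
    blocks: list[tuple[str, int, int]] = []
    for i, p in enumerate(ordered):
        if blocks and blocks[-1][0] == p.chrom:
            chrom, off, n = blocks[-1]
            blocks[-1] = (chrom, off, n + 1)
        else:
            blocks.append((p.chrom, i, 1))
    return blocks


# ---------------------------------------------------------------------------
# coverage matrices
# ---------------------------------------------------------------------------

def gen_coverage(config: SimConfig,
                 panel: Optional[Sequence[SmMipRecord]] = None
                 ) -> tuple[CoverageMatrix, dict]:
    """Simulated coverage matrix plus ground truth.

    counts[s, p] = round(base_p * factor(s, p) * LogNormal(0, sigma)),
    where base_p ~ Gamma(shape, mean/shape) models uneven probe
    efficiency.  NTC wells receive near-zero counts.  The truth dict
    records the planted events and the panel-order probe list.
    """
    rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = gen_panel(config.n_probes)
    panel = sorted(panel, key=lambda p: (p.chrom, p.panel_index))
    if len(panel) != config.n_probes:
        raise ValidationError("panel size does not match config.n_probes")
    ids = config.sample_ids()
    roles = config.roles()

    base = rng.gamma(config.gamma_shape,
                     config.mean_probe_count / config.gamma_shape,
                     size=config.n_probes)
    factors = np.ones((config.n_samples, config.n_probes))
    for cnv in config.planted_cnvs:
        if cnv.first_probe + cnv.n_probes > config.n_probes:
            raise ValidationError("planted CNV span outside the panel")
        factors[cnv.sample_index,
                cnv.first_probe:cnv.first_probe + cnv.n_probes] = cnv.factor
    if config.noise_sigma > 0:
        noise = rng.lognormal(0.0, config.noise_sigma,
                              size=factors.shape)
    else:
        noise = 1.0
    counts = np.rint(base[None, :] * factors * noise).astype(np.int64)
    # NTC wells: stray molecules only
    for i, s in enumerate(ids):
        if roles[s] == "NTC":
            counts[i] = rng.poisson(0.05, size=config.n_probes)

    df = pd.DataFrame(counts, index=ids,
                      columns=[p.probe_id for p in panel])
    df.index.name = "sample_id"
    truth = {
        "planted_cnvs": [asdict(c) for c in config.planted_cnvs],
        "probe_order": [p.probe_id for p in panel],
        "seed": config.seed,
    }
    return CoverageMatrix(df, roles), truth


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

# annotation templates per ACMG class: type + scores that land the
# variant in tiers 1-3 of the cascade
_CLASS_TEMPLATES = {
    5: dict(variant_type="stop_gain", phylop=4.0, cadd_phred=38.0,
            grantham=None),
    4: dict(variant_type="frameshift", phylop=3.1, cadd_phred=28.0,
            grantham=None),
    3: dict(variant_type="missense", phylop=3.5, cadd_phred=24.0,
            grantham=120.0),
}

# ground-truth verdict table of the generator (kept independent of the
# verdict module on purpose): genotype x classes -> expected status
def _expected_status(mode: str, genotype: str,
                     classes: tuple[int, ...],
                     severities: Optional[tuple[str, ...]]) -> str:
    if severities is not None:
        # ABCA4 severity rule for an RP phenotype
        dosage = 2 if genotype in ("homozygous", "hemizygous") else len(severities)
        ok = all(s in ("moderate", "severe") for s in severities)
        return "very_likely_solved" if ok and dosage >= 2 else "unsolved"
    if mode == "AD":
        return ("very_likely_solved" if max(classes) >= 4 else "unsolved")
    if genotype in ("homozygous", "hemizygous"):
        return ("very_likely_solved" if classes[0] >= 4 else "possibly_solved")
    if genotype == "compound_het":
        lo, hi = sorted(classes)
        if (lo, hi) in ((4, 4), (4, 5), (5, 5), (3, 5)):
            return "very_likely_solved"
        if (lo, hi) in ((3, 4), (3, 3)):
            return "possibly_solved"
        return "unsolved"
    return "unsolved"     # single heterozygous allele, recessive gene


def gen_variant_table(config: SimConfig) -> tuple[list[VariantRecord], dict]:
    """Annotated variant table with planted causal genotypes.

    Planted variants receive class-consistent annotations (rare MAFs,
    good depth, tier-1/3 types and scores).  Background variants each
    fail exactly one cascade step by construction — common MAF, shallow
    depth, sub-threshold alt fraction, or a benign type with no splice
    signal — so the designed leak rate through the cascade is zero.
    Recurrent injections are well-annotated variants carried by
    ``recurrence_fraction`` of samples; the run-frequency filter is
    expected to remove them all.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = config.sample_ids()
    roles = config.roles()
    probands = [s for s in ids if roles[s] == "proband"]
    variants: list[VariantRecord] = []
    expected: dict[str, dict] = {s: {"status": "unsolved", "gene": None}
                                 for s in ids}
    gene_chrom = {g: c for g, c, _ in GENE_TABLE}

    pos_counter = 2_000_000
    for pv in config.planted_variants:
        sample = ids[pv.sample_index]
        mode = GENE_MODES[pv.gene]
        chrom = gene_chrom[pv.gene]
        n_alleles = 2 if pv.genotype == "compound_het" else 1
        for a in range(n_alleles):
            cls = pv.classes[a]
            tmpl = dict(_CLASS_TEMPLATES[cls])
            hom_like = pv.genotype in ("homozygous", "hemizygous")
            total = int(rng.integers(80, 160))
            frac = 0.95 if hom_like else 0.47
            sev = (pv.severities[a]
                   if pv.severities is not None else None)
            pos_counter += int(rng.integers(10, 500))
            variants.append(VariantRecord(
                sample_id=sample, chrom=chrom, pos=pos_counter,
                ref="C", alt="T", gene=pv.gene, inheritance=mode,
                alt_reads=int(round(total * frac)), total_reads=total,
                maf_gnomad=1e-5, maf_genomes=None, maf_inhouse=1e-5,
                acmg_class=cls, abca4_severity=sev,
                sai_ag=0.0, sai_al=0.0, sai_dg=0.0, sai_dl=0.0,
                **tmpl))
        expected[sample] = {
            "status": _expected_status(mode, pv.genotype, pv.classes,
                                       pv.severities),
            "gene": pv.gene,
        }

    # recurrent injections: strong annotations, >= 10% of samples
    recurrent_keys = []
    for r in range(config.recurrence_injections):
        n_carriers = int(np.ceil(config.recurrence_fraction * len(ids)))
        carriers = rng.choice(ids, size=n_carriers, replace=False)
        pos = 5_000_000 + r * 1000
        recurrent_keys.append(("chr1", pos, "G", "A"))
        for sample in carriers:
            total = int(rng.integers(50, 150))
            variants.append(VariantRecord(
                sample_id=str(sample), chrom="chr1", pos=pos, ref="G",
                alt="A", gene="USH2A", inheritance="AR",
                variant_type="stop_gain", alt_reads=int(round(total * 0.48)),
                total_reads=total, maf_gnomad=None, acmg_class=5,
                phylop=4.0, cadd_phred=35.0))

    # background: each record fails one designed step
    failure_modes = ("common", "shallow", "low_fraction", "benign_type",
                     "weak_missense")
    bg_genes = [g for g, _, _ in GENE_TABLE]
    for sample in ids:
        n_bg = rng.poisson(config.background_variant_rate)
        for _ in range(n_bg):
            mode_name = failure_modes[int(rng.integers(len(failure_modes)))]
            gene = bg_genes[int(rng.integers(len(bg_genes)))]
            inh = GENE_MODES[gene]
            chrom = gene_chrom[gene]
            pos = int(rng.integers(10_000, 900_000))
            total = int(rng.integers(40, 200))
            frac = float(rng.uniform(0.36, 0.95))
            kwargs = dict(variant_type="missense", phylop=3.5,
                          cadd_phred=24.0, grantham=120.0,
                          maf_gnomad=2e-4, maf_genomes=2e-4,
                          maf_inhouse=2e-4, acmg_class=3)
            if mode_name == "common":
                kwargs.update(maf_gnomad=float(rng.uniform(0.02, 0.2)))
            elif mode_name == "shallow":
                total = int(rng.integers(1, 10))
            elif mode_name == "low_fraction":
                frac = float(rng.uniform(0.02, 0.30))
            elif mode_name == "benign_type":
                kwargs.update(variant_type="synonymous", phylop=0.3,
                              cadd_phred=2.0, grantham=None, acmg_class=2,
                              sai_ag=0.05, sai_al=0.0, sai_dg=0.02,
                              sai_dl=0.0)
            elif mode_name == "weak_missense":
                kwargs.update(phylop=0.5, cadd_phred=6.0, grantham=20.0,
                              acmg_class=2)
            variants.append(VariantRecord(
                sample_id=sample, chrom=chrom, pos=pos, ref="A", alt="G",
                gene=gene, inheritance=inh,
                alt_reads=int(round(total * frac)), total_reads=total,
                **kwargs))

    truth = {
        "expected": expected,
        "n_probands": len(probands),
        "recurrent_keys": recurrent_keys,
        "n_planted": len(config.planted_variants),
        "designed_leak_rate": 0.0,
        "seed": config.seed,
    }
    return variants, truth


# ---------------------------------------------------------------------------
# SAM fixtures
# ---------------------------------------------------------------------------

def gen_sam_fixture(region: TargetRegion,
                    target_depths: Sequence[int],
                    path: Union[str, Path],
                    mate_overlap: bool = False,
                    n_lowq_pairs: int = 0,
                    base_quality: int = 30,
                    low_quality: int = 11) -> Path:
    """Write a SAM-text fixture whose pileup depth equals ``target_depths``.

    The requested profile is decomposed into horizontal layers; each
    layer interval becomes one proper read pair.  With ``mate_overlap``
    both mates span the interval (so a per-mate counter sees double the
    depth while overlap-aware pileup sees the target); otherwise the mate
    is placed beyond the region.  ``n_lowq_pairs`` adds extra pairs whose
    bases sit below the quality threshold and must not change depth.
    """
    depths = np.asarray(target_depths, dtype=np.int64)
    if depths.size != region.length:
        raise ValidationError("target profile length must match the region")
    if (depths < 0).any():
        raise ValidationError("target depths must be non-negative")
    if depths.size and depths.max(initial=0) > 10_000:
        raise ValidationError("target depth above 10,000 not supported")

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": region.chrom, "LN": int(region.end + 100_000)}],
    })

    segments = []
    layer = depths.copy()
    pair_no = 0

    def make_pair(start: int, end: int, quality: int):
        nonlocal pair_no
        pair_no += 1
        name = f"sim{pair_no:06d}"
        length = end - start
        if mate_overlap:
            mate_start = start
            tlen = length
        else:
            mate_start = region.end + 1000 + pair_no * 5
            tlen = mate_start + 50 - start
        for flag, pos, seg_len in (
                (99, start, length),
                (147, mate_start, length if mate_overlap else 50)):
            a = pysam.AlignedSegment(header=header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = [(0, seg_len)]
            a.query_sequence = "A" * seg_len
            a.query_qualities = pysam.qualitystring_to_array(
                chr(quality + 33) * seg_len)
            a.next_reference_id = 0
            a.next_reference_start = mate_start if flag == 99 else start
            a.template_length = tlen if flag == 99 else -tlen
            segments.append(a)

    while layer.size and layer.max(initial=0) > 0:
        in_run = False
        run_start = 0
        for i in range(layer.size + 1):
            positive = i < layer.size and layer[i] > 0
            if positive and not in_run:
                in_run, run_start = True, i
            elif not positive and in_run:
                in_run = False
                make_pair(region.start + run_start, region.start + i,
                          base_quality)
                layer[run_start:i] -= 1

    for _ in range(n_lowq_pairs):
        make_pair(region.start, region.end, low_quality)

    segments.sort(key=lambda a: a.reference_start)
    path = Path(path)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in segments:
            out.write(a)
    return path
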