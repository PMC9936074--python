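"""SNV/indel filtering and prioritization cascade.

The cascade mirrors diagnostic practice for recessive/dominant retinal
disease panels:

1. known pathogenic deep-intronic variants (DIVs) are whitelisted into
   the analysis regardless of frequency;
2. zygosity from the alt-read fraction (>=80% homozygous, 35-80%
   heterozygous, otherwise excluded; sites under 10 reads excluded);
3. rarity: every available minor allele frequency (exomes, genomes,
   in-house cohort) must be <= 0.5% for recessive genes and <= 0.1% for
   dominant genes; a variant absent from a database counts as rare;
4. recurrence: variants seen in >= 10% of probands of the run are
   presumed artefacts or benign and removed;
5. variant-type tiers: protein-truncating/canonical-splice first, then
   in-frame indels, then missense variants by how many of the PhyloP
   (>=2.7), CADD-PHRED (>=15) and Grantham (>=80) thresholds they meet;
6. a splice gate flags any variant with a SpliceAI delta >= 0.2 on any of
   the four parameters (canonical +/-1,2 splice variants are exempt —
   they are already top tier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from ._util import ValidationError

INHERITANCE_MODES = ("AR", "AD", "XL")
VARIANT_TYPES = (
    "stop_gain", "stop_loss", "frameshift", "start_loss", "canonical_splice",
    "inframe_indel", "missense", "synonymous", "ncss", "deep_intronic", "utr",
)
TIER1_TYPES = frozenset(
    {"stop_gain", "stop_loss", "frameshift", "start_loss", "canonical_splice"}
)

# default thresholds of the cascade
AR_MAF_CUTOFF = 0.005
AD_MAF_CUTOFF = 0.001
HOM_FRACTION = 0.80
HET_FRACTION = 0.35
MIN_READS = 10
RUN_FREQUENCY_FRACTION = 0.10
PHYLOP_MIN = 2.7
CADD_MIN = 15.0
GRANTHAM_MIN = 80.0
SPLICEAI_MIN = 0.2

_TSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "inheritance",
    "variant_type", "alt_reads", "total_reads", "maf_gnomad", "maf_genomes",
    "maf_inhouse", "phylop", "cadd_phred", "grantham", "sai_ag", "sai_al",
    "sai_dg", "sai_dl", "acmg_class", "abca4_severity", "known_div",
]


@dataclass(frozen=True)
class VariantRecord:
    """One called and annotated variant in one sample.

    ``pos`` is 1-based (VCF convention).  The three MAFs come from
    independent population resources; ``None`` means absent from that
    resource.  The four SpliceAI deltas are acceptor gain/loss and donor
    gain/loss.  ``acmg_class`` is the 1 (benign) .. 5 (pathogenic) scale;
    ``abca4_severity`` carries the allele-severity annotation used for
    ABCA4 instead of the ACMG class.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    inheritance: str
    variant_type: str
    alt_reads: int
    total_reads: int
    maf_gnomad: Optional[float] = None
    maf_genomes: Optional[float] = None
    maf_inhouse: Optional[float] = None
    phylop: Optional[float] = None
    cadd_phred: Optional[float] = None
    grantham: Optional[float] = None
    sai_ag: Optional[float] = None
    sai_al: Optional[float] = None
    sai_dg: Optional[float] = None
    sai_dl: Optional[float] = None
    acmg_class: Optional[int] = None
    abca4_severity: Optional[str] = None
    known_div: bool = False

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValidationError(
                f"{self.key_str()}: inheritance must be one of "
                f"{INHERITANCE_MODES}, got {self.inheritance!r}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(
                f"{self.key_str()}: unknown variant_type "
                f"{self.variant_type!r}")
        if self.alt_reads < 0 or self.total_reads < 0:
            raise ValidationError(f"{self.key_str()}: negative read counts")
        if self.alt_reads > self.total_reads:
            raise ValidationError(
                f"{self.key_str()}: alt_reads exceeds total_reads")
        for name in ("sai_ag", "sai_al", "sai_dg", "sai_dl"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"{self.key_str()}: SpliceAI delta {name}={v} "
                    "outside [0, 1]")
        if self.acmg_class is not None and self.acmg_class not in range(1, 6):
            raise ValidationError(
                f"{self.key_str()}: ACMG class must be 1..5")
        if self.abca4_severity is not None and \
                self.abca4_severity not in ("mild", "moderate", "severe"):
            raise ValidationError(
                f"{self.key_str()}: abca4_severity must be "
                "mild/moderate/severe")

    @property
    def allele_key(self) -> tuple[str, int, str, str]:
        """Identity of the variant irrespective of carrier."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def key_str(self) -> str:
        return f"{self.sample_id} {self.chrom}:{self.pos}{self.ref}>{self.alt}"

    @property
    def mafs(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return (self.maf_gnomad, self.maf_genomes, self.maf_inhouse)

    @property
    def spliceai_deltas(self) -> tuple[float, float, float, float]:
        return tuple((v if v is not None else 0.0)
                     for v in (self.sai_ag, self.sai_al,
                               self.sai_dg, self.sai_dl))


@dataclass
class PrioritizedVariant:
    """A variant with its cascade outcome and audit trail."""

    variant: VariantRecord
    zygosity: str                 # homozygous | heterozygous | excluded
    tier: int                     # 1..5
    splice_flag: bool
    candidate: bool               # survived all filters & tiers/gates
    audit: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# individual cascade steps
# ---------------------------------------------------------------------------

def call_zygosity(alt_reads: int, total_reads: int,
                  hom_fraction: float = HOM_FRACTION,
                  het_fraction: float = HET_FRACTION,
                  min_reads: int = MIN_READS) -> str:
    """Zygosity from the alt-read fraction.

    The 35%-80% / >=80% bands overlap at exactly 80%, resolved half-open:
    [0.35, 0.80) heterozygous, [0.80, 1] homozygous.  Sites with fewer
    than ``min_reads`` total reads are excluded outright.
    """
    if alt_reads > total_reads:
        raise ValidationError("alt_reads exceeds total_reads")
    if total_reads < min_reads:
        return "excluded"
    fraction = alt_reads / total_reads
    if fraction >= hom_fraction:
        return "homozygous"
    if fraction >= het_fraction:
        return "heterozygous"
    return "excluded"


def maf_filter(v: VariantRecord,
               ar_cutoff: float = AR_MAF_CUTOFF,
               ad_cutoff: float = AD_MAF_CUTOFF) -> bool:
    """True when the variant is rare enough for its inheritance mode.

    All MAFs present must meet the cut-off; a missing MAF is treated as 0
    (absence from a population resource is evidence of rarity).  X-linked
    genes use the recessive cut-off.  Known pathogenic DIVs bypass the
    filter entirely.
    """
    if v.known_div:
        return True
    cutoff = ad_cutoff if v.inheritance == "AD" else ar_cutoff
    return all(maf is None or maf <= cutoff for maf in v.mafs)


def run_frequency_threshold(n_probands: int,
                            fraction: float = RUN_FREQUENCY_FRACTION) -> int:
    """Carrier count at/above which a variant is presumed artefactual.

    ceil(fraction x n_probands); e.g. 38 carriers in a 380-proband run.
    """
    if n_probands <= 0:
        raise ValidationError("n_probands must be positive")
    return math.ceil(fraction * n_probands)


def run_frequency_filter(variants: Sequence[VariantRecord],
                         n_probands: int,
                         fraction: float = RUN_FREQUENCY_FRACTION
                         ) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split variants into (kept, removed) by run-level recurrence.

    A distinct variant (chrom, pos, ref, alt) carried by at least
    ``ceil(fraction x n_probands)`` distinct probands is removed for all
    carriers; whitelisted DIVs are exempt.
    """
    threshold = run_frequency_threshold(n_probands, fraction)
    carriers: dict[tuple, set[str]] = {}
    for v in variants:
        carriers.setdefault(v.allele_key, set()).add(v.sample_id)
    kept, removed = [], []
    for v in variants:
        if not v.known_div and len(carriers[v.allele_key]) >= threshold:
            removed.append(v)
        else:
            kept.append(v)
    return kept, removed


def assign_tier(v: VariantRecord,
                phylop_min: float = PHYLOP_MIN,
                cadd_min: float = CADD_MIN,
                grantham_min: float = GRANTHAM_MIN) -> int:
    """Variant-type tier, 1 (strongest) to 5.

    1: protein-truncating / start-loss / canonical splice;
    2: in-frame indel;
    3: missense meeting all three in-silico thresholds (inclusive);
    4: missense meeting one or two;
    5: everything else (missense meeting none, synonymous, non-canonical
       splice region, deep intronic, UTR) — reachable only through the
       splice gate or the DIV whitelist.  Missing scores do not pass.
    """
    if v.variant_type in TIER1_TYPES:
        return 1
    if v.variant_type == "inframe_indel":
        return 2
    if v.variant_type == "missense":
        passes = sum((
            v.phylop is not None and v.phylop >= phylop_min,
            v.cadd_phred is not None and v.cadd_phred >= cadd_min,
            v.grantham is not None and v.grantham >= grantham_min,
        ))
        if passes == 3:
            return 3
        if passes >= 1:
            return 4
    return 5


def spliceai_gate(v: VariantRecord,
                  threshold: float = SPLICEAI_MIN) -> bool:
    """Splice-prediction flag: any of the four deltas >= threshold.

    Canonical splice-site variants (+/-1 and +/-2 positions) skip the
    gate — they are tier 1 on type alone — so the flag is False for them.
    """
    if v.variant_type == "canonical_splice":
        return False
    return max(v.spliceai_deltas) >= threshold


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

def apply_div_whitelist(variants: Iterable[VariantRecord],
                        whitelist: Optional[set[tuple[str, int, str, str]]]
                        ) -> list[VariantRecord]:
    """Mark variants on the published-DIV whitelist as known_div."""
    if not whitelist:
        return list(variants)
    return [replace(v, known_div=True)
            if v.allele_key in whitelist else v
            for v in variants]


def prioritize(variants: Sequence[VariantRecord],
               n_probands: Optional[int] = None,
               div_whitelist: Optional[set[tuple[str, int, str, str]]] = None,
               ar_cutoff: float = AR_MAF_CUTOFF,
               ad_cutoff: float = AD_MAF_CUTOFF,
               run_fraction: float = RUN_FREQUENCY_FRACTION,
               min_reads: int = MIN_READS,
               spliceai_min: float = SPLICEAI_MIN,
               phylop_min: float = PHYLOP_MIN,
               cadd_min: float = CADD_MIN,
               grantham_min: float = GRANTHAM_MIN
               ) -> list[PrioritizedVariant]:
    """Run the whole cascade and return every variant with its audit.

    Order: DIV whitelist injection -> zygosity (incl. depth) -> MAF ->
    run-frequency -> tier assignment -> splice gate.  ``candidate`` marks
    survivors: pass zygosity, MAF and frequency, and reach tier <= 4, or
    carry a splice flag, or sit on the DIV whitelist.  The returned list
    is sorted by (sample, tier, splice flag desc, position).
    """
    marked = apply_div_whitelist(variants, div_whitelist)
    if n_probands is None:
        n_probands = len({v.sample_id for v in marked}) or 1
    _, removed = run_frequency_filter(marked, n_probands, run_fraction)
    removed_keys = {v.allele_key for v in removed}

    out: list[PrioritizedVariant] = []
    for v in marked:
        audit: dict[str, str] = {}
        zyg = call_zygosity(v.alt_reads, v.total_reads, min_reads=min_reads)
        audit["zygosity"] = zyg
        maf_ok = maf_filter(v, ar_cutoff, ad_cutoff)
        audit["maf"] = "pass" if maf_ok else "fail"
        freq_ok = v.allele_key not in removed_keys
        audit["run_frequency"] = "pass" if freq_ok else "fail"
        tier = assign_tier(v, phylop_min, cadd_min, grantham_min)
        flag = spliceai_gate(v, spliceai_min)
        audit["tier"] = str(tier)
        audit["splice_flag"] = str(flag)
        candidate = (zyg != "excluded" and maf_ok and freq_ok
                     and (tier <= 4 or flag or v.known_div))
        audit["candidate"] = "yes" if candidate else "no"
        out.append(PrioritizedVariant(variant=v, zygosity=zyg, tier=tier,
                                      splice_flag=flag, candidate=candidate,
                                      audit=audit))
    out.sort(key=lambda p: (p.variant.sample_id, p.tier, not p.splice_flag,
                            p.variant.chrom, p.variant.pos))
    return out


def candidates(prioritized: Iterable[PrioritizedVariant]
               ) -> list[PrioritizedVariant]:
    return [p for p in prioritized if p.candidate]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) \
            or value == ".":
        return None
    return float(value)


def read_variants_tsv(path: Union[str, Path]) -> list[VariantRecord]:
    """Read an annotated variant table (TSV dialect)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        sev = d.get("abca4_severity")
        if isinstance(sev, float) and math.isnan(sev):
            sev = None
        acmg = _opt_float(d.get("acmg_class"))
        records.append(VariantRecord(
            sample_id=str(d["sample_id"]), chrom=str(d["chrom"]),
            pos=int(d["pos"]), ref=str(d["ref"]), alt=str(d["alt"]),
            gene=str(d["gene"]), inheritance=str(d["inheritance"]),
            variant_type=str(d["variant_type"]),
            alt_reads=int(d["alt_reads"]), total_reads=int(d["total_reads"]),
            maf_gnomad=_opt_float(d.get("maf_gnomad")),
            maf_genomes=_opt_float(d.get("maf_genomes")),
            maf_inhouse=_opt_float(d.get("maf_inhouse")),
            phylop=_opt_float(d.get("phylop")),
            cadd_phred=_opt_float(d.get("cadd_phred")),
            grantham=_opt_float(d.get("grantham")),
            sai_ag=_opt_float(d.get("sai_ag")),
            sai_al=_opt_float(d.get("sai_al")),
            sai_dg=_opt_float(d.get("sai_dg")),
            sai_dl=_opt_float(d.get("sai_dl")),
            acmg_class=None if acmg is None else int(acmg),
            abca4_severity=sev,
            known_div=bool(d.get("known_div", False)),
        ))
    return records


def write_variants_tsv(variants: Sequence[VariantRecord],
                       path: Union[str, Path]) -> None:
    rows = []
    for v in variants:
        rows.append({c: getattr(v, c) for c in _TSV_COLUMNS})
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=".")


def write_prioritized_tsv(prioritized: Sequence[PrioritizedVariant],
                          path: Union[str, Path]) -> None:
    """Prioritized table with audit columns appended."""
    rows = []
    for p in prioritized:
        row = {c: getattr(p.variant, c) for c in _TSV_COLUMNS}
        row.update({"zygosity": p.zygosity, "tier": p.tier,
                    "splice_flag": p.splice_flag, "candidate": p.candidate,
                    "audit_maf": p.audit.get("maf"),
                    "audit_run_frequency": p.audit.get("run_frequency")})
        rows.append(row)
    cols = _TSV_COLUMNS + ["zygosity", "tier", "splice_flag", "candidate",
                           "audit_maf", "audit_run_frequency"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            na_rep=".")


#: INFO keys of the VCF dialect carrying the annotations.
_VCF_INFO_KEYS = {
    "GENE": "gene", "INH": "inheritance", "TYPE": "variant_type",
    "MAF_G": "maf_gnomad", "MAF_WGS": "maf_genomes", "MAF_IH": "maf_inhouse",
    "PHYLOP": "phylop", "CADD": "cadd_phred", "GRANTHAM": "grantham",
    "SAI_AG": "sai_ag", "SAI_AL": "sai_al", "SAI_DG": "sai_dg",
    "SAI_DL": "sai_dl", "ACMG": "acmg_class", "ABCA4_SEV": "abca4_severity",
}


def read_variants_vcf(path: Union[str, Path],
                      sample_id: Optional[str] = None) -> list[VariantRecord]:
    """Read variants from a single-sample annotated VCF.

    Annotations come from INFO keys (GENE, INH, TYPE, MAF_G, MAF_WGS,
    MAF_IH, PHYLOP, CADD, GRANTHAM, SAI_AG/AL/DG/DL, ACMG, ABCA4_SEV,
    DIV); read support from INFO AO (alt reads) and DP (total).  The
    sample defaults to the VCF's (single) sample name.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        default_sample = sample_id or (list(vcf.header.samples) or ["sample"])[0]
        for rec in vcf:
            info = dict(rec.info)
            kwargs = {}
            for key, attr in _VCF_INFO_KEYS.items():
                if key in info:
                    value = info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    kwargs[attr] = value
            if "acmg_class" in kwargs and kwargs["acmg_class"] is not None:
                kwargs["acmg_class"] = int(kwargs["acmg_class"])
            for numeric in ("maf_gnomad", "maf_genomes", "maf_inhouse",
                            "phylop", "cadd_phred", "grantham",
                            "sai_ag", "sai_al", "sai_dg", "sai_dl"):
                if numeric in kwargs and kwargs[numeric] is not None:
                    kwargs[numeric] = float(kwargs[numeric])
            records.append(VariantRecord(
                sample_id=str(info.get("SAMPLE", default_sample)),
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alt=rec.alts[0] if rec.alts else ".",
                alt_reads=int(info.get("AO", 0)),
                total_reads=int(info.get("DP", 0)),
                known_div=bool(info.get("DIV", False)),
                **kwargs,
            ))
    return records


def load_div_whitelist(path: Union[str, Path]
                       ) -> set[tuple[str, int, str, str]]:
    """Published deep-intronic variants: TSV chrom, pos, ref, alt, gene, citation."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    return {(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples(index=False)}
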