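"""Inheritance-aware diagnostic verdicts and cohort yield.

Surviving variants and CNV calls are combined per gene into allele
pairs, each pair is judged against the inheritance mode of its gene, and
every proband receives one of three statuses:

* very_likely_solved — e.g. a homozygous or compound-heterozygous
  combination of class 4/5 alleles in a recessive gene (class 5 + class 3
  also qualifies), a heterozygous class 4/5 allele in a dominant gene, or
  a hemizygous class 4/5 allele in an X-linked gene;
* possibly_solved — class 4 + class 3 or two class 3 alleles in a
  recessive gene, homozygous class 3, or a hemizygous class 3 allele in
  an X-linked gene;
* unsolved — anything less, including a single heterozygous allele in a
  recessive gene (no segregation data, so no definitive "solved" exists).

For ABCA4, allele severity (mild / moderate / severe) overrides the ACMG
class: a retinitis-pigmentosa phenotype needs two moderate-or-severe
alleles, and mild alleles do not count towards an RP diagnosis.

When several genes could explain one proband, the best-scoring gene is
labelled ``primary`` and the rest ``secondary``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from ._util import ValidationError, percent
from .cnv import CnvCall
from .variants import PrioritizedVariant

VERY_LIKELY = "very_likely_solved"
POSSIBLY = "possibly_solved"
UNSOLVED = "unsolved"
_STATUS_RANK = {UNSOLVED: 0, POSSIBLY: 1, VERY_LIKELY: 2}

PHENOTYPES = ("RP", "LCA", "RD")

#: Optional digenic combinations (gene pair -> minimum classes), off by
#: default.  The classic retinal example is a heterozygous pathogenic
#: variant in each of PRPH2 and ROM1.
DIGENIC_RULES_DEFAULT: dict[frozenset, int] = {}
DIGENIC_PRPH2_ROM1 = {frozenset({"PRPH2", "ROM1"}): 4}


@dataclass(frozen=True)
class Allele:
    """One allele supporting a diagnosis: an SNV/indel or a CNV."""

    source: str                       # "SNV" | "CNV"
    acmg_class: int                   # CNV deletions enter as class 5
    zygosity: str                     # heterozygous | homozygous | hemizygous
    abca4_severity: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("SNV", "CNV"):
            raise ValidationError("allele source must be SNV or CNV")
        if self.zygosity not in ("heterozygous", "homozygous", "hemizygous"):
            raise ValidationError(
                f"unsupported allele zygosity {self.zygosity!r}")

    @property
    def dosage(self) -> int:
        return 1 if self.zygosity == "heterozygous" else 2


@dataclass(frozen=True)
class AllelePair:
    """The allele(s) observed in one gene of one proband."""

    gene: str
    inheritance: str                  # AR | AD | XL
    alleles: tuple[Allele, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValidationError("an allele pair holds 1 or 2 alleles")
        if self.dosage > 2:
            raise ValidationError(
                f"{self.gene}: allele dosage {self.dosage} exceeds 2")

    @property
    def dosage(self) -> int:
        return sum(a.dosage for a in self.alleles)

    @property
    def classes(self) -> tuple[int, ...]:
        return tuple(sorted(a.acmg_class for a in self.alleles))

    @property
    def class_sum(self) -> int:
        return sum(a.acmg_class for a in self.alleles)


@dataclass
class Explanation:
    gene: str
    pair: AllelePair
    status: str
    label: str = "secondary"          # primary | secondary


@dataclass
class ProbandVerdict:
    sample_id: str
    status: str
    explanations: list[Explanation] = field(default_factory=list)

    @property
    def primary_gene(self) -> Optional[str]:
        for e in self.explanations:
            if e.label == "primary":
                return e.gene
        return None


# ---------------------------------------------------------------------------
# single-pair verdicts
# ---------------------------------------------------------------------------

def pair_verdict(pair: AllelePair) -> str:
    """Status earned by one allele pair under its gene's inheritance mode.

    Classes below 3 must have been removed upstream.  Recessive genes
    need allele dosage 2; a single heterozygous allele of any class
    leaves the proband unsolved.
    """
    for a in pair.alleles:
        if a.acmg_class not in (3, 4, 5):
            raise ValidationError(
                f"{pair.gene}: allele class {a.acmg_class} — classes 1/2 "
                "must be removed before verdict assignment")
    mode = pair.inheritance
    if mode == "AR":
        return _ar_verdict(pair)
    if mode == "AD":
        best = max(a.acmg_class for a in pair.alleles)
        return VERY_LIKELY if best >= 4 else UNSOLVED
    if mode == "XL":
        return _xl_verdict(pair)
    raise ValidationError(f"unknown inheritance mode {mode!r}")


def _ar_verdict(pair: AllelePair) -> str:
    if pair.dosage < 2:
        return UNSOLVED
    if len(pair.alleles) == 1:        # homozygous single allele
        return VERY_LIKELY if pair.alleles[0].acmg_class >= 4 else POSSIBLY
    lo, hi = pair.classes
    if (lo, hi) in ((4, 4), (4, 5), (5, 5), (3, 5)):
        return VERY_LIKELY
    if (lo, hi) in ((3, 4), (3, 3)):
        return POSSIBLY
    return UNSOLVED

def _xl_verdict(pair: AllelePair) -> str:
    # hemizygous (or homozygous-female) single allele
    if len(pair.alleles) == 1 and pair.alleles[0].zygosity in (
            "hemizygous", "homozygous"):
        return VERY_LIKELY if pair.alleles[0].acmg_class >= 4 else POSSIBLY
    # two heterozygous alleles in an X-linked gene: judge as recessive
    if pair.dosage >= 2:
        return _ar_verdict(pair)
    return UNSOLVED


def abca4_verdict(pair: AllelePair, phenotype: str = "RP") -> str:
    """ABCA4 verdict where allele severities override the ACMG classes.

    For an RP phenotype both alleles must be moderate or severe; mild
    alleles do not count (a pair left incomplete by a mild allele is
    unsolved).  When any severity annotation is missing the ordinary
    class-based verdict applies, with a warning.
    """
    if pair.gene != "ABCA4":
        raise ValidationError("abca4_verdict applies to ABCA4 pairs only")
    if any(a.abca4_severity is None for a in pair.alleles):
        warnings.warn(
            "ABCA4 allele without severity annotation; falling back to "
            "class-based verdict", stacklevel=2)
        return pair_verdict(pair)
    if phenotype != "RP":
        return pair_verdict(pair)
    qualifying = [a for a in pair.alleles
                  if a.abca4_severity in ("moderate", "severe")]
    if sum(a.dosage for a in qualifying) >= 2:
        return VERY_LIKELY
    return UNSOLVED


def judge_pair(pair: AllelePair, phenotype: str = "RP") -> str:
    """Dispatch: ABCA4 severity rule when annotated, otherwise class rules."""
    if pair.gene == "ABCA4" and any(a.abca4_severity is not None
                                    for a in pair.alleles):
        return abca4_verdict(pair, phenotype)
    return pair_verdict(pair)


# ---------------------------------------------------------------------------
# per-proband combination
# ---------------------------------------------------------------------------

def proband_verdict(sample_id: str,
                    pairs: Sequence[AllelePair],
                    phenotype: str = "RP",
                    inheritance_hint: Optional[str] = None,
                    digenic_rules: Optional[Mapping[frozenset, int]] = None
                    ) -> ProbandVerdict:
    """Combine all of one proband's allele pairs into a single verdict.

    The status is the best over genes; the gene achieving it is labelled
    primary, ties broken by higher summed ACMG class, then concordance
    with the submitted inheritance mode, then gene name.  Every other
    gene reaching at least possibly_solved is a secondary finding.
    """
    explanations = []
    for pair in pairs:
        status = judge_pair(pair, phenotype)
        explanations.append(Explanation(gene=pair.gene, pair=pair,
                                        status=status))
    if digenic_rules:
        explanations.extend(
            _digenic_explanations(pairs, digenic_rules))
    solving = [e for e in explanations if e.status != UNSOLVED]
    if not solving:
        return ProbandVerdict(sample_id=sample_id, status=UNSOLVED,
                              explanations=[])

    def rank(e: Explanation):
        concordant = (inheritance_hint is not None
                      and e.pair.inheritance == inheritance_hint)
        return (_STATUS_RANK[e.status], e.pair.class_sum, concordant)

    solving.sort(key=lambda e: (rank(e), e.gene), reverse=False)
    # best = highest rank; among equal ranks the alphabetically first gene
    best_rank = max(rank(e) for e in solving)
    winners = [e for e in solving if rank(e) == best_rank]
    primary = min(winners, key=lambda e: e.gene)
    primary.label = "primary"
    ordered = [primary] + [e for e in solving if e is not primary]
    return ProbandVerdict(sample_id=sample_id, status=primary.status,
                          explanations=ordered)


def _digenic_explanations(pairs: Sequence[AllelePair],
                          rules: Mapping[frozenset, int]) -> list[Explanation]:
    """Digenic findings: one qualifying het allele in each gene of a rule."""
    by_gene = {p.gene: p for p in pairs}
    out = []
    for genes, min_class in rules.items():
        if not genes <= set(by_gene):
            continue
        members = [by_gene[g] for g in sorted(genes)]
        if all(any(a.acmg_class >= min_class and a.zygosity == "heterozygous"
                   for a in p.alleles) for p in members):
            combined = AllelePair(
                gene="+".join(sorted(genes)), inheritance="AD",
                alleles=(max(members[0].alleles,
                             key=lambda a: a.acmg_class),))
            out.append(Explanation(gene=combined.gene, pair=combined,
                                   status=VERY_LIKELY))
    return out


# ---------------------------------------------------------------------------
# assembling pairs from cascade survivors and CNV calls
# ---------------------------------------------------------------------------

def assemble_pairs(prioritized: Iterable[PrioritizedVariant],
                   cnv_calls: Iterable[CnvCall] = (),
                   gene_modes: Optional[Mapping[str, str]] = None,
                   pair_duplications: bool = False
                   ) -> dict[str, list[AllelePair]]:
    """Build per-proband allele pairs from survivors and CNV calls.

    Only candidate variants with ACMG class 3-5 become alleles.  CNV
    deletions enter as class-5 alleles (heterozygous, or homozygous /
    hemizygous when the normalized coverage indicates full loss);
    duplications are excluded unless ``pair_duplications`` is set, since
    a coverage gain alone has uncertain pathogenicity.  In X-linked genes
    an apparently homozygous genotype is treated as hemizygous.

    Per gene: a homozygous (or hemizygous) allele stands alone; otherwise
    the two highest-class heterozygous alleles pair up; a lone
    heterozygous allele forms an (unsolvable) single-allele recessive
    pair so it still appears in the audit trail.
    """
    gene_modes = dict(gene_modes or {})
    candidates: dict[tuple[str, str], list[Allele]] = {}
    modes: dict[tuple[str, str], str] = {}
    for p in prioritized:
        v = p.variant
        if not p.candidate or p.zygosity == "excluded":
            continue
        if v.acmg_class is None or v.acmg_class < 3:
            continue
        zyg = p.zygosity
        if v.inheritance == "XL" and zyg == "homozygous":
            zyg = "hemizygous"
        key = (v.sample_id, v.gene)
        candidates.setdefault(key, []).append(Allele(
            source="SNV", acmg_class=v.acmg_class, zygosity=zyg,
            abca4_severity=v.abca4_severity,
            description=f"{v.chrom}:{v.pos}{v.ref}>{v.alt}"))
        modes[key] = v.inheritance
        gene_modes.setdefault(v.gene, v.inheritance)
    for c in cnv_calls:
        if c.type == "duplication" and not pair_duplications:
            continue
        for gene in c.genes:
            mode = gene_modes.get(gene, "AR")
            if c.type == "deletion" and \
                    c.zygosity == "homozygous_or_hemizygous":
                zyg = "hemizygous" if mode == "XL" else "homozygous"
            else:
                zyg = "heterozygous"
            key = (c.sample_id, gene)
            candidates.setdefault(key, []).append(Allele(
                source="CNV", acmg_class=5 if c.type == "deletion" else 3,
                zygosity=zyg,
                description=(f"{c.type} {c.chrom} probes "
                             f"{c.first_probe_index}-{c.last_probe_index}")))
            modes.setdefault(key, mode)

    pairs: dict[str, list[AllelePair]] = {}
    for (sample, gene), alleles in candidates.items():
        mode = modes[(sample, gene)]
        full = [a for a in alleles if a.dosage == 2]
        hets = sorted((a for a in alleles if a.dosage == 1),
                      key=lambda a: a.acmg_class, reverse=True)
        if full:
            chosen = (max(full, key=lambda a: a.acmg_class),)
        elif mode == "AD":
            chosen = (hets[0],)
        else:
            chosen = tuple(hets[:2])
        pairs.setdefault(sample, []).append(
            AllelePair(gene=gene, inheritance=mode, alleles=chosen))
    return pairs


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortYield:
    n: int
    n_very_likely: int
    n_possibly: int
    pct_very_likely: float
    pct_possibly: float
    pct_combined: float


def cohort_yield(verdicts: Sequence[ProbandVerdict]) -> CohortYield:
    """Diagnostic yield of a cohort, percentages to one decimal."""
    if not verdicts:
        raise ValidationError("empty cohort")
    n = len(verdicts)
    nv = sum(1 for v in verdicts if v.status == VERY_LIKELY)
    np_ = sum(1 for v in verdicts if v.status == POSSIBLY)
    return cohort_yield_from_counts(n, nv, np_)


def cohort_yield_from_counts(n: int, n_very_likely: int,
                             n_possibly: int) -> CohortYield:
    if n <= 0:
        raise ValidationError("cohort size must be positive")
    return CohortYield(
        n=n, n_very_likely=n_very_likely, n_possibly=n_possibly,
        pct_very_likely=percent(n_very_likely, n),
        pct_possibly=percent(n_possibly, n),
        pct_combined=percent(n_very_likely + n_possibly, n),
    )


def write_verdicts(verdicts: Sequence[ProbandVerdict],
                   path: Union[str, Path]) -> None:
    rows = []
    for v in verdicts:
        if not v.explanations:
            rows.append({"sample_id": v.sample_id, "status": v.status,
                         "gene": ".", "label": ".", "alleles": ".",
                         "classes": "."})
        for e in v.explanations:
            rows.append({
                "sample_id": v.sample_id, "status": v.status,
                "gene": e.gene, "label": e.label,
                "alleles": ";".join(
                    f"{a.source}:{a.zygosity}:{a.description}"
                    for a in e.pair.alleles),
                "classes": ",".join(str(c) for c in e.pair.classes),
            })
    pd.DataFrame(rows, columns=["sample_id", "status", "gene", "label",
                                "alleles", "classes"]).to_csv(
        path, sep="\t", index=False)
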