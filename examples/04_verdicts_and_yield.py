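"""Inheritance-aware verdicts and diagnostic yield.

Runs the cascade on a synthetic cohort, assembles per-gene allele pairs
(including the ABCA4 severity rule), assigns each proband
very_likely_solved / possibly_solved / unsolved, and aggregates the
cohort yield — the same arithmetic that turns 566 + 100 solved of 1,192
probands into a 55.9% diagnostic yield.
"""

from rplca import (
    PlantedVariant, SimConfig, assemble_pairs, cohort_yield,
    cohort_yield_from_counts, gen_variant_table, prioritize,
    proband_verdict,
)

config = SimConfig(
    seed=2, n_samples=40, n_controls=2, n_ntc=1,
    planted_variants=[
        PlantedVariant(0, "USH2A", "homozygous", (5,)),       # AR hom class 5
        PlantedVariant(1, "CRB1", "compound_het", (4, 3)),    # AR 4+3
        PlantedVariant(2, "PRPF31", "heterozygous", (5,)),    # AD het class 5
        PlantedVariant(3, "RPGR", "hemizygous", (4,)),        # XL hemi
        PlantedVariant(4, "ABCA4", "compound_het", (5, 5),
                       ("severe", "mild")),                   # mild: not RP
    ])

variants, truth = gen_variant_table(config)
prioritized = prioritize(variants, n_probands=truth["n_probands"])
pairs = assemble_pairs(prioritized)
samples = sorted({v.sample_id for v in variants})
verdicts = [proband_verdict(s, pairs.get(s, []), phenotype="RP")
            for s in samples]

for v in verdicts:
    if v.status != "unsolved":
        primary = next(e for e in v.explanations if e.label == "primary")
        print(f"{v.sample_id}: {v.status:20s} primary={primary.gene} "
              f"classes={primary.pair.classes}")
print("S0005 stays unsolved: its mild ABCA4 allele does not count "
      "towards an RP diagnosis.\n")

y = cohort_yield(verdicts)
print(f"cohort of {y.n}: very likely {y.n_very_likely} "
      f"({y.pct_very_likely}%), possibly {y.n_possibly} "
      f"({y.pct_possibly}%), combined yield {y.pct_combined}%")

printed = cohort_yield_from_counts(1192, 566, 100)
print(f"published-scale check: 566+100 of 1192 -> "
      f"{printed.pct_very_likely}% / {printed.pct_possibly}% / "
      f"{printed.pct_combined}% combined")
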