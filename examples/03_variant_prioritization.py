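"""The SNV/indel filtering and prioritization cascade.

Generates an annotated variant table for 60 samples with three planted
causal genotypes, ~8 background variants per sample (each designed to
fail one filter) and one artefact recurring in 12% of samples, then runs
the cascade: zygosity from alt-read fractions, tri-source MAF cut-offs
by inheritance mode, the 10% run-recurrence filter, variant-type tiers,
and the SpliceAI gate.
"""

from rplca import PlantedVariant, SimConfig, gen_variant_table, prioritize
from rplca.variants import candidates

config = SimConfig(
    seed=5, n_samples=60, n_controls=2, n_ntc=1,
    recurrence_injections=1,
    planted_variants=[
        PlantedVariant(0, "USH2A", "homozygous", (5,)),
        PlantedVariant(1, "EYS", "compound_het", (4, 3)),
        PlantedVariant(2, "RHO", "heterozygous", (4,)),
    ])

variants, truth = gen_variant_table(config)
prioritized = prioritize(variants, n_probands=truth["n_probands"])
survivors = candidates(prioritized)

print(f"{len(variants)} annotated variants across "
      f"{truth['n_probands']} probands")
print(f"{len(survivors)} candidate allele(s) survive the cascade:")
for p in survivors:
    v = p.variant
    print(f"  {v.sample_id} {v.gene:7s} {v.variant_type:12s} "
          f"class {v.acmg_class}  tier {p.tier}  {p.zygosity}")
removed = len(variants) - len(survivors)
print(f"\n{removed} variants were removed: common alleles, shallow or "
      f"low-fraction calls,\nbenign types without splice signal, and the "
      f"recurrent artefact seen in >=10% of probands.")
print("The survivors are exactly the planted causal alleles "
      f"(designed leak rate {truth['designed_leak_rate']}).")
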