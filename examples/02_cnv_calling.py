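"""Normalized-coverage CNV calling with planted events.

Simulates a 24-sample run over a 60-probe panel with three planted
events — a heterozygous deletion (factor 0.5), a homozygous deletion
(0.0) and a duplication (1.5) — plus a 5-probe deletion that must NOT be
called (the rule needs six or more consecutive probes).
"""

from rplca import (
    PlantedCnv, SimConfig, call_cnvs, chromosome_blocks, gen_coverage,
    gen_panel, normalize,
)

n_probes = 60
panel = gen_panel(n_probes)
# place every event inside one chromosome (runs never cross chromosomes)
chrom, offset, block_len = max(chromosome_blocks(panel), key=lambda b: b[2])

config = SimConfig(
    seed=11, n_samples=24, n_probes=n_probes, n_controls=2, n_ntc=1,
    noise_sigma=0.1,
    planted_cnvs=[
        PlantedCnv(sample_index=0, first_probe=offset, n_probes=7,
                   factor=0.5),
        PlantedCnv(sample_index=1, first_probe=offset, n_probes=6,
                   factor=0.0),
        PlantedCnv(sample_index=2, first_probe=offset, n_probes=8,
                   factor=1.5),
        PlantedCnv(sample_index=3, first_probe=offset, n_probes=5,
                   factor=0.5),   # too short: must stay silent
    ])

matrix, truth = gen_coverage(config, panel)
calls = call_cnvs(normalize(matrix), panel)

print(f"panel: {n_probes} probes; events planted on {chrom} "
      f"(probes {offset}..{offset + block_len - 1})")
print(f"{len(calls)} call(s):")
for c in calls:
    print(f"  {c.sample_id}: {c.type:12s} zygosity={c.zygosity or '-':24s} "
          f"probes {c.first_probe_index}-{c.last_probe_index} "
          f"({c.n_probes} probes), mean normalized coverage "
          f"{c.mean_normalized_coverage:.2f}, genes {'/'.join(c.genes)}")
print("\nS0001 sits near 0.5 (one allele lost), S0002 near 0 (both lost,")
print("reported homozygous_or_hemizygous), S0003 near 1.5 (gain); the")
print("5-probe plant in S0004 is below the six-probe rule and is absent.")
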