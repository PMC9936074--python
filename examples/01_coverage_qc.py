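"""Per-nucleotide coverage QC on a small alignment fixture.

Builds a SAM fixture with a known depth profile over one target region,
runs the pileup (proper pairs only, base quality >= 12, overlapping
mates counted once), and classifies every nucleotide as well (>= 50
reads), moderately (11-49) or poorly (<= 10) covered.
"""

import tempfile
from pathlib import Path

import numpy as np

from rplca import (
    TargetRegion, classify_coverage, coverage_fractions, gen_sam_fixture,
    gene_summary, pileup_depth,
)

region = TargetRegion(gene="RPE65", chrom="chr1", start=5000, end=5300,
                      category="exon")
# 300 nt: 200 well covered, 60 moderate, 40 poor
target = np.concatenate([np.full(200, 80), np.full(60, 30), np.full(40, 6)])

with tempfile.TemporaryDirectory() as tmp:
    sam = gen_sam_fixture(region, target, Path(tmp) / "fixture.sam",
                          mate_overlap=True, n_lowq_pairs=5)
    profile = pileup_depth(sam, region)

counts = classify_coverage(profile)
well, moderate, poor = coverage_fractions(counts)

print(f"region {region.chrom}:{region.start}-{region.end} "
      f"({region.length} nt), mean depth {profile.depths.mean():.0f}x")
print(f"well covered      (>=50 reads): {counts.well:4d} nt  ({well}%)")
print(f"moderately covered (11-49):     {counts.moderate:4d} nt  ({moderate}%)")
print(f"poorly covered     (<=10):      {counts.poor:4d} nt  ({poor}%)")
print(gene_summary({"RPE65": profile}).to_string(index=False))
print("\nThe fixture plants the profile exactly: overlapping mates and")
print("low-quality bases are present but never inflate the depth.")
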