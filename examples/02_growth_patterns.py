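"""Classify centile-crossing growth patterns.

Weight change between two ages, expressed as a difference in SDS, counts
as acceleration above +0.67 SD and deceleration below -0.67 SD (one
centile band).  The fetal (20 weeks -> birth) and infant (birth -> last
available infant weight, 24 -> 11 -> 6 months fallback) categories combine
into 9 patterns.
"""
from earlygrowth import SimConfig, simulate_cohort, true_reference_charts
from earlygrowth.patterns import group_shares, pattern_counts, pattern_table
from earlygrowth.pipeline import derive_efw, derive_sds

cohort = simulate_cohort(SimConfig(n_children=3000, seed=2))
sds = derive_sds(cohort.wide, derive_efw(cohort.wide), true_reference_charts())
patterns = pattern_table(sds)

counts = pattern_counts(patterns["pattern"])
shares = group_shares(counts)
print(f"children with both categories: {counts.sum()}")
for level in counts.index:
    print(f"  {level:30s} n={counts[level]:4d}  ({shares[level]:.1f}%)")
print("source of the infant weight used:")
print(patterns["infant_source"].value_counts().to_string())
# The reference (normal/normal) group is the largest; deceleration followed
# by acceleration is common because of regression to the mean.
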