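"""Simulate a small atrophic vs. control cohort and summarize group effects.

Draws 6+6 synthetic heads (atrophic cortex 2.26 +/- 0.12 mm, control
2.41 +/- 0.10 mm, CSF-compensated), solves all montages per subject and
prints the two directional findings: lower field strength and higher
coefficient of variation in the atrophic group.
"""

from tdcsphere import CohortParams, generate_cohort, simulate_cohort_dataset

cohort = generate_cohort(CohortParams(n_per_group=6, seed=1))
ds = simulate_cohort_dataset(cohort, n_nodes=2000, include_optimized=False)

by = ds.metrics.groupby(["montage", "group"])["mean_normfield"].mean().unstack()
by["reduction_%"] = 100 * (by["control"] - by["AD"]) / by["control"]
print("mean |E| by montage (V/m):")
print(by.round(4).to_string())

cv = ds.metrics.groupby(["group"])["cv"].mean()
print(f"\nmean coefficient of variation: AD {cv['AD']:.1f}%  "
      f"control {cv['control']:.1f}%")

# Gray-matter thinning with CSF expansion shunts current away from the
# cortex: the atrophic group receives a weaker field under every montage,
# while its greater anatomical irregularity raises the spatial variability
# of the normal component in every region.
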