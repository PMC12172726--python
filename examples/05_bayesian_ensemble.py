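"""Fit a small hierarchical model ensemble on known-truth data.

Simulates a balanced long-format table from a hierarchical linear model
with a pure group main effect, fits four candidate mean structures (each
with a subject random intercept) and ranks them by LOOIC.
"""

from tdcsphere import (
    ModelSpec,
    SamplerConfig,
    TruthSpec,
    compare_loo,
    fit_hierarchical,
    simulate_regression_dataset,
)

truth = TruthSpec(
    coefficients={"group[control]": 0.02},
    random_intercept_sd=0.004,
    residual_sd=0.01,
)
data = simulate_regression_dataset(truth, n_subjects=16, seed=3)
sampler = SamplerConfig(chains=2, draws=500, warmup=300, seed=0)

specs = [
    ModelSpec("mean_normal", ()),
    ModelSpec("mean_normal", ("group",)),
    ModelSpec("mean_normal", ("hemisphere",)),
    ModelSpec("mean_normal", ("group", "hemisphere")),
]
fits = [fit_hierarchical(s, data, sampler) for s in specs]
ranking = compare_loo(fits)
print(ranking.table[["model", "looic", "se", "r2"]].round(2).to_string(index=False))

gc = ranking.winner.group_contrast()
print(f"\nwinner: {ranking.winner_name()}")
print(f"group contrast (AD - control): {gc['mean']:.4f} "
      f"[{gc['hdi_lo']:.4f}, {gc['hdi_hi']:.4f}] 95% HDI")

# The generating structure (a group main effect) achieves the lowest LOOIC,
# and the posterior contrast recovers the simulated -0.02 difference with
# an interval that excludes zero.
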