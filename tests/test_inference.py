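"""Model ensemble, Gibbs sampler, LOO ranking, HDI and summary t-test."""

import numpy as np
import pandas as pd
import pytest

from tdcsphere.cohort import TruthSpec, simulate_regression_dataset
from tdcsphere.inference import (
    ModelSpec,
    SamplerConfig,
    build_model_ensemble,
    compare_loo,
    design_matrix,
    fit_hierarchical,
    hdi,
    two_sample_t,
)

FAST = SamplerConfig(chains=2, draws=400, warmup=300, seed=0)


class TestEnsembleConstruction:
    def test_sixteen_models(self):
        specs = build_model_ensemble()
        assert len(specs) == 16
        sizes = sorted(len(s.factors) for s in specs)
        assert sizes == [0] + [1] * 4 + [2] * 6 + [3] * 4 + [4]

    def test_seventeen_with_group_main_only_flag(self):
        specs = build_model_ensemble(include_group_main_only=True)
        assert len(specs) == 17
        extra = specs[-1]
        assert extra.group_main_only
        assert extra.factors == ("region", "hemisphere", "montage")
        assert extra.includes_group()

    def test_null_model_is_intercept_only(self):
        null = build_model_ensemble()[0]
        d = simulate_regression_dataset(TruthSpec(), n_subjects=4, seed=0)
        X, names = design_matrix(d, null)
        assert names == ["intercept"]
        assert np.all(X == 1.0)

    def test_full_interaction_design_has_product_columns(self):
        spec = ModelSpec("mean_normal", ("hemisphere", "group"))
        d = simulate_regression_dataset(TruthSpec(), n_subjects=4, seed=0)
        X, names = design_matrix(d, spec)
        assert "hemisphere[R]" in names and "group[control]" in names
        assert "hemisphere[R]:group[control]" in names
        i = names.index("hemisphere[R]:group[control]")
        manual = ((d["hemisphere"] == "R") & (d["group"] == "control")).to_numpy(float)
        assert np.array_equal(X[:, i], manual)


class TestFitHierarchical:
    def test_constant_data_concentrates_intercept(self):
        d = simulate_regression_dataset(
            TruthSpec(intercept=0.15, random_intercept_sd=0.0, residual_sd=0.0),
            n_subjects=20, seed=0,
        )
        fit = fit_hierarchical(ModelSpec("mean_normal", ()), d, FAST)
        draws = fit.coef_draws("intercept")
        assert np.mean(draws) == pytest.approx(0.15, abs=1e-3)
        # residual width is the subject-variance prior's influence only
        assert np.std(draws) < 2e-2

    def test_recovers_group_coefficient(self):
        truth = TruthSpec(
            coefficients={"group[control]": 0.011},
            random_intercept_sd=0.004, residual_sd=0.01,
        )
        d = simulate_regression_dataset(truth, n_subjects=24, seed=8)
        fit = fit_hierarchical(ModelSpec("mean_normal", ("group",)), d, FAST)
        s = fit.summary().set_index("coefficient")
        row = s.loc["group[control]"]
        assert row["hdi_lo"] < 0.011 < row["hdi_hi"]
        assert fit.converged

    def test_seeded_fit_is_reproducible(self):
        d = simulate_regression_dataset(TruthSpec(), n_subjects=8, seed=0)
        spec = ModelSpec("mean_normal", ("hemisphere",))
        f1 = fit_hierarchical(spec, d, FAST)
        f2 = fit_hierarchical(spec, d, FAST)
        assert np.array_equal(
            f1.idata.posterior["beta"].values, f2.idata.posterior["beta"].values
        )
        assert f1.looic == f2.looic

    def test_group_contrast_sign_convention(self):
        """Contrast is AD minus control: negative when AD is reduced."""
        truth = TruthSpec(
            coefficients={"group[control]": 0.011},  # control above AD
            random_intercept_sd=0.003, residual_sd=0.01,
        )
        d = simulate_regression_dataset(truth, n_subjects=24, seed=9)
        fit = fit_hierarchical(ModelSpec("mean_normal", ("group",)), d, FAST)
        gc = fit.group_contrast()
        assert gc["mean"] < 0
        assert gc["hdi_hi"] < 0


class TestCompareLoo:
    def test_duplicate_fits_tie_within_mc_error(self):
        d = simulate_regression_dataset(TruthSpec(), n_subjects=8, seed=1)
        spec = ModelSpec("mean_normal", ("hemisphere",))
        f1 = fit_hierarchical(spec, d, FAST)
        f2 = fit_hierarchical(spec, d, SamplerConfig(chains=2, draws=400, warmup=300, seed=99))
        ranking = compare_loo([f1, f2])
        diff = abs(ranking.table["looic"].iloc[0] - ranking.table["looic"].iloc[1])
        assert diff < 3.0

    def test_larger_true_model_wins_on_its_own_data(self):
        truth = TruthSpec(
            coefficients={"group[control]": 0.03, "hemisphere[R]": 0.02,
                          "hemisphere[R]:group[control]": 0.02},
            random_intercept_sd=0.003, residual_sd=0.01,
        )
        d = simulate_regression_dataset(truth, n_subjects=24, seed=4)
        small = fit_hierarchical(ModelSpec("mean_normal", ("group",)), d, FAST)
        big = fit_hierarchical(ModelSpec("mean_normal", ("group", "hemisphere")), d, FAST)
        ranking = compare_loo([small, big])
        assert ranking.winner_name() == "group x hemisphere"

    def test_ranking_invariant_under_response_shift(self):
        d = simulate_regression_dataset(
            TruthSpec(coefficients={"hemisphere[R]": 0.05},
                      random_intercept_sd=0.003, residual_sd=0.01),
            n_subjects=16, seed=5,
        )
        d2 = d.copy()
        d2["mean_normal"] = d2["mean_normal"] + 10.0
        specs = [ModelSpec("mean_normal", ()), ModelSpec("mean_normal", ("hemisphere",)),
                 ModelSpec("mean_normal", ("group",))]
        r1 = compare_loo([fit_hierarchical(s, d, FAST) for s in specs])
        r2 = compare_loo([fit_hierarchical(s, d2, FAST) for s in specs])
        assert list(r1.table["model"]) == list(r2.table["model"])


class TestHdi:
    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(2000, 3.14), 0.95)
        assert lo == hi == pytest.approx(3.14)

    def test_interval_within_draw_range(self):
        draws = np.random.default_rng(1).exponential(size=5000)
        lo, hi = hdi(draws, 0.9)
        assert draws.min() <= lo < hi <= draws.max()

    def test_skewed_distribution_narrower_than_central_interval(self):
        draws = np.random.default_rng(2).exponential(size=50_000)
        lo, hi = hdi(draws, 0.9)
        clo, chi = np.quantile(draws, [0.05, 0.95])
        assert (hi - lo) < (chi - clo)


class TestTwoSampleT:
    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,expected",
        [
            (72.05, 5.49, 24, 70.36, 2.20, 24, 1.40),    # age
            (14.96, 2.79, 24, 16.42, 2.67, 24, -1.85),   # education years
            (17.04, 4.90, 24, 29.71, 0.46, 24, -12.60),  # MMSE-NR
        ],
    )
    def test_demographic_rows(self, m1, s1, n1, m2, s2, n2, expected):
        t, df, p = two_sample_t(m1, s1, n1, m2, s2, n2)
        assert t == pytest.approx(expected, abs=0.02)
        assert df == n1 + n2 - 2

    def test_equal_means_give_zero(self):
        t, df, p = two_sample_t(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_symmetry(self):
        t1, _, p1 = two_sample_t(3.0, 1.0, 9, 2.0, 1.2, 11)
        t2, _, p2 = two_sample_t(2.0, 1.2, 11, 3.0, 1.0, 9)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t(1.0, 0.0, 10, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            two_sample_t(1.0, 1.0, 1, 2.0, 1.0, 10)
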