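"""Synthetic cohort generators: geometry cohort and known-truth tables."""

import numpy as np
import pandas as pd
import pytest

from tdcsphere.cohort import (
    CohortParams,
    TruthSpec,
    generate_cohort,
    simulate_cohort_dataset,
    simulate_regression_dataset,
    subject_mesh,
)
from tdcsphere.geometry import build_atlas


class TestGenerateCohort:
    def test_seeded_determinism(self):
        p = CohortParams(n_per_group=6, seed=42)
        c1, c2 = generate_cohort(p), generate_cohort(p)
        for a, b in zip(c1, c2):
            assert a.subject_id == b.subject_id
            assert a.cortical_thickness_mm == b.cortical_thickness_mm
            assert np.allclose(a.head.radii(), b.head.radii())
            assert a.atlas_rotation == b.atlas_rotation

    def test_group_sizes_and_labels(self):
        cohort = generate_cohort(CohortParams(n_per_group=5, seed=0))
        assert sum(s.group == "AD" for s in cohort) == 5
        assert sum(s.group == "control" for s in cohort) == 5

    def test_thickness_sampling_matches_targets(self):
        """Sample means stay within 3 standard errors of the generative
        group means (AD 2.26, control 2.41 mm)."""
        cohort = generate_cohort(CohortParams(n_per_group=24, seed=3))
        for grp, mu, sd in [("AD", 2.26, 0.12), ("control", 2.41, 0.10)]:
            vals = [s.cortical_thickness_mm for s in cohort if s.group == grp]
            se = sd / np.sqrt(len(vals))
            assert abs(np.mean(vals) - mu) < 3 * se

    def test_csf_outer_radius_fixed_thinning_becomes_csf(self):
        cohort = generate_cohort(CohortParams(n_per_group=8, seed=1))
        for s in cohort:
            assert s.head.radius("csf") == pytest.approx(81.0)
            # GM thinning is compensated by CSF thickening
            assert s.head.thickness("csf") == pytest.approx(
                81.0 - s.head.radius("wm") - s.head.thickness("gm")
            )

    def test_null_configuration_centres_group_difference_on_zero(self):
        p = CohortParams(
            n_per_group=10, seed=7,
            ad_thickness_mm=2.41, ad_thickness_sd=0.10,
            ad_variability_factor=1.0,
        )
        cohort = generate_cohort(p)
        gm = {g: np.mean([s.head.thickness("gm") for s in cohort if s.group == g])
              for g in ("AD", "control")}
        # same generative law: difference is pure sampling noise
        assert abs(gm["AD"] - gm["control"]) < 0.2

    def test_subject_mesh_stays_inside_gm_shell(self, atlas):
        cohort = generate_cohort(CohortParams(n_per_group=2, seed=9))
        _, base = build_atlas(cohort[0].head, n_nodes=2000)
        for s in cohort:
            m = subject_mesh(s, base, atlas=atlas)
            assert np.all(m.radii > s.head.radius("wm"))
            assert np.all(m.radii < s.head.radius("gm"))
            assert np.allclose(np.linalg.norm(m.inward_normal, axis=1), 1.0)


@pytest.fixture(scope="module")
def small_ds():
    cohort = generate_cohort(CohortParams(n_per_group=2, seed=11))
    return simulate_cohort_dataset(cohort, n_nodes=2000, include_optimized=False)


class TestSimulateCohortDataset:
    def test_row_count_is_subjects_by_montages_by_cells(self, small_ds):
        # 4 subjects x 5 montages x 10 regions x 2 hemispheres
        assert len(small_ds.metrics) == 4 * 5 * 10 * 2

    def test_no_missing_cells(self, small_ds):
        assert not small_ds.metrics["mean_normfield"].isna().any()
        counts = small_ds.metrics.groupby(["subject", "montage"]).size()
        assert (counts == 20).all()

    def test_rerun_bit_identical(self):
        cohort = generate_cohort(CohortParams(n_per_group=1, seed=13))
        a = simulate_cohort_dataset(cohort, n_nodes=2000)
        b = simulate_cohort_dataset(cohort, n_nodes=2000)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        pd.testing.assert_frame_equal(a.focality, b.focality)

    def test_all_control_cohort_single_group(self):
        p = CohortParams(n_per_group=1, seed=5)
        cohort = [s for s in generate_cohort(p) if s.group == "control"]
        ds = simulate_cohort_dataset(cohort, n_nodes=2000)
        assert set(ds.metrics["group"]) == {"control"}


class TestRegressionSimulator:
    def test_zero_noise_zero_coefficients_constant(self):
        truth = TruthSpec(coefficients={}, random_intercept_sd=0.0, residual_sd=0.0)
        d = simulate_regression_dataset(truth, n_subjects=4, seed=0)
        assert np.allclose(d["mean_normal"], truth.intercept)

    def test_group_contrast_converges_to_truth(self):
        truth = TruthSpec(
            coefficients={"group[control]": 0.011},
            random_intercept_sd=0.004, residual_sd=0.01,
        )
        d = simulate_regression_dataset(truth, n_subjects=400, seed=1)
        means = d.groupby("group")["mean_normal"].mean()
        # MC tolerance: SE of the contrast at this n is well under 0.002
        assert means["control"] - means["AD"] == pytest.approx(0.011, abs=0.002)

    def test_balanced_design(self):
        truth = TruthSpec()
        d = simulate_regression_dataset(truth, n_subjects=8, seed=2)
        cells = d.groupby(["region", "hemisphere", "montage"]).size()
        assert cells.nunique() == 1
        assert d.groupby("group")["subject"].nunique().nunique() == 1

    def test_different_seeds_same_marginal_means(self):
        truth = TruthSpec(coefficients={"hemisphere[R]": 0.02},
                          random_intercept_sd=0.003, residual_sd=0.01)
        d1 = simulate_regression_dataset(truth, n_subjects=200, seed=3)
        d2 = simulate_regression_dataset(truth, n_subjects=200, seed=4)
        assert not d1["mean_normal"].equals(d2["mean_normal"])
        m1 = d1.groupby("hemisphere")["mean_normal"].mean()
        m2 = d2.groupby("hemisphere")["mean_normal"].mean()
        assert np.allclose(m1, m2, atol=0.003)

    def test_unknown_coefficient_name_rejected(self):
        truth = TruthSpec(coefficients={"group[Martians]": 1.0})
        with pytest.raises(ValueError):
            simulate_regression_dataset(truth, n_subjects=4, seed=0)
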