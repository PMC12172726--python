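"""Volume-conductor solver: closed-form oracle, linearity, field invariants."""

import numpy as np
import pytest

from tdcsphere.geometry import build_atlas, build_head_model
from tdcsphere.montages import Electrode, MontageSpec, hd_ring
from tdcsphere.solver import MontageError, point_source_series, solve_field


def homogeneous_monopole_potential(I_mA, sigma, R, r, cos_gamma):
    """Closed-form potential of a scalp point source in a homogeneous sphere
    with the monopole (n=0) term removed: summing the interior Legendre
    series sum_n I (2n+1)/(4 pi sigma R n) t^n P_n analytically via the
    generating functions sum t^n P_n = 1/D - 1 and sum t^n P_n / n =
    log(2 / (1 - t x + D)), D = sqrt(1 - 2 t x + t^2)."""
    t = r / R
    D = np.sqrt(1.0 - 2.0 * t * cos_gamma + t * t)
    return I_mA / (4 * np.pi * sigma * R) * (
        2.0 * (1.0 / D - 1.0) + np.log(2.0 / (1.0 - t * cos_gamma + D))
    )


@pytest.fixture(scope="module")
def homogeneous_head():
    return build_head_model(conductivities=dict.fromkeys(
        ("wm", "gm", "csf", "skull", "scalp"), 0.3))


class TestSeries:
    def test_homogeneous_limit_matches_closed_form(self, homogeneous_head):
        """Beyond 10 deg from the source the series matches the closed form
        to well under 1%."""
        sol = point_source_series(homogeneous_head, np.array([0, 0, 1.0]), 2.0,
                                  n_max=200)
        gamma = np.deg2rad(np.linspace(10, 179, 60))
        r = 74.0
        pts = np.column_stack(
            [r * np.sin(gamma), np.zeros_like(gamma), r * np.cos(gamma)]
        )
        v = sol.potential(pts)
        v_ref = homogeneous_monopole_potential(2.0, 0.3, 92.0, r, np.cos(gamma))
        assert np.max(np.abs(v - v_ref) / np.abs(v_ref)) < 0.01

    def test_zero_current_gives_zero_coefficients(self, head):
        sol = point_source_series(head, np.array([0, 0, 1.0]), 0.0)
        assert np.all(sol.A == 0) and np.all(sol.B == 0)

    def test_linearity_in_current(self, head):
        s1 = point_source_series(head, np.array([0, 0, 1.0]), 1.0)
        s2 = point_source_series(head, np.array([0, 0, 1.0]), 2.0)
        assert np.allclose(2 * s1.A, s2.A) and np.allclose(2 * s1.B, s2.B)

    def test_potential_continuous_across_interfaces(self, head):
        sol = point_source_series(head, np.array([0, 0, 1.0]), 2.0)
        d = np.array([np.sin(0.7), 0, np.cos(0.7)])
        for r_if in (70.0, 78.0, 81.0, 86.0):
            below = sol.potential(d * (r_if - 1e-9))
            above = sol.potential(d * (r_if + 1e-9))
            assert below == pytest.approx(above, rel=1e-6)


class TestSolveField:
    def test_current_reversal_antisymmetry(self, head, mesh, bipolar_montage, bipolar_field):
        swapped = MontageSpec(
            id="swapped",
            electrodes=tuple(
                Electrode(e.position, -e.current_mA, e.area_cm2, e.shape)
                for e in bipolar_montage.electrodes
            ),
            family="bipolar",
            layout=bipolar_montage.layout,
        )
        rev = solve_field(head, swapped, mesh)
        assert np.allclose(rev.normal_component, -bipolar_field.normal_component)
        assert np.allclose(rev.normfield, bipolar_field.normfield)

    def test_cauchy_schwarz_everywhere(self, hd_field, bipolar_field):
        for f in (hd_field, bipolar_field):
            assert np.all(np.abs(f.normal_component) <= f.normfield + 1e-12)

    def test_nonzero_net_current_rejected(self, head, mesh, layout):
        with pytest.raises(Exception):
            MontageSpec(
                id="bad",
                electrodes=(Electrode("F3", 2.0, 35.0), Electrode("F4", -1.0, 35.0)),
                family="bipolar",
                layout=layout,
            )

    def test_insulating_skull_blocks_field(self, mesh, hd_montage):
        open_head = build_head_model()
        closed = build_head_model(conductivities={"skull": 1e-6})
        f_open = solve_field(open_head, hd_montage, mesh)
        f_closed = solve_field(closed, hd_montage, mesh)
        assert f_closed.normfield.max() < 1e-3 * f_open.normfield.max()

    def test_hd_peak_under_anode(self, layout, mesh, hd_field):
        """Brute-force scan: the node with the largest inward normal
        component lies within 20 deg of F3's radial projection."""
        i = int(np.argmax(hd_field.normal_component))
        cosang = mesh.nodes[i] @ layout.direction("F3")
        assert cosang > np.cos(np.deg2rad(20))

    def test_superposition_over_electrodes(self, head, mesh, layout):
        """Field of the 4x1 ring equals the sum of per-electrode fields,
        each run against a common distant reference electrode."""
        ring = hd_ring(layout, "F3", ("F7", "C3", "Fz", "Fp1"))
        full = solve_field(head, ring, mesh)
        total = np.zeros_like(full.E)
        for e in ring.electrodes:
            pair = MontageSpec(
                id=f"pair_{e.position}",
                electrodes=(
                    Electrode(e.position, e.current_mA, e.area_cm2, "hd"),
                    Electrode("Iz", -e.current_mA, e.area_cm2, "hd"),
                ),
                family="bipolar",
                layout=layout,
            )
            total += solve_field(head, pair, mesh).E
        # reference contributions cancel because the ring currents sum to 0
        assert np.allclose(total, full.E, atol=1e-9 + 1e-6 * np.abs(full.E).max())

    def test_series_convergence_n80_to_n120(self, head, mesh, hd_montage):
        f80 = solve_field(head, hd_montage, mesh, n_max=80)
        f120 = solve_field(head, hd_montage, mesh, n_max=120)
        m = mesh.is_region("dlPFC", "L")
        mean80 = np.average(f80.normfield[m], weights=mesh.area_weight[m])
        mean120 = np.average(f120.normfield[m], weights=mesh.area_weight[m])
        assert abs(mean80 - mean120) / mean120 < 0.005

    def test_atrophy_reduces_global_mean_field(self, mesh, library):
        """Thinning GM (CSF outer radius fixed) lowers the global mean field
        strength for every montage in the library."""
        thick = build_head_model()
        thin = thick.with_gm_thickness(8.0 * 2.26 / 2.41)
        _, mesh_thin = build_atlas(thin, n_nodes=2000)
        for montage in library:
            f_thick = solve_field(thick, montage, mesh)
            f_thin = solve_field(thin, montage, mesh_thin)
            assert f_thin.normfield.mean() < f_thick.normfield.mean()
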