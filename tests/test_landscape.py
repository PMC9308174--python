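"""KDE landscape, quasi-potential, advection/reaction fields, restrictions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statefate.abstraction import adopt_labels, build_metric_graph
from statefate.landscape import (FieldError, advection_differentiation,
                                 advection_homeostatic, estimate_nu,
                                 grid_quadrature, kde, reaction, signal,
                                 restrict_to_edges)
from statefate.synthetic import simulate_random_walk


class TestKde:
    def test_single_point_peak_height(self):
        h = 0.1
        ls = kde(np.array([[0.5, 0.5], [0.5, 0.5]]), h, grid_shape=(81, 81),
                 bounds=((0.0, 1.0), (0.0, 1.0)))
        peak = ls.us.max()
        assert peak == pytest.approx(1.0 / (2 * np.pi * h * h), rel=1e-9)

    def test_mass_integrates_to_one(self, rng):
        h = 0.07
        pts = rng.normal(0.0, 0.3, size=(400, 2))
        ls = kde(pts, h, grid_shape=(120, 120), padding=3 * h)
        assert grid_quadrature(ls.us, ls) == pytest.approx(1.0, abs=0.02)

    def test_gradient_vanishes_at_symmetric_mode(self):
        h = 0.2
        ls = kde(np.array([[0.0, 0.0]] * 3), h, grid_shape=(41, 41),
                 bounds=((-1.0, 1.0), (-1.0, 1.0)))
        i = j = 20  # grid centre == the mode
        assert abs(ls.gradU[0][i, j]) < 1e-10
        assert abs(ls.gradU[1][i, j]) < 1e-10

    def test_bandwidth_must_be_positive(self):
        with pytest.raises(FieldError):
            kde(np.zeros((3, 2)), 0.0)


class TestAdvectionHomeostatic:
    def gaussian_landscape(self, sigma=0.25):
        # analytic isotropic Gaussian installed directly as u_s
        x = np.linspace(-1, 1, 101)
        ls = kde(np.zeros((2, 2)), 0.1, grid_shape=(101, 101),
                 bounds=((-1.0, 1.0), (-1.0, 1.0)))
        gx, gy = ls.mesh()
        us = np.exp(-(gx ** 2 + gy ** 2) / (2 * sigma ** 2))
        return ls.with_us(us), sigma

    def test_matches_closed_form_for_gaussian(self):
        ls, sigma = self.gaussian_landscape()
        nu = 0.01
        v1x, v1y = advection_homeostatic(ls, nu)
        gx, gy = ls.mesh()
        sl = slice(30, 70)  # interior, away from the potential floor
        np.testing.assert_allclose(v1x[sl, sl],
                                   -nu * gx[sl, sl] / sigma ** 2, atol=1e-3)
        np.testing.assert_allclose(v1y[sl, sl],
                                   -nu * gy[sl, sl] / sigma ** 2, atol=1e-3)

    def test_zero_at_mode(self):
        ls, _ = self.gaussian_landscape()
        v1x, v1y = advection_homeostatic(ls, 0.01)
        assert abs(v1x[50, 50]) < 1e-12 and abs(v1y[50, 50]) < 1e-12

    def test_linear_in_nu(self):
        ls, _ = self.gaussian_landscape()
        a = advection_homeostatic(ls, 0.01)
        b = advection_homeostatic(ls, 0.02)
        np.testing.assert_allclose(b[0], 2 * a[0])
        np.testing.assert_allclose(b[1], 2 * a[1])


class TestSignalAndV2:
    def test_signal_values(self):
        assert signal(0.0, 5.0) == 1.0
        assert signal(1.0, 1.0) == 0.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0.01, 100))
    def test_signal_monotone_nonincreasing_in_m(self, m1, m2, kappa):
        lo, hi = sorted((m1, m2))
        assert signal(hi, kappa) <= signal(lo, kappa)

    def test_pure_self_renewal_kills_differentiation(self):
        c = (np.ones((4, 4)), np.zeros((4, 4)))
        v2 = advection_differentiation(c, np.ones((4, 4)), np.ones((4, 4)), 1.0)
        np.testing.assert_array_equal(v2[0], 0.0)

    def test_unit_magnitude_case(self):
        c = (np.ones((2, 2)), np.zeros((2, 2)))
        v2 = advection_differentiation(c, np.ones((2, 2)),
                                       np.full((2, 2), 0.5), 1.0)
        np.testing.assert_allclose(v2[0], 1.0)  # 2 (1 - 0.5) * 1 * 1

    def test_linear_in_s(self):
        c = (np.ones((2, 2)), np.ones((2, 2)))
        r = np.full((2, 2), 0.7)
        a = np.full((2, 2), 0.3)
        full = advection_differentiation(c, r, a, 1.0)
        half = advection_differentiation(c, r, a, 0.5)
        np.testing.assert_allclose(half[0], 0.5 * full[0])

    def test_self_renewal_out_of_range_rejected(self):
        c = (np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(FieldError):
            advection_differentiation(c, np.ones((2, 2)),
                                      np.full((2, 2), 1.5), 1.0)


class TestReaction:
    def test_equilibrium_is_zero(self):
        us = np.full((3, 3), 0.7)
        np.testing.assert_array_equal(reaction(us.copy(), us, 1.0, 1.0), 0.0)

    def test_zero_density_zero_reaction(self):
        us = np.full((3, 3), 0.7)
        np.testing.assert_array_equal(reaction(np.zeros((3, 3)), us, 1.0), 0.0)

    def test_overshoot_with_capped_and_uncapped_death(self):
        us = np.ones((2, 2))
        u = 2 * us
        # cap at 1: no decay beyond the cap
        np.testing.assert_array_equal(reaction(u, us, 1.0, dbar=1.0), 0.0)
        # cap at 1.5: d = 1.5, R = r (1 - 1.5) u < 0
        np.testing.assert_allclose(reaction(u, us, 1.0, dbar=1.5), -0.5 * u)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FieldError):
            reaction(np.zeros((2, 2)), np.ones((3, 3)), 1.0)


class TestEstimateNu:
    def test_step_formula(self):
        assert estimate_nu(dx=0.1, dt=0.5) == pytest.approx(0.005)

    def test_zero_step_gives_zero(self):
        assert estimate_nu(dx=0.0, dt=1.0) == 0.0

    def test_round_trip_from_simulated_walks(self):
        nu0 = 0.01
        traj = simulate_random_walk(nu0, 0.02, 2.0, 10000, seed=2)
        est = estimate_nu(trajectories=traj, T=2.0)
        assert abs(est - nu0) / nu0 < 0.15

    def test_too_few_trajectories_rejected(self):
        traj = simulate_random_walk(0.01, 0.1, 1.0, 5, seed=0)
        with pytest.raises(FieldError, match="10"):
            estimate_nu(trajectories=traj, T=1.0)


class TestRestrictToEdges:
    def toy_graph(self):
        coords = np.array([[0.2, 0.5], [0.8, 0.5]] * 5)
        cl = adopt_labels(["L", "R"] * 5, coords)
        return build_metric_graph(cl, {("L", "R"): 1.0}, "L", threshold=0.5)

    def grid_landscape(self):
        return kde(np.array([[0.5, 0.5], [0.4, 0.6]]), 0.2,
                   grid_shape=(101, 101), bounds=((0.0, 1.0), (0.0, 1.0)))

    def test_constant_field_restricts_to_constant(self):
        ls = self.grid_landscape()
        g = self.toy_graph()
        out = restrict_to_edges(ls, g, {"f": np.full(ls.shape, 3.5)},
                                points_per_unit=50)
        np.testing.assert_allclose(out[0].arrays["f"], 3.5)

    def test_axis_aligned_edge_hits_grid_values(self):
        ls = self.grid_landscape()
        g = self.toy_graph()
        field = np.arange(101 * 101, dtype=float).reshape(101, 101)
        out = restrict_to_edges(ls, g, {"f": field}, points_per_unit=100)
        # edge spans x in [0.2, 0.8] at y = 0.5 -> row index 20..80, col 50
        ef = out[0]
        np.testing.assert_allclose(ef.arrays["f"][0], field[20, 50],
                                   atol=1e-9)
        np.testing.assert_allclose(ef.arrays["f"][-1], field[80, 50],
                                   atol=1e-9)

    def test_gaussian_interpolation_error_small(self):
        ls = self.grid_landscape()
        g = self.toy_graph()
        gx, gy = ls.mesh()
        field = np.exp(-((gx - 0.5) ** 2 + (gy - 0.5) ** 2) / 0.08)
        out = restrict_to_edges(ls, g, {"f": field}, points_per_unit=100)
        ef = out[0]
        x = np.linspace(0.2, 0.8, ef.x.size)
        exact = np.exp(-((x - 0.5) ** 2) / 0.08)
        assert np.abs(ef.arrays["f"] - exact).max() < 1e-3

    def test_edge_outside_grid_rejected(self):
        ls = kde(np.array([[0.45, 0.5], [0.55, 0.5]]), 0.01,
                 grid_shape=(11, 11), padding=0.01)
        g = self.toy_graph()  # spans beyond the tiny landscape
        with pytest.raises(FieldError, match="exits"):
            restrict_to_edges(ls, g, {"f": ls.us})
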