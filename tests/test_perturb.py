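"""Gene perturbation and AML scenario modifications."""

import numpy as np
import pytest

from statefate.io import ExpressionMatrix
from statefate.landscape import kde
from statefate.perturb import (PerturbError, PerturbationSpec,
                               aml_field_from_data, aml_field_to_target,
                               block_differentiation_continuum,
                               block_differentiation_graph,
                               boost_proliferation, lowered_death_cap,
                               modify_capacity, perturb_genes)


def raw_matrix():
    values = np.array([[3.0, 0.0, 100.0],
                       [1.0, 5.0, 2.0 ** 15],
                       [0.0, 2.0, 7.0]])
    return ExpressionMatrix(values, ["up", "down", "big"],
                            ["c1", "c2", "c3"])


class TestPerturbGenes:
    def test_fold_change(self):
        out = perturb_genes(raw_matrix(), PerturbationSpec({"up": 1.0}))
        np.testing.assert_allclose(out.values[:, 0], [6.0, 2.0, 0.0])

    def test_zero_expression_stays_zero(self):
        out = perturb_genes(raw_matrix(), PerturbationSpec({"down": 3.0}))
        assert out.values[0, 1] == 0.0

    def test_log_cap_enforced(self):
        out = perturb_genes(raw_matrix(), PerturbationSpec({"big": 5.0}))
        assert np.log2(out.values[:, 2] + 1).max() <= 16.0
        assert out.values[1, 2] == 2.0 ** 16 - 1

    def test_extreme_levels(self):
        spec = PerturbationSpec({"up": 2.0, "down": -1.5}, extreme=True)
        out = perturb_genes(raw_matrix(), spec)
        np.testing.assert_allclose(np.log2(out.values[:, 0] + 1), 16.0)
        np.testing.assert_allclose(np.log2(out.values[:, 1] + 1), 0.0)

    def test_extreme_idempotent(self):
        spec = PerturbationSpec({"up": 2.0, "down": -1.5}, extreme=True)
        once = perturb_genes(raw_matrix(), spec)
        twice = perturb_genes(once, spec)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_unlisted_genes_bitwise_unchanged(self):
        m = raw_matrix()
        out = perturb_genes(m, PerturbationSpec({"up": 1.0}))
        np.testing.assert_array_equal(out.values[:, 1:], m.values[:, 1:])

    def test_unknown_gene_rejected(self):
        with pytest.raises(PerturbError, match="unknown"):
            perturb_genes(raw_matrix(), PerturbationSpec({"nope": 1.0}))

    def test_log_scale_input_rejected(self):
        m = ExpressionMatrix(np.ones((2, 1)), ["g"], ["a", "b"],
                             log_scale=True)
        with pytest.raises(PerturbError, match="raw"):
            perturb_genes(m, PerturbationSpec({"g": 1.0}))


def small_landscape():
    return kde(np.array([[0.5, 0.5], [0.45, 0.55]]), 0.15,
               grid_shape=(41, 41), bounds=((0.0, 1.0), (0.0, 1.0)))


class TestAmlFieldToTarget:
    def test_zero_at_target(self):
        ls = small_landscape()
        vx, vy = aml_field_to_target((0.5, 0.5), 0.05, ls)
        assert vx[20, 20] == 0.0 and vy[20, 20] == 0.0

    def test_points_toward_target(self):
        ls = small_landscape()
        vx, vy = aml_field_to_target((0.5, 0.5), 0.05, ls)
        gx, gy = ls.mesh()
        dot = vx * (0.5 - gx) + vy * (0.5 - gy)
        off = (gx != 0.5) | (gy != 0.5)
        assert np.all(dot[off] > 0)

    def test_magnitude_is_probe_value(self):
        ls = small_landscape()
        d = np.sqrt(0.1)
        vx, vy = aml_field_to_target((0.5 - d, 0.5), 0.05, ls)
        i = int(np.argmin(np.abs(ls.x - 0.5)))
        j = int(np.argmin(np.abs(ls.y - 0.5)))
        mag = np.hypot(vx[i, j], vy[i, j])
        assert mag == pytest.approx(np.exp(-1.0) / (2 * np.pi * 0.05),
                                    rel=1e-6)
        assert mag == pytest.approx(1.1710, abs=1e-3)

    def test_bad_sigma_rejected(self):
        with pytest.raises(PerturbError):
            aml_field_to_target((0.5, 0.5), 0.0, small_landscape())


class TestAmlFieldFromData(object):
    def test_unperturbed_gives_zero_field_with_warning(self, rng):
        from statefate.reduction import diffusion_map

        x = rng.uniform(0, 2, size=(25, 4))
        m = ExpressionMatrix(x, [f"g{j}" for j in range(4)],
                             [f"c{i}" for i in range(25)], log_scale=True)
        space = diffusion_map(m, n_components=2)
        ls = small_landscape()
        with pytest.warns(UserWarning, match="zero"):
            vx, vy = aml_field_from_data(space, m, m, np.arange(25), ls)
        assert np.all(vx == 0) and np.all(vy == 0)

    def test_kernel_regression_matches_hand_computation(self):
        # 3 anchors with known displacements: Nadaraya-Watson by hand
        from statefate.perturb import _nw_smooth

        anchors = np.array([[0.2, 0.2], [0.8, 0.2], [0.5, 0.9]])
        vectors = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.5]])
        ls = small_landscape()
        bw = 0.3
        vx, vy = _nw_smooth(anchors, vectors, ls, bw)
        gx, gy = ls.mesh()
        pt = np.array([gx[10, 25], gy[10, 25]])
        w = np.exp(-((anchors - pt) ** 2).sum(1) / (2 * bw * bw))
        want = (w[:, None] * vectors).sum(0) / w.sum()
        assert vx[10, 25] == pytest.approx(want[0], rel=1e-12)
        assert vy[10, 25] == pytest.approx(want[1], rel=1e-12)

    def test_single_anchor_reproduces_displacement(self):
        from statefate.perturb import _nw_smooth

        ls = small_landscape()
        vx, vy = _nw_smooth(np.array([[0.5, 0.5]]),
                            np.array([[1.0, 0.0]]), ls, 0.05)
        assert vx[20, 20] == pytest.approx(1.0)
        assert vy[20, 20] == 0.0


class TestCapacityAndDeathCap:
    def test_fold_one_is_identity(self):
        ls = small_landscape()
        out = modify_capacity(ls, np.ones(ls.shape), 1.0)
        np.testing.assert_array_equal(out.us, ls.us)

    def test_uniform_tenfold_shifts_potential(self):
        ls = small_landscape()
        out = modify_capacity(ls, np.ones(ls.shape), 10.0)
        np.testing.assert_allclose(out.us, 10 * ls.us)
        interior = ls.us > ls.floor
        np.testing.assert_allclose((ls.U - out.U)[interior], np.log(10.0),
                                   atol=1e-9)

    def test_invalid_weights_rejected(self):
        ls = small_landscape()
        with pytest.raises(PerturbError):
            modify_capacity(ls, np.full(ls.shape, 1.5), 2.0)

    def test_lowered_death_cap_profile(self):
        ls = small_landscape()
        d = lowered_death_cap(ls, (0.5, 0.5), 0.05, 10.0)
        assert d[20, 20] == pytest.approx(0.1)
        assert d.max() <= 1.0 and d.min() >= 0.1 - 1e-12
        np.testing.assert_array_equal(
            lowered_death_cap(ls, (0.5, 0.5), 0.05, 1.0), 1.0)


class TestBlockDifferentiation:
    def test_graph_blocking_clamps_edges_into_target(self, pipeline_small):
        gf = pipeline_small.graph_fields
        graph = pipeline_small.graph
        # Ery is a leaf, so blocking its only edge isolates it
        with pytest.warns(UserWarning, match="isolates"):
            blocked = block_differentiation_graph(graph, ["Ery"])
        assert blocked == {k for k, (_, b, _, _) in enumerate(graph.edges)
                           if b == "Ery"}
        gf.blocked = blocked
        for k in blocked:
            assert gf.face_velocity(k, 1.0).max() <= 0.0
        gf.blocked = set()

    def test_no_targets_is_identity(self, pipeline_small):
        assert block_differentiation_graph(pipeline_small.graph, []) == set()

    def test_unknown_target_rejected(self, pipeline_small):
        with pytest.raises(PerturbError):
            block_differentiation_graph(pipeline_small.graph, ["Nope"])

    def test_continuum_blocking_removes_inward_component(self):
        ls = small_landscape()
        gx, gy = ls.mesh()
        w = np.exp(-((gx - 0.7) ** 2 + (gy - 0.5) ** 2) / 0.02)
        v = (np.ones(ls.shape), np.zeros(ls.shape))
        bx, by = block_differentiation_continuum(v, w)
        wx = np.gradient(w, axis=0)
        wy = np.gradient(w, axis=1)
        dot_after = bx * wx + by * wy
        assert dot_after.max() < 1e-10
        # untouched where the original field pointed away from the cluster
        away = (v[0] * wx + v[1] * wy) <= 0
        np.testing.assert_array_equal(bx[away], v[0][away])


class TestBoostProliferation:
    def test_zero_boost_is_identity(self):
        ls = small_landscape()
        np.testing.assert_array_equal(
            boost_proliferation(ls, 0.0, (0.5, 0.5), 0.05), 0.0)

    def test_short_time_exponential_growth(self):
        # closed-form ODE check: du/dt = r_aml f u at theta*
        from statefate.continuum import ContinuumFields, ContinuumState, simulate

        ls = small_landscape()
        boost = boost_proliferation(ls, 1.0, (0.5, 0.5), 0.05)
        fields = ContinuumFields(landscape=ls, nu=0.0, r_boost=boost,
                                 include_v1=False)
        u0 = np.zeros(ls.shape)
        u0[20, 20] = 1.0
        state = ContinuumState(u0)
        t = 0.05
        simulate(state, fields, T=t, dt=1e-4)
        want = np.exp(boost[20, 20] * t)
        assert state.u[20, 20] == pytest.approx(want, rel=0.01)
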