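"""Metric-graph solver: junction coupling, conservation, edge equivalence."""

import numpy as np
import pytest

from statefate.abstraction import MetricGraph
from statefate.continuum import SolverError
from statefate.graphpde import (GraphFields, GraphState, discretize,
                                graph_mass, initial_condition_graph,
                                node_masses, simulate_graph, step_graph)
from statefate.io import read_result, write_result


def line_graph(n_edges=1, length=1.0):
    labels = [chr(65 + i) for i in range(n_edges + 1)]
    positions = {lab: np.array([i * length, 0.0])
                 for i, lab in enumerate(labels)}
    edges = [(labels[i], labels[i + 1], length, 1.0) for i in range(n_edges)]
    return MetricGraph(labels, positions, edges, labels[0])


def y_graph():
    labels = ["A", "B", "C", "D"]
    positions = {"A": np.array([0.0, 0]), "B": np.array([1.0, 0]),
                 "C": np.array([2.0, 1]), "D": np.array([2.0, -1])}
    edges = [("A", "B", 1.0, 1.0), ("B", "C", 1.0, 1.0),
             ("B", "D", 1.0, 1.0)]
    return MetricGraph(labels, positions, edges, "A")


def uniform_fields(graph, mesh, nu=0.0, us_val=1.0, r_val=0.0, v=0.0,
                   scheme="upwind"):
    us = [np.full(n + 1, us_val) for n in mesh.n_cells]
    return GraphFields(
        mesh=mesh, nu=nu, us=us, U=[-np.log(u) for u in us],
        r=[np.full(n + 1, r_val) for n in mesh.n_cells],
        v2=[np.zeros(n + 1) for n in mesh.n_cells],
        extra_v=[np.full(n + 1, v) for n in mesh.n_cells],
        include_v1=False, scheme=scheme)


class TestDiscretize:
    def test_unit_edge_at_100_per_unit_has_101_samples(self):
        mesh = discretize(line_graph(), points_per_unit=100)
        assert mesh.n_cells == [100]  # samples = n_cells + 1 = 101

    def test_y_junction_volume_is_sum_of_half_cells(self):
        mesh = discretize(y_graph(), points_per_unit=10)
        b = mesh.node_index["B"]
        assert mesh.node_volume[b] == pytest.approx(3 * 0.05)

    def test_mismatched_field_lengths_rejected(self):
        mesh = discretize(line_graph(), points_per_unit=10)
        with pytest.raises(SolverError, match="one array per edge|length"):
            GraphFields(mesh=mesh, nu=0.0, us=[np.ones(3)],
                        U=[np.zeros(3)], r=[np.zeros(3)],
                        v2=[np.zeros(3)], extra_v=[np.zeros(3)])


class TestConservation:
    def test_mass_conserved_without_reaction(self):
        graph = y_graph()
        mesh = discretize(graph, points_per_unit=25)
        fields = uniform_fields(graph, mesh, nu=0.01, v=0.1)
        state = initial_condition_graph(mesh, fields, 0.5)
        m0 = graph_mass(state, mesh)
        dt = fields.cfl_dt()
        for _ in range(200):
            before = graph_mass(state, mesh)
            step_graph(state, fields, dt)
            assert abs(graph_mass(state, mesh) - before) <= 1e-12 * max(1.0, before)
        assert graph_mass(state, mesh) == pytest.approx(m0, rel=1e-10)

    def test_zero_density_stays_zero(self):
        graph = line_graph(2)
        mesh = discretize(graph, points_per_unit=20)
        fields = uniform_fields(graph, mesh, nu=0.01, v=0.2, r_val=0.5)
        state = GraphState(np.zeros(mesh.n_nodes),
                           [np.zeros(n - 1) for n in mesh.n_cells])
        simulate_graph(state, fields, T=1.0)
        assert graph_mass(state, mesh) == 0.0


class TestJunctionTransport:
    def test_pulse_crosses_junction_with_correct_arrival(self):
        # 2-edge path vs the fine single-edge oracle of the merged path
        v, L = 0.5, 1.0
        graph2 = line_graph(2, length=L / 2)
        mesh2 = discretize(graph2, points_per_unit=400)
        fields2 = uniform_fields(graph2, mesh2, nu=0.0, v=v)
        # Gaussian pulse centred at x = 0.15 on the first edge
        state2 = GraphState(np.zeros(3), [np.zeros(n - 1) for n in mesh2.n_cells])
        x = np.arange(1, mesh2.n_cells[0]) * mesh2.h[0]
        state2.edge_u[0] = np.exp(-((x - 0.15) ** 2) / (2 * 0.03 ** 2))
        m0 = graph_mass(state2, mesh2)

        graph1 = line_graph(1, length=L)
        mesh1 = discretize(graph1, points_per_unit=400)
        fields1 = uniform_fields(graph1, mesh1, nu=0.0, v=v)
        state1 = GraphState(np.zeros(2), [np.zeros(n - 1) for n in mesh1.n_cells])
        x1 = np.arange(1, mesh1.n_cells[0]) * mesh1.h[0]
        state1.edge_u[0] = np.exp(-((x1 - 0.15) ** 2) / (2 * 0.03 ** 2))

        T = 1.0  # pulse centre moves to x = 0.65, past the junction at 0.5
        dt = min(fields1.cfl_dt(), fields2.cfl_dt())
        simulate_graph(state2, fields2, T, dt=dt)
        simulate_graph(state1, fields1, T, dt=dt)
        assert graph_mass(state2, mesh2) == pytest.approx(m0, rel=1e-9)
        # peak position on the merged path: second edge local coordinate
        peak2 = (np.argmax(state2.edge_u[1]) + 1) * mesh2.h[1] + L / 2
        assert peak2 == pytest.approx(0.15 + v * T, abs=0.02)
        # profiles agree between the split and merged geometries
        merged = np.concatenate([state2.edge_u[0],
                                 [state2.node_u[1]], state2.edge_u[1]])
        np.testing.assert_allclose(merged, state1.edge_u[0], atol=5e-3)

    def test_stationary_homeostatic_profile(self):
        # v1 = -nu dU/dx with D = nu keeps u_s,k stationary on every edge
        graph = y_graph()
        mesh = discretize(graph, points_per_unit=50)
        nu = 0.01
        us, U = [], []
        # profile over the arclength from the root so that the three edge
        # restrictions agree at the shared junction values
        offsets = [0.0, 1.0, 1.0]
        for k, n in enumerate(mesh.n_cells):
            s = np.linspace(0, 1, n + 1) + offsets[k]
            us_k = np.exp(-(s - 0.8) ** 2)
            us.append(us_k)
            U.append(-np.log(us_k))
        fields = GraphFields(
            mesh=mesh, nu=nu, us=us, U=U,
            r=[np.zeros(n + 1) for n in mesh.n_cells],
            v2=[np.zeros(n + 1) for n in mesh.n_cells],
            extra_v=[np.zeros(n + 1) for n in mesh.n_cells],
            scheme="exponential")
        state = GraphState(
            np.array([us[0][0], us[0][-1], us[1][-1], us[2][-1]]),
            [u[1:-1].copy() for u in us])
        simulate_graph(state, fields, T=10.0)
        for k in range(3):
            rel = np.abs(state.edge_u[k] - us[k][1:-1]).max() / us[k].max()
            assert rel < 0.02

    def test_logistic_dynamics_converge_to_capacity(self):
        graph = line_graph(2)
        mesh = discretize(graph, points_per_unit=30)
        fields = uniform_fields(graph, mesh, nu=0.0, us_val=0.8, r_val=1.0)
        state = initial_condition_graph(mesh, fields, 0.1)
        # seed everywhere so every point relaxes by the logistic closed form
        state.node_u[:] = 0.08
        state.edge_u = [np.full(n - 1, 0.08) for n in mesh.n_cells]
        simulate_graph(state, fields, T=10.0, dt=1e-2)
        for u in state.edge_u:
            assert np.abs(u - 0.8).max() / 0.8 < 0.05


class TestNodeMassesAndInit:
    def test_uniform_density_splits_edge_at_midpoint(self):
        graph = line_graph(1, length=2.0)
        mesh = discretize(graph, points_per_unit=25)
        state = GraphState(np.ones(2),
                           [np.ones(n - 1) for n in mesh.n_cells])
        masses = node_masses(state, mesh)
        assert masses["A"] == pytest.approx(1.0)  # u * L / 2
        assert masses["B"] == pytest.approx(1.0)
        assert sum(masses.values()) == pytest.approx(graph_mass(state, mesh))

    def test_initial_condition_mass_on_stem_half_only(self):
        graph = line_graph(1)
        mesh = discretize(graph, points_per_unit=20)
        fields = uniform_fields(graph, mesh, us_val=1.0)
        state = initial_condition_graph(mesh, fields, 0.5)
        masses = node_masses(state, mesh)
        assert masses["A"] > 0
        assert masses["B"] == 0.0

    def test_bad_fraction_rejected(self):
        graph = line_graph(1)
        mesh = discretize(graph, points_per_unit=20)
        fields = uniform_fields(graph, mesh)
        with pytest.raises(SolverError):
            initial_condition_graph(mesh, fields, 0.0)


class TestResultRoundTrip:
    def test_graph_snapshot_io_lossless(self, tmp_path):
        graph = y_graph()
        mesh = discretize(graph, points_per_unit=15)
        fields = uniform_fields(graph, mesh, nu=0.01, v=0.05)
        state = initial_condition_graph(mesh, fields, 0.3)
        res, _ = simulate_graph(state, fields, T=0.5,
                                snapshot_times=(0.25, 0.5))
        write_result(res, tmp_path / "g.h5")
        back = read_result(tmp_path / "g.h5")
        np.testing.assert_array_equal(back.node_snapshots, res.node_snapshots)
        for a, b in zip(back.edge_snapshots, res.edge_snapshots):
            np.testing.assert_array_equal(a, b)
        assert back.edge_meta == res.edge_meta
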