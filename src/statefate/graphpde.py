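"""Finite-volume solver for the cell-density PDE on a metric graph.

Each edge e_k = (a_k, b_k) carries a 1-D advection-reaction-diffusion
equation; at interior nodes the density is continuous across incident
edges and the advective + diffusive fluxes balance, while terminal nodes
(no inflow or no outflow) reflect.  The discretization keeps a single
shared unknown per node whose control volume is the sum of the adjacent
half-cells: continuity holds exactly by construction, flux balance holds
discretely, and with R = 0 total mass is conserved to machine precision
because every face flux appears once with each sign.

Fluxes use the same upwind / exponential-fitting pair as the continuum
solver; with the exponential flux the restricted homeostatic profile
u_{s,k} = exp(-U_k) is an exact discrete stationary state of the
v1-diffusion pair on every edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abstraction import MetricGraph
from .continuum import SolverError, _bernoulli
from .io import SimulationResult
from .landscape import EdgeField, signal


@dataclass
class GraphMesh:
    """Uniform 1-D meshes per edge plus finite-volume node cells."""

    graph: MetricGraph
    n_cells: list[int]              # samples per edge = n_cells + 1
    h: list[float]
    node_index: dict[str, int]
    node_volume: np.ndarray         # (n_nodes,) sum of adjacent half-cells

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)


def discretize(
    graph: MetricGraph, points_per_unit: float = 100.0, min_interior: int = 4
) -> GraphMesh:
    """Mesh every edge with ``points_per_unit`` cells per unit length."""
    n_cells, h = [], []
    for a, b, length, _ in graph.edges:
        if length <= 0:
            raise SolverError(f"degenerate edge ({a}, {b})")
        n = max(min_interior + 1, int(round(points_per_unit * length)))
        n_cells.append(n)
        h.append(length / n)
    node_index = {lab: i for i, lab in enumerate(graph.node_labels)}
    vol = np.zeros(len(node_index))
    for (a, b, _, _), hk in zip(graph.edges, h):
        vol[node_index[a]] += hk / 2.0
        vol[node_index[b]] += hk / 2.0
    return GraphMesh(graph, n_cells, h, node_index, vol)


@dataclass
class GraphFields:
    """Per-edge coefficient arrays sampled on the solver mesh.

    Every per-edge array has one value per mesh sample (n_k + 1 including
    the endpoints).  ``v2`` carries the s-independent magnitude
    2 (1 - a_k) r_k oriented along the edge; ``blocked`` edges have their
    advective velocity clamped to min(V, 0) (no forward flux).
    """

    mesh: GraphMesh
    nu: float
    us: list[np.ndarray]
    U: list[np.ndarray]
    r: list[np.ndarray]
    v2: list[np.ndarray]
    extra_v: list[np.ndarray]
    kappa: float = 0.0
    dbar: float = 1.0
    include_v1: bool = True
    scheme: str = "exponential"
    blocked: set[int] = field(default_factory=set)
    matured_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("us", "U", "r", "v2", "extra_v"):
            arrs = getattr(self, name)
            if len(arrs) != len(self.mesh.graph.edges):
                raise SolverError(f"{name}: one array per edge required")
            for arr, n in zip(arrs, self.mesh.n_cells):
                if arr.shape != (n + 1,):
                    raise SolverError(
                        f"{name} length {arr.shape[0]} != mesh {n + 1}"
                    )

    def face_velocity(self, k: int, s_value: float) -> np.ndarray:
        """Velocity on the n_k faces between consecutive samples of edge k."""
        v_cell = s_value * self.v2[k] + self.extra_v[k]
        vf = 0.5 * (v_cell[:-1] + v_cell[1:])
        if self.include_v1:
            vf = vf - self.nu * np.diff(self.U[k]) / self.mesh.h[k]
        if k in self.blocked:
            vf = np.minimum(vf, 0.0)
        return vf

    def cfl_dt(self, safety: float = 0.9) -> float:
        bound = np.inf
        for k, hk in enumerate(self.mesh.h):
            if self.nu > 0:
                bound = min(bound, hk * hk / (4.0 * self.nu))
            vmax = float(np.abs(self.face_velocity(k, 1.0)).max())
            if vmax > 0:
                bound = min(bound, hk / vmax)
        # inf when velocity and diffusion both vanish: any dt is admissible
        return safety * bound


def build_graph_fields(
    mesh: GraphMesh,
    edge_fields: list[EdgeField],
    nu: float,
    kappa: float = 0.0,
    dbar: float = 1.0,
    scheme: str = "exponential",
    normalize_us: bool = True,
) -> GraphFields:
    """Assemble solver fields from edge restrictions of the grid fields.

    Expects each :class:`EdgeField` to carry ``us``, ``r`` and ``a``
    arrays.  ``normalize_us`` rescales the restricted homeostatic profile
    to unit total mass over the graph so that continuum and graph masses
    live on the same scale; U_k is recomputed from the rescaled profile.
    """
    graph = mesh.graph
    us, U, r, v2 = [], [], [], []
    floor = 1e-12 * max(float(ef.arrays["us"].max()) for ef in edge_fields)
    for ef, n, hk in zip(edge_fields, mesh.n_cells, mesh.h):
        if ef.x.shape != (n + 1,):
            raise SolverError("edge field sampling does not match the mesh")
        us_k = np.maximum(ef.arrays["us"].copy(), floor)
        us.append(us_k)
        r.append(ef.arrays["r"].copy())
        v2.append(2.0 * (1.0 - ef.arrays["a"]) * ef.arrays["r"])
    if normalize_us:
        total = _graph_integral(us, mesh)
        us = [u / total for u in us]
    U = [-np.log(u) for u in us]
    extra = [np.zeros(n + 1) for n in mesh.n_cells]
    matured = graph.node_classes()["N_F"]
    return GraphFields(mesh, nu, us, U, r, v2, extra, kappa=kappa, dbar=dbar,
                       scheme=scheme, matured_nodes=matured)


def _graph_integral(edge_arrays: list[np.ndarray], mesh: GraphMesh) -> float:
    """Finite-volume integral: half-cells at the endpoints, full inside."""
    total = 0.0
    for arr, hk in zip(edge_arrays, mesh.h):
        total += hk * (0.5 * arr[0] + arr[1:-1].sum() + 0.5 * arr[-1])
    return float(total)


@dataclass
class GraphState:
    """Shared node values plus per-edge interior values."""

    node_u: np.ndarray
    edge_u: list[np.ndarray]        # (n_k - 1,) interior samples per edge
    t: float = 0.0
    s: float = 1.0
    mass_times: list[float] = field(default_factory=list)
    mass_trace: list[float] = field(default_factory=list)
    s_trace: list[float] = field(default_factory=list)

    def copy(self) -> "GraphState":
        return GraphState(self.node_u.copy(), [e.copy() for e in self.edge_u],
                          self.t, self.s, list(self.mass_times),
                          list(self.mass_trace), list(self.s_trace))

    def full_edge(self, mesh: GraphMesh, k: int) -> np.ndarray:
        """Edge samples with the shared node values at the endpoints."""
        a, b, _, _ = mesh.graph.edges[k]
        return np.concatenate((
            [self.node_u[mesh.node_index[a]]],
            self.edge_u[k],
            [self.node_u[mesh.node_index[b]]],
        ))


def graph_mass(state: GraphState, mesh: GraphMesh) -> float:
    total = float((state.node_u * mesh.node_volume).sum())
    for u, hk in zip(state.edge_u, mesh.h):
        total += float(u.sum() * hk)
    return total


def node_masses(state: GraphState, mesh: GraphMesh) -> dict[str, float]:
    """Per-node mass by half-edge counting (samples go to the closest node).

    A sample sitting exactly on an edge midpoint is split evenly.
    """
    masses = {lab: float(state.node_u[i] * mesh.node_volume[i])
              for lab, i in mesh.node_index.items()}
    for k, (a, b, length, _) in enumerate(mesh.graph.edges):
        n, hk = mesh.n_cells[k], mesh.h[k]
        x = np.arange(1, n) * hk
        tol = 1e-12 * length
        near_a = x < length / 2.0 - tol
        near_b = x > length / 2.0 + tol
        mid = ~near_a & ~near_b
        u = state.edge_u[k]
        masses[a] += float((u[near_a].sum() + 0.5 * u[mid].sum()) * hk)
        masses[b] += float((u[near_b].sum() + 0.5 * u[mid].sum()) * hk)
    return masses


def initial_condition_graph(
    mesh: GraphMesh, fields: GraphFields, fraction: float,
    stem_labels: set[str] | None = None,
) -> GraphState:
    """fraction * u_s on the stem node cells and their closest half-edges.

    ``stem_labels`` defaults to the graph's initial (no-inflow) node set.
    """
    if not 0.0 < fraction <= 1.0:
        raise SolverError("fraction must lie in (0, 1]")
    graph = mesh.graph
    if stem_labels is None:
        stem_labels = graph.node_classes()["N_I"]
    stem_labels = set(stem_labels)
    if not stem_labels & set(graph.node_labels):
        raise SolverError("empty stem set")
    node_u = np.zeros(mesh.n_nodes)
    edge_u = []
    for k, (a, b, length, _) in enumerate(graph.edges):
        n, hk = mesh.n_cells[k], mesh.h[k]
        x = np.arange(1, n) * hk
        u = np.zeros(n - 1)
        us_int = fields.us[k][1:-1]
        if a in stem_labels:
            u[x < length / 2.0] = fraction * us_int[x < length / 2.0]
        if b in stem_labels:
            u[x >= length / 2.0] = fraction * us_int[x >= length / 2.0]
        edge_u.append(u)
    for lab in stem_labels:
        i = mesh.node_index[lab]
        us_node = _node_us(fields, mesh, lab)
        node_u[i] = fraction * us_node
    return GraphState(node_u, edge_u)


def _node_us(fields: GraphFields, mesh: GraphMesh, label: str) -> float:
    """Node capacity: average of the adjacent edge-endpoint u_s values."""
    vals = []
    for k, (a, b, _, _) in enumerate(mesh.graph.edges):
        if a == label:
            vals.append(fields.us[k][0])
        if b == label:
            vals.append(fields.us[k][-1])
    return float(np.mean(vals)) if vals else 0.0


def _edge_flux(u_full, vf, nu, h, scheme):
    u_l, u_r = u_full[:-1], u_full[1:]
    if scheme == "exponential" and nu > 0:
        pe = vf * h / nu
        return (nu / h) * (_bernoulli(-pe) * u_l - _bernoulli(pe) * u_r)
    adv = np.where(vf > 0, vf * u_l, vf * u_r)
    return adv - nu * (u_r - u_l) / h


def matured_mass(state: GraphState, mesh: GraphMesh,
                 matured_nodes: set[str]) -> float:
    masses = node_masses(state, mesh)
    return sum(masses[lab] for lab in matured_nodes)


def step_graph(
    state: GraphState, fields: GraphFields, dt: float
) -> GraphState:
    """One explicit finite-volume step on the whole graph."""
    mesh = fields.mesh
    bound = fields.cfl_dt()
    if dt > bound * (1 + 1e-12):
        raise SolverError(
            f"dt = {dt} violates the CFL bound; use dt <= {bound:.3e}"
        )
    m = matured_mass(state, mesh, fields.matured_nodes) \
        if fields.kappa > 0 else 0.0
    s = signal(m, fields.kappa) if fields.kappa > 0 else 1.0

    node_du = np.zeros(mesh.n_nodes)
    new_edges = []
    for k, (a, b, _, _) in enumerate(mesh.graph.edges):
        hk = mesh.h[k]
        u_full = state.full_edge(mesh, k)
        vf = fields.face_velocity(k, s)
        flux = _edge_flux(u_full, vf, fields.nu, hk, fields.scheme)
        interior = u_full[1:-1]
        us_int = fields.us[k][1:-1]
        d = np.minimum(interior / us_int, fields.dbar)
        reaction = fields.r[k][1:-1] * (1.0 - d) * interior
        new_edges.append(
            interior + dt * (-(flux[1:] - flux[:-1]) / hk + reaction)
        )
        node_du[mesh.node_index[a]] -= flux[0]
        node_du[mesh.node_index[b]] += flux[-1]

    new_nodes = state.node_u.copy()
    for lab, i in mesh.node_index.items():
        us_node = _node_us(fields, mesh, lab)
        r_node = _node_value(fields.r, mesh, lab)
        d = min(state.node_u[i] / max(us_node, 1e-300), fields.dbar)
        reaction = r_node * (1.0 - d) * state.node_u[i]
        new_nodes[i] += dt * (node_du[i] / mesh.node_volume[i] + reaction)

    for arr in new_edges:
        np.maximum(arr, 0.0, out=arr)
    np.maximum(new_nodes, 0.0, out=new_nodes)
    state.node_u = new_nodes
    state.edge_u = new_edges
    state.t += dt
    state.s = s
    state.mass_times.append(state.t)
    state.mass_trace.append(graph_mass(state, mesh))
    state.s_trace.append(s)
    return state


def _node_value(arrays: list[np.ndarray], mesh: GraphMesh, label: str) -> float:
    vals = []
    for k, (a, b, _, _) in enumerate(mesh.graph.edges):
        if a == label:
            vals.append(arrays[k][0])
        if b == label:
            vals.append(arrays[k][-1])
    return float(np.mean(vals)) if vals else 0.0


def simulate_graph(
    state0: GraphState,
    fields: GraphFields,
    T: float,
    dt: float | None = None,
    snapshot_times: tuple[float, ...] = (),
    stop_mass_ratio: float | None = None,
    equilibrium_tol: float | None = None,
) -> tuple[SimulationResult, GraphState]:
    """Advance the graph state to ``state0.t + T``; mirrors the continuum API."""
    mesh = fields.mesh
    snapshot_times = tuple(sorted(snapshot_times))
    t0 = state0.t
    if snapshot_times and (snapshot_times[0] < t0 - 1e-9
                           or snapshot_times[-1] > t0 + T + 1e-9):
        raise SolverError("snapshot times must lie within [t0, t0 + T]")
    if dt is None:
        dt = fields.cfl_dt()
        if not np.isfinite(dt):
            raise SolverError("give dt explicitly when V = 0 and nu = 0")
    state = state0
    m0 = graph_mass(state, mesh)
    snap_times: list[float] = []
    node_snaps: list[np.ndarray] = []
    edge_snaps: list[list[np.ndarray]] = [[] for _ in mesh.graph.edges]
    pending = list(snapshot_times)

    def take_snapshot():
        snap_times.append(state.t)
        node_snaps.append(state.node_u.copy())
        for k, u in enumerate(state.edge_u):
            edge_snaps[k].append(u.copy())

    while pending and pending[0] <= state.t + 1e-12:
        take_snapshot()
        pending.pop(0)

    n_steps = int(np.ceil(T / dt - 1e-12))
    check_every = max(1, int(round(1.0 / dt)))
    last_mass, last_t = m0, state.t
    for j in range(n_steps):
        this_dt = min(dt, t0 + T - state.t)
        if this_dt <= 0:
            break
        step_graph(state, fields, this_dt)
        while pending and pending[0] <= state.t + 1e-9:
            take_snapshot()
            pending.pop(0)
        if stop_mass_ratio is not None and m0 > 0 and \
                state.mass_trace[-1] >= stop_mass_ratio * m0:
            break
        if equilibrium_tol is not None and (j + 1) % check_every == 0:
            mass = state.mass_trace[-1]
            rate = abs(mass - last_mass) / max(mass, 1e-300) / (state.t - last_t)
            if rate < equilibrium_tol:
                break
            last_mass, last_t = mass, state.t

    result = SimulationResult(
        geometry="graph",
        times=np.asarray(snap_times),
        mass_times=np.asarray(state.mass_times),
        mass=np.asarray(state.mass_trace),
        s_values=np.asarray(state.s_trace),
        node_snapshots=np.asarray(node_snaps) if node_snaps else np.zeros(
            (0, mesh.n_nodes)),
        edge_snapshots=[np.asarray(sn) if sn else np.zeros((0, n - 1))
                        for sn, n in zip(edge_snaps, mesh.n_cells)],
        edge_meta=[(a, b, length, n - 1) for (a, b, length, _), n in
                   zip(mesh.graph.edges, mesh.n_cells)],
        node_labels=list(mesh.graph.node_labels),
    )
    return result, state


def stacked_edge_table(state: GraphState, mesh: GraphMesh):
    """Edge-stacked export (one row per sample: edge, a, b, x, u)."""
    import pandas as pd

    rows = []
    for k, (a, b, length, _) in enumerate(mesh.graph.edges):
        u_full = state.full_edge(mesh, k)
        x = np.linspace(0.0, length, mesh.n_cells[k] + 1)
        for xi, ui in zip(x, u_full):
            rows.append((k, a, b, xi, ui))
    return pd.DataFrame(rows, columns=["edge", "a", "b", "x", "u"])
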