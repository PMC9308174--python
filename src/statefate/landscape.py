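"""Homeostatic landscape, quasi-potential and PDE coefficient fields.

The homeostatic cell distribution u_s is an isotropic Gaussian kernel
density estimate of the embedded cells on a rectangular grid over the
reduced space; the quasi-potential is U = -ln(u_s) (floored so U stays
finite outside the support).  From these the solvers obtain

* v1 = -nu * grad(U): drift toward the homeostatic attractor,
* v2 = c(theta) * 2 (1 - a) r * s(t): active differentiation along the
  lineage graph, damped by the matured-cell feedback signal s(t),
* R = r (1 - min(u/u_s, d_bar)) u: logistic growth against the local
  capacity u_s,
* D = nu: constant phenotypic-instability diffusion.

All grid fields can be restricted to the straight edges of a metric graph
by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .abstraction import CellClustering, MetricGraph

FLOOR_FACTOR = 1e-12  # potential floor: eps = FLOOR_FACTOR * max(u_s)


class FieldError(ValueError):
    pass


@dataclass
class Landscape:
    """u_s, U = -ln(u_s) and grad(U) on a uniform rectangular grid."""

    x: np.ndarray            # (M1,) grid axis of theta_1
    y: np.ndarray            # (M2,) grid axis of theta_2
    us: np.ndarray           # (M1, M2) homeostatic density
    U: np.ndarray
    gradU: tuple[np.ndarray, np.ndarray]
    h: float                 # KDE bandwidth
    floor: float

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.us.shape

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="ij")

    def interpolator(self, values: np.ndarray) -> RegularGridInterpolator:
        return RegularGridInterpolator((self.x, self.y), values,
                                       bounds_error=True)

    def with_us(self, us: np.ndarray) -> "Landscape":
        """Rebuild U and grad(U) from a replacement density."""
        U, gradU, floor = _potential(us, self.dx, self.dy)
        return replace(self, us=us, U=U, gradU=gradU, floor=floor)


def _potential(us, dx, dy):
    floor = FLOOR_FACTOR * float(us.max())
    U = -np.log(np.maximum(us, floor))
    gx, gy = np.gradient(U, dx, dy)
    return U, (gx, gy), floor


def kde(
    points: np.ndarray,
    h: float,
    grid_shape: tuple[int, int] = (100, 100),
    padding: float | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> Landscape:
    """Gaussian KDE of embedded cells on a uniform grid.

    u_s(theta) = (1/N) sum_i K_h(theta - theta_i) with the isotropic 2-D
    standard normal kernel, so a single point peaks at 1/(2 pi h^2).
    The grid covers the bounding box of the points padded by ``padding``
    (absolute units; default 10% of the larger span), unless explicit
    ``bounds`` are given.
    """
    points = np.asarray(points, dtype=float)
    if h <= 0:
        raise FieldError("KDE bandwidth h must be positive")
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 2:
        raise FieldError("need at least 2 points in 2-D")
    if bounds is None:
        lo, hi = points.min(axis=0), points.max(axis=0)
        if padding is None:
            padding = 0.1 * float((hi - lo).max())
        lo, hi = lo - padding, hi + padding
        bounds = ((lo[0], hi[0]), (lo[1], hi[1]))
    x = np.linspace(*bounds[0], grid_shape[0])
    y = np.linspace(*bounds[1], grid_shape[1])
    us = _gaussian_kde_grid(points, x, y, h)
    U, gradU, floor = _potential(us, float(x[1] - x[0]), float(y[1] - y[0]))
    return Landscape(x, y, us, U, gradU, h, floor)


def _gaussian_kde_grid(points, x, y, h) -> np.ndarray:
    # separable kernel: K(dx) K(dy) summed over points, in chunks
    kx = np.exp(-((x[:, None] - points[None, :, 0]) ** 2) / (2 * h * h))
    ky = np.exp(-((y[:, None] - points[None, :, 1]) ** 2) / (2 * h * h))
    us = kx @ ky.T  # (M1, M2) = sum_i kx[:, i] * ky[:, i]
    return us / (2.0 * np.pi * h * h * points.shape[0])


def grid_quadrature(values: np.ndarray, landscape: Landscape) -> float:
    """Trapezoid integral of a grid field over the landscape domain."""
    return float(np.trapezoid(np.trapezoid(values, landscape.y, axis=1),
                              landscape.x))


def advection_homeostatic(
    landscape: Landscape, nu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Attractor drift v1 = -nu * grad(U) toward the homeostatic landscape."""
    gx, gy = landscape.gradU
    return -nu * gx, -nu * gy


def signal(matured_mass: float, kappa: float) -> float:
    """Differentiation feedback s = 1 / (1 + kappa * m), in (0, 1]."""
    if matured_mass < 0 or kappa < 0:
        raise FieldError("matured mass and kappa must be non-negative")
    return 1.0 / (1.0 + kappa * matured_mass)


def advection_differentiation(
    c_field: tuple[np.ndarray, np.ndarray],
    r: np.ndarray,
    a: np.ndarray,
    s_value: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Active differentiation drift v2 = c * [2 (1 - a) r] * s."""
    if not 0.0 < s_value <= 1.0:
        raise FieldError("s must lie in (0, 1]")
    if np.any(a < 0) or np.any(a > 1):
        raise FieldError("self-renewal rate a must lie in [0, 1]")
    mag = 2.0 * (1.0 - a) * r * s_value
    return c_field[0] * mag, c_field[1] * mag


def reaction(
    u: np.ndarray, us: np.ndarray, r: np.ndarray | float,
    dbar: float = 1.0, floor: float = 0.0
) -> np.ndarray:
    """Logistic reaction R = r (1 - min(u/u_s, d_bar)) u."""
    if np.shape(u) != np.shape(us):
        raise FieldError("u and u_s shapes must match")
    d = np.minimum(u / np.maximum(us, max(floor, 1e-300)), dbar)
    return r * (1.0 - d) * u


def estimate_nu(
    trajectories: np.ndarray | None = None,
    T: float | None = None,
    dx: float | None = None,
    dt: float | None = None,
) -> float:
    """Diffusivity from random-walk statistics.

    Step form: nu = dx^2 / (4 dt).  Trajectory form: the total (summed over
    both components) variance of Brownian endpoints is 4 nu T, so nu is
    that variance divided by 4 T.
    """
    if trajectories is not None:
        if T is None or T <= 0:
            raise FieldError("trajectory form needs the horizon T > 0")
        traj = np.asarray(trajectories, dtype=float)
        if traj.shape[0] < 10:
            raise FieldError("need at least 10 trajectories")
        var_total = traj[:, -1, :].var(axis=0).sum()
        return float(var_total / (4.0 * T))
    if dx is None or dt is None:
        raise FieldError("provide either trajectories or (dx, dt)")
    if dx < 0 or dt <= 0:
        raise FieldError("need dx >= 0 and dt > 0")
    return float(dx * dx / (4.0 * dt))


def nearest_cluster_grid(
    landscape: Landscape, clustering: CellClustering
) -> np.ndarray:
    """(M1, M2) integer map of the nearest cluster centroid per grid point."""
    gx, gy = landscape.mesh()
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    labels = clustering.cluster_labels
    cents = np.stack([clustering.centroids[lab] for lab in labels])
    d2 = ((pts[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1).reshape(landscape.shape)


def direction_field(
    graph: MetricGraph, landscape: Landscape
) -> tuple[np.ndarray, np.ndarray]:
    """Unit differentiation direction c(theta) from the metric graph.

    At each grid point, c is the unit vector of the nearest edge segment
    in its root-to-leaf direction (magnitude 1 everywhere).
    """
    gx, gy = landscape.mesh()
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    best_d2 = np.full(len(pts), np.inf)
    cx = np.zeros(len(pts))
    cy = np.zeros(len(pts))
    for a, b, length, _ in graph.edges:
        pa, pb = graph.positions[a], graph.positions[b]
        seg = pb - pa
        t = np.clip(((pts - pa) @ seg) / (length * length), 0.0, 1.0)
        proj = pa[None, :] + t[:, None] * seg[None, :]
        d2 = ((pts - proj) ** 2).sum(axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        unit = seg / length
        cx[closer], cy[closer] = unit[0], unit[1]
    return cx.reshape(landscape.shape), cy.reshape(landscape.shape)


#: fallback (proliferation, self-renewal) for unknown cluster labels
DEFAULT_RATE = (0.5, 0.9)

#: per-cluster (r, a) defaults for the stock hematopoiesis tree, fixed by
#: the normal-hematopoiesis calibration (see docs/methods.md)
DEFAULT_RATES: dict[str, tuple[float, float]] = {
    "HSC": (0.2, 0.90), "MPP": (0.4, 0.90), "CMP": (0.5, 0.90),
    "GMP": (0.6, 0.90), "MEP": (0.6, 0.90), "Lymph": (0.6, 1.0),
    "Ery": (0.8, 1.0), "Neu": (0.8, 1.0), "Mo": (0.8, 1.0),
}


@dataclass
class RateField:
    """Piecewise-constant rate fields plus scalar model parameters."""

    r_grid: np.ndarray                       # proliferation rate [1/pseudotime]
    a_grid: np.ndarray                       # self-renewal rate in [0, 1]
    c_field: tuple[np.ndarray, np.ndarray]   # unit differentiation direction
    nu: float                                # diffusivity
    kappa: float                             # signal gain
    dbar: float                              # max apoptosis magnitude
    matured_labels: set[str] = field(default_factory=set)
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.a_grid < 0) or np.any(self.a_grid > 1):
            raise FieldError("a must lie in [0, 1]")
        if np.any(self.r_grid < 0):
            raise FieldError("r must be non-negative")
        if self.nu <= 0:
            raise FieldError("nu must be positive")
        if not 0.0 < self.dbar:
            raise FieldError("d_bar must be positive")


def build_rate_field(
    landscape: Landscape,
    clustering: CellClustering,
    graph: MetricGraph,
    rates: dict[str, tuple[float, float]] | None = None,
    nu: float = 0.005,
    kappa: float = 100.0,
    dbar: float = 1.0,
) -> RateField:
    """Assemble r(theta), a(theta), c(theta) from per-cluster parameters.

    ``rates`` maps cluster label -> (r, a); missing labels fall back to
    :data:`DEFAULT_RATES` then :data:`DEFAULT_RATE`.  Matured clusters are
    the graph's terminal (no-outflow) nodes; their mass drives s(t).
    """
    rates = {**DEFAULT_RATES, **(rates or {})}
    labels = clustering.cluster_labels
    nearest = nearest_cluster_grid(landscape, clustering)
    r_grid = np.empty(landscape.shape)
    a_grid = np.empty(landscape.shape)
    for k, lab in enumerate(labels):
        r, a = rates.get(lab, DEFAULT_RATE)
        mask = nearest == k
        r_grid[mask] = r
        a_grid[mask] = a
    c = direction_field(graph, landscape)
    matured = graph.node_classes()["N_F"]
    return RateField(r_grid, a_grid, c, nu, kappa, dbar, matured,
                     {lab: rates.get(lab, DEFAULT_RATE) for lab in labels})


@dataclass
class EdgeField:
    """1-D restriction of grid fields to one metric-graph edge."""

    a: str
    b: str
    length: float
    x: np.ndarray                      # (n+1,) positions along the edge
    arrays: dict[str, np.ndarray]      # per-field samples, each (n+1,)

    def __post_init__(self) -> None:
        for name, arr in self.arrays.items():
            if arr.shape != self.x.shape:
                raise FieldError(
                    f"field {name!r} length {arr.shape} != mesh {self.x.shape}"
                )


def restrict_to_edges(
    landscape: Landscape,
    graph: MetricGraph,
    fields: dict[str, np.ndarray],
    points_per_unit: float = 100.0,
    min_interior: int = 4,
) -> list[EdgeField]:
    """Sample grid fields along each straight edge by bilinear interpolation.

    Each edge gets a uniform 1-D mesh with ``points_per_unit`` samples per
    unit length (at least ``min_interior`` interior points); sample 0 sits
    on node a and the last sample on node b.
    """
    interps = {name: landscape.interpolator(arr)
               for name, arr in fields.items()}
    out = []
    for a, b, length, _ in graph.edges:
        if length <= 0:
            raise FieldError(f"degenerate edge ({a}, {b})")
        n = max(min_interior + 1, int(round(points_per_unit * length)))
        x = np.linspace(0.0, length, n + 1)
        pa, pb = landscapes_pos(graph, a), landscapes_pos(graph, b)
        pts = pa[None, :] + (x / length)[:, None] * (pb - pa)[None, :]
        try:
            arrays = {name: itp(pts) for name, itp in interps.items()}
        except ValueError as err:
            raise FieldError(
                f"edge ({a}, {b}) exits the landscape grid: {err}"
            ) from err
        out.append(EdgeField(a, b, length, x, arrays))
    return out


def landscapes_pos(graph: MetricGraph, node: str) -> np.ndarray:
    return np.asarray(graph.positions[node], dtype=float)
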