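"""Gene-level perturbations and leukemia scenario modifications.

In-silico perturbation multiplies selected genes by 2**gamma (gamma the
log2 fold change) with the log2(g + 1) level clipped into [0, 16]; the
extreme mode pins the log level to exactly 16 (up) or 0 (down).  The
scenario builders translate perturbed data or a hypothesised abnormal
state theta* into modifications of the PDE model: an aberrant advection
field smoothed from per-cell displacements (v_aml1) or aimed at theta*
(v_aml2), a local capacity increase, a differentiation block, and a local
over-proliferation boost.  All reduce to the identity at
(c_aml, r_aml, fold) = (0, 0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import LOG2_CAP, ExpressionMatrix
from .landscape import Landscape
from .quantify import gaussian_probe
from .reduction import ReducedSpace, displacement_field


class PerturbError(ValueError):
    pass


RAW_CAP = 2.0 ** LOG2_CAP - 1.0  # raw count whose log2(g + 1) level is 16


@dataclass
class PerturbationSpec:
    """Gene -> log2 fold change map plus AML scenario parameters."""

    genes: dict[str, float]
    extreme: bool = False
    c_aml: float = 0.0
    r_aml: float = 0.0
    theta_star: tuple[float, float] | None = None
    sigma2: float = 0.05
    capacity_fold: float = 1.0
    blocked_targets: list[str] = field(default_factory=list)
    subset_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.capacity_fold < 1.0:
            raise PerturbError("capacity_fold must be >= 1")
        if self.c_aml < 0 or self.r_aml < 0:
            raise PerturbError("c_aml and r_aml must be non-negative")


def perturb_genes(
    E: ExpressionMatrix, spec: PerturbationSpec
) -> ExpressionMatrix:
    """Apply g_tilde = 2**gamma * g per listed gene, capped at log level 16.

    The matrix must be raw scale.  In extreme mode, up-regulated genes
    (gamma > 0) are pinned to log2(g + 1) = 16 and down-regulated ones
    (gamma < 0) to 0; unlisted genes are untouched bitwise.
    """
    if E.log_scale:
        raise PerturbError("perturbation operates on the raw scale")
    unknown = sorted(set(spec.genes) - set(E.gene_ids))
    if unknown:
        raise PerturbError(f"unknown gene ids: {unknown[:5]}")
    values = E.values.copy()
    col = {g: j for j, g in enumerate(E.gene_ids)}
    for gene, gamma in spec.genes.items():
        j = col[gene]
        if spec.extreme:
            if gamma > 0:
                values[:, j] = RAW_CAP
            elif gamma < 0:
                values[:, j] = 0.0
        else:
            values[:, j] = np.minimum(values[:, j] * 2.0 ** gamma, RAW_CAP)
    return E.with_values(values)


def aml_field_from_data(
    space: ReducedSpace,
    E_log: ExpressionMatrix,
    E_perturbed_log: ExpressionMatrix,
    subset: np.ndarray,
    landscape: Landscape,
    smoothing_bandwidth: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Aberrant advection v_aml1: smoothed per-cell displacement vectors.

    Per-cell displacements P(g_tilde) - P(g) on the selected cells are
    spread onto the landscape grid by Nadaraya-Watson kernel regression
    (Gaussian kernel, ``smoothing_bandwidth``); grid points whose total
    kernel weight falls below 1e-6 get a zero vector, so the field
    vanishes away from the perturbed subset.
    """
    vectors, _ = displacement_field(space, E_log, E_perturbed_log, subset)
    idx = np.arange(E_log.n_cells)
    idx = idx[subset] if np.asarray(subset).dtype == bool else np.asarray(subset)
    anchors = space.embedding[idx]
    if np.allclose(vectors, 0.0):
        warnings.warn("all displacements are zero; returning a zero field",
                      stacklevel=2)
        z = np.zeros(landscape.shape)
        return z, z.copy()
    return _nw_smooth(anchors, vectors, landscape, smoothing_bandwidth)


def _nw_smooth(anchors, vectors, landscape, bandwidth):
    """Nadaraya-Watson regression of per-cell vectors onto the grid."""
    gx, gy = landscape.mesh()
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    d2 = cdist(pts, anchors, "sqeuclidean")
    w = np.exp(-d2 / (2.0 * bandwidth ** 2))
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = (w @ vectors[:, 0]) / wsum
        vy = (w @ vectors[:, 1]) / wsum
    small = wsum < 1e-6
    vx[small] = 0.0
    vy[small] = 0.0
    return vx.reshape(landscape.shape), vy.reshape(landscape.shape)


def aml_field_to_target(
    theta_star, sigma2: float, landscape: Landscape
) -> tuple[np.ndarray, np.ndarray]:
    """Aberrant advection v_aml2: Gaussian-weighted unit vectors toward theta*.

    v_aml2(theta) = f_theta*(theta) * (theta* - theta)/||theta* - theta||,
    with the zero vector at theta* itself by convention.
    """
    if sigma2 <= 0:
        raise PerturbError("sigma2 must be positive")
    theta_star = np.asarray(theta_star, dtype=float)
    if not (landscape.x[0] <= theta_star[0] <= landscape.x[-1]
            and landscape.y[0] <= theta_star[1] <= landscape.y[-1]):
        raise PerturbError("theta_star must lie inside the landscape grid")
    gx, gy = landscape.mesh()
    dx_ = theta_star[0] - gx
    dy_ = theta_star[1] - gy
    dist = np.sqrt(dx_ * dx_ + dy_ * dy_)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    f = gaussian_probe(pts, theta_star, sigma2).reshape(landscape.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(dist > 0, dx_ / dist, 0.0)
        uy = np.where(dist > 0, dy_ / dist, 0.0)
    return f * ux, f * uy


def modify_capacity(
    landscape: Landscape, region_weights: np.ndarray, fold: float
) -> Landscape:
    """Raise local capacity: u_s -> u_s * (1 + (fold - 1) * w_region).

    Lowering the local apoptosis term d = u / u_s by raising u_s is the
    mechanism behind the leukemic capacity increase; U and grad(U) are
    recomputed from the modified landscape.
    """
    if fold < 1.0:
        raise PerturbError("fold must be >= 1")
    w = np.asarray(region_weights, dtype=float)
    if np.any(w < -1e-9) or np.any(w > 1 + 1e-9):
        raise PerturbError("region weights must lie in [0, 1]")
    w = np.clip(w, 0.0, 1.0)
    if w.shape != landscape.shape:
        raise PerturbError("region weight shape mismatch")
    return landscape.with_us(landscape.us * (1.0 + (fold - 1.0) * w))


def block_differentiation_continuum(
    v: tuple[np.ndarray, np.ndarray],
    blocked_weight: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the advection component pointing into a blocked cluster.

    Wherever V has a positive projection onto the gradient of the blocked
    cluster's weight field (i.e. points up into the cluster), that
    projection is subtracted; elsewhere V is untouched.
    """
    gx = np.gradient(blocked_weight, axis=0)
    gy = np.gradient(blocked_weight, axis=1)
    norm2 = gx * gx + gy * gy
    dot = v[0] * gx + v[1] * gy
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where((dot > 0) & (norm2 > 0), dot / norm2, 0.0)
    return v[0] - coef * gx, v[1] - coef * gy


def block_differentiation_graph(graph, blocked_targets: list[str]) -> set[int]:
    """Indices of edges entering blocked nodes (their V is clamped <= 0)."""
    labels = set(graph.node_labels)
    unknown = [t for t in blocked_targets if t not in labels]
    if unknown:
        raise PerturbError(f"unknown blocked targets: {unknown}")
    blocked = {k for k, (_, b, _, _) in enumerate(graph.edges)
               if b in blocked_targets}
    for t in blocked_targets:
        incident = set(graph.in_edges(t)) | set(graph.out_edges(t))
        if incident and incident <= blocked:
            warnings.warn(f"blocking all edges of node {t!r} isolates it",
                          stacklevel=2)
    return blocked


def lowered_death_cap(
    landscape: Landscape, theta_star, sigma2: float, fold: float
) -> np.ndarray:
    """Death-cap grid lowered along a Gaussian profile around theta*.

    d_bar(theta) = 1 - w(theta) (1 - 1/fold) with w the unit-peak Gaussian
    at theta*: at theta* the apoptosis cap is 1/fold (cells keep
    proliferating at rate r (1 - 1/fold) no matter how crowded), far away
    it stays 1.  Lowering the local death term is the capacity-increase
    mechanism; fold = 1 is the identity.
    """
    if fold < 1.0:
        raise PerturbError("fold must be >= 1")
    gx, gy = landscape.mesh()
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    f = gaussian_probe(pts, theta_star, sigma2).reshape(landscape.shape)
    w = f / f.max()
    return 1.0 - w * (1.0 - 1.0 / fold)


def boost_proliferation(
    landscape: Landscape, r_aml: float, theta_star, sigma2: float
) -> np.ndarray:
    """Over-proliferation boost grid r_aml * f_theta*(theta).

    Added to the growth rate, the reaction becomes
    R(theta, u) + r_aml * f_theta*(theta) * u.
    """
    if r_aml < 0:
        raise PerturbError("r_aml must be non-negative")
    gx, gy = landscape.mesh()
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    f = gaussian_probe(pts, theta_star, sigma2).reshape(landscape.shape)
    return r_aml * f
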