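"""Cell-number quantification and gene-state correlation screens.

Total and per-type cell numbers are integrals of the density: on the grid
weighted by per-cluster KDE-ratio weight fields w_k (which sum to one
pointwise), on the graph by assigning each edge sample to its closest
node.  Correlation screens score every gene against a Gaussian probe
around a target state theta*, against a reduced component, or against a
direction vector — the tools used to interpret novel cell states that sit
away from the annotated clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .abstraction import CellClustering
from .graphpde import GraphMesh, GraphState, graph_mass, node_masses
from .io import ExpressionMatrix
from .landscape import Landscape, _gaussian_kde_grid, grid_quadrature


class QuantifyError(ValueError):
    pass


@dataclass
class TypeWeights:
    """Per-cluster weight fields w_k(theta) with sum_k w_k = 1 pointwise."""

    labels: list[str]
    w: np.ndarray                     # (K, M1, M2)

    def __post_init__(self) -> None:
        if np.any(self.w < 0):
            raise QuantifyError("weights must be non-negative")
        total = self.w.sum(axis=0)
        if np.max(np.abs(total - 1.0)) > 1e-10:
            raise QuantifyError("weights must sum to 1 pointwise")

    def field(self, label: str) -> np.ndarray:
        return self.w[self.labels.index(label)]

    def combined(self, labels) -> np.ndarray:
        return sum(self.field(lab) for lab in labels)


def type_weights(
    coords: np.ndarray, clustering: CellClustering, landscape: Landscape,
    h: float | None = None,
) -> TypeWeights:
    """w_k = KDE of cluster k's cells / sum_j KDE of cluster j's cells.

    A tiny floor is applied before normalization so the weights are
    defined (and sum to one) even far from every cluster.
    """
    coords = np.asarray(coords, dtype=float)
    if h is None:
        h = landscape.h
    labels = clustering.cluster_labels
    if len(labels) < 2:
        raise QuantifyError("need at least 2 clusters")
    dens = []
    for lab in labels:
        mask = np.array([x == lab for x in clustering.labels])
        if mask.sum() < 2:
            raise QuantifyError(f"cluster {lab!r} has fewer than 2 cells")
        dens.append(_gaussian_kde_grid(coords[mask], landscape.x,
                                       landscape.y, h))
    dens = np.stack(dens)
    dens = np.maximum(dens, 1e-300)
    return TypeWeights(labels, dens / dens.sum(axis=0, keepdims=True))


def total_mass_grid(u: np.ndarray, landscape: Landscape) -> float:
    """Trapezoid quadrature of the continuum density."""
    return grid_quadrature(u, landscape)


def total_mass_graph(state: GraphState, mesh: GraphMesh) -> float:
    return graph_mass(state, mesh)


def mass_by_type_grid(
    u: np.ndarray, landscape: Landscape, weights: TypeWeights
) -> dict[str, float]:
    """Per-type masses; sums to the total exactly (same quadrature)."""
    return {lab: grid_quadrature(u * weights.field(lab), landscape)
            for lab in weights.labels}


def mass_by_type_graph(state: GraphState, mesh: GraphMesh) -> dict[str, float]:
    """Per-node-type masses by half-edge counting."""
    return node_masses(state, mesh)


def gaussian_probe(
    coords: np.ndarray, theta_star, sigma2: float
) -> np.ndarray:
    """f_theta*(theta) = 1/(2 pi sigma^2) exp(-||theta - theta*||^2 / (2 sigma^2))."""
    if sigma2 <= 0:
        raise QuantifyError("sigma2 must be positive")
    theta_star = np.asarray(theta_star, dtype=float)
    d2 = ((np.atleast_2d(coords) - theta_star) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma2)) / (2.0 * np.pi * sigma2)


def correlation_screen(
    E_log: ExpressionMatrix,
    coords: np.ndarray,
    probe: tuple | None = None,
    direction: np.ndarray | None = None,
    component: int | None = None,
    subdomain: tuple[tuple[float, float], ...] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-gene correlation scores against a probe, component or direction.

    Exactly one of ``probe`` ((theta*, sigma2) for r_{f,j}), ``component``
    (0-based index k for r_{k,j}) or ``direction`` (vector v for
    r_{v,j} = sum_k v_k r_{k,j}) must be given.  ``subdomain`` restricts
    the screen to cells inside an axis-aligned box ((lo1, hi1), (lo2,
    hi2), ...); genes with zero variance get NaN (undefined), and the
    result is sorted by |score| with a ``rank`` column.
    """
    chosen = sum(x is not None for x in (probe, direction, component))
    if chosen != 1:
        raise QuantifyError("give exactly one of probe, direction, component")
    if method not in ("pearson", "spearman"):
        raise QuantifyError(f"unknown correlation method {method!r}")
    coords = np.asarray(coords, dtype=float)
    genes = np.asarray(E_log.values, dtype=float)
    if subdomain is not None:
        mask = np.ones(len(coords), dtype=bool)
        for axis, (lo, hi) in enumerate(subdomain):
            mask &= (coords[:, axis] >= lo) & (coords[:, axis] <= hi)
        if mask.sum() < 3:
            raise QuantifyError("subdomain selects fewer than 3 cells")
        coords, genes = coords[mask], genes[mask]
    if len(coords) < 3:
        raise QuantifyError("need at least 3 cells")

    if method == "spearman":
        genes = rankdata(genes, axis=0)
        coords = rankdata(coords, axis=0)

    def corr_against(target: np.ndarray) -> np.ndarray:
        t = target - target.mean()
        g = genes - genes.mean(axis=0)
        t_norm = np.sqrt((t * t).sum())
        g_norm = np.sqrt((g * g).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (g * t[:, None]).sum(axis=0) / (g_norm * t_norm)
        r[g_norm == 0] = np.nan
        if t_norm == 0:
            r[:] = np.nan
        return r

    if probe is not None:
        theta_star, sigma2 = probe
        target = gaussian_probe(coords, theta_star, sigma2)
        if method == "spearman":
            target = rankdata(target)
        scores = corr_against(target)
    elif component is not None:
        scores = corr_against(coords[:, component])
    else:
        direction = np.asarray(direction, dtype=float)
        per_comp = np.stack([corr_against(coords[:, k])
                             for k in range(coords.shape[1])])
        scores = direction @ per_comp

    frame = pd.DataFrame({"gene_id": E_log.gene_ids, "score": scores})
    frame["rank"] = (-frame["score"].abs()).rank(method="first")
    return frame.sort_values("rank").reset_index(drop=True)


def rescale_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max rescale of a score vector into [-1, 1] (a display choice)."""
    finite = scores[np.isfinite(scores)]
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        return np.zeros_like(scores)
    return -1.0 + 2.0 * (scores - lo) / (hi - lo)
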