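"""Diffusion-map reduced component space and its out-of-sample extension.

The reduced space operator P maps a G-dimensional expression vector to a
point theta in an n-dimensional component space.  It is built from a
Gaussian-kernel Markov operator over the (log-scaled) cells with alpha = 1
density normalization, which makes the embedding robust to non-uniform
sampling density.  New cells — e.g. perturbed copies of training cells —
are projected with the Nystrom extension, so the displacement P(g_tilde) -
P(g) of a perturbation can be read directly in component space.

Each retained component is affinely rescaled to [0, 1]; anchor coordinates
such as a target state theta* are therefore expressed on that common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix


class ReductionError(ValueError):
    pass


@dataclass
class ReducedSpace:
    """A fitted diffusion-map embedding plus what projection needs.

    ``embedding`` holds the rescaled per-cell coordinates in [0, 1]^n.
    ``psi`` are the Markov right eigenvectors, ``q`` the raw kernel row
    sums; together with ``epsilon`` and the affine rescale parameters they
    reproduce any training coordinate through the Nystrom formula to
    machine precision.
    """

    embedding: np.ndarray          # (N, n) rescaled coordinates
    eigenvalues: np.ndarray        # (n,) strictly decreasing, in (0, 1]
    psi: np.ndarray                # (N, n) Markov right eigenvectors
    epsilon: float                 # Gaussian kernel bandwidth (squared scale)
    train_points: np.ndarray       # (N, G) log-scale training expression
    gene_ids: list[str]
    q: np.ndarray                  # (N,) raw kernel row sums
    signs: np.ndarray              # (n,) +-1 per component
    raw_min: np.ndarray            # (n,) affine rescale offsets
    raw_max: np.ndarray

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]


def _median_knn_epsilon(x: np.ndarray, k: int) -> float:
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(x)))
    nn.fit(x)
    dists, _ = nn.kneighbors(x)
    return float(np.median(dists[:, 1:] ** 2))


def diffusion_map(
    E_log: ExpressionMatrix,
    n_components: int = 2,
    epsilon: float | None = None,
    knn_k: int = 15,
    root_cells: np.ndarray | None = None,
) -> ReducedSpace:
    """Fit the diffusion-map reduced space on a log-scale matrix.

    Pipeline: pairwise squared Euclidean distances; Gaussian kernel
    W = exp(-d^2 / (2 eps)); alpha = 1 density normalization
    W' = W / (q q^T) with q the row sums of W; Markov normalization; then
    the eigen-decomposition of the symmetrized operator.  The constant
    eigenvector is skipped and each retained component lambda_l * psi_l is
    affinely rescaled into [0, 1].

    ``epsilon`` defaults to the median squared distance to the ``knn_k``
    nearest neighbours.  ``root_cells`` (boolean mask or index array) fixes
    the arbitrary sign of each eigenvector so that root cells sit at the
    low end of every component; without it the sign is fixed by making the
    largest-magnitude entry positive.
    """
    if not E_log.log_scale:
        raise ReductionError("diffusion_map expects a log-scale matrix")
    x = np.asarray(E_log.values, dtype=float)
    n = x.shape[0]
    if n < n_components + 2:
        raise ReductionError("need at least n_components + 2 cells")
    if epsilon is None:
        epsilon = _median_knn_epsilon(x, knn_k)
    if epsilon <= 0:
        raise ReductionError("kernel bandwidth must be positive")

    d2 = cdist(x, x, metric="sqeuclidean")
    w = np.exp(-d2 / (2.0 * epsilon))
    q = w.sum(axis=1)
    off_diag = q - 1.0  # the self-kernel contributes exactly 1 to each row
    if np.any(off_diag < 1e-300):
        raise ReductionError(
            "kernel graph has isolated cells; increase the bandwidth epsilon"
        )
    w1 = w / np.outer(q, q)
    d1 = w1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    sym = w1 * np.outer(inv_sqrt, inv_sqrt)
    sym = 0.5 * (sym + sym.T)  # guard against round-off asymmetry

    k = n_components + 1
    if n <= 400:
        evals, evecs = eigh(sym, subset_by_index=(n - k, n - 1))
        evals, evecs = evals[::-1], evecs[:, ::-1]
    else:
        evals, evecs = eigsh(sym, k=k, which="LA")
        order = np.argsort(-evals)
        evals, evecs = evals[order], evecs[:, order]

    lam = evals[1:]
    if np.any(lam <= 0) or np.any(lam > 1 + 1e-10) or np.any(np.diff(lam) >= 0):
        raise ReductionError(
            "spectrum not strictly decreasing in (0, 1]; the kernel graph "
            "may be disconnected — increase the bandwidth epsilon"
        )
    lam = np.minimum(lam, 1.0)
    psi = evecs[:, 1:] * inv_sqrt[:, None]
    raw = psi * lam[None, :]

    signs = np.ones(n_components)
    for l in range(n_components):
        if root_cells is not None:
            # root compartment anchored at the low end of each component
            if raw[root_cells, l].mean() > raw[:, l].mean():
                signs[l] = -1.0
        elif raw[np.argmax(np.abs(raw[:, l])), l] < 0:
            signs[l] = -1.0
    raw = raw * signs[None, :]
    psi = psi * signs[None, :]

    raw_min, raw_max = raw.min(axis=0), raw.max(axis=0)
    span = raw_max - raw_min
    if np.any(span <= 0):
        raise ReductionError("degenerate component with zero span")
    embedding = (raw - raw_min) / span

    return ReducedSpace(embedding, lam, psi, float(epsilon), x,
                        list(E_log.gene_ids), q, signs, raw_min, raw_max)


def nystrom_project(
    space: ReducedSpace, new_cells: ExpressionMatrix | np.ndarray
) -> np.ndarray:
    """Project new (log-scale) cells into a fitted reduced space.

    The kernel row to the training points goes through the same density
    and Markov normalization as in fitting; the raw Nystrom coordinate
    p_row . psi_l equals the eigenvalue-scaled training coordinate for a
    training cell, so training cells reproduce their stored embedding
    exactly.  The stored affine rescale is applied last.
    """
    if isinstance(new_cells, ExpressionMatrix):
        if not new_cells.log_scale:
            raise ReductionError("nystrom_project expects log-scale values")
        if new_cells.gene_ids != space.gene_ids:
            missing = sorted(set(space.gene_ids) - set(new_cells.gene_ids))
            raise ReductionError(
                f"gene set mismatch; missing or reordered genes "
                f"(first missing: {missing[:5]})"
            )
        x = new_cells.values
    else:
        x = np.atleast_2d(np.asarray(new_cells, dtype=float))
        if x.shape[1] != space.train_points.shape[1]:
            raise ReductionError("gene dimension mismatch")

    k_row = np.exp(-cdist(x, space.train_points, "sqeuclidean")
                   / (2.0 * space.epsilon))
    q_new = k_row.sum(axis=1)
    w1 = k_row / np.outer(q_new, space.q)
    p_row = w1 / w1.sum(axis=1, keepdims=True)
    # space.psi already carries the sign convention
    raw = p_row @ space.psi
    return (raw - space.raw_min) / (space.raw_max - space.raw_min)


def displacement_field(
    space: ReducedSpace,
    E_log: ExpressionMatrix,
    E_perturbed_log: ExpressionMatrix,
    subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell displacement vectors P(g_tilde) - P(g) and their mean.

    ``subset`` selects cells (boolean mask or index array) whose
    displacement is computed; the two matrices must be aligned cell by
    cell.
    """
    if E_log.cell_ids != E_perturbed_log.cell_ids:
        raise ReductionError("matrices must be aligned cell-by-cell")
    idx = np.arange(E_log.n_cells)
    if subset is not None:
        idx = idx[subset] if np.asarray(subset).dtype == bool else np.asarray(subset)
    if len(idx) == 0:
        raise ReductionError("empty cell subset")
    base = nystrom_project(space, E_log.values[idx])
    moved = nystrom_project(space, E_perturbed_log.values[idx])
    vectors = moved - base
    return vectors, vectors.mean(axis=0)
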