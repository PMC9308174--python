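"""Synthetic hematopoiesis-like scRNA-seq with a known lineage tree.

The generator emulates the geometry the downstream models need: a branching
lineage tree (stem cells at the root, matured types at the leaves), per-cell
latent pseudotime, branch-specific gene programs, and negative-binomial count
noise with dropout.  Every quantity is reproducible from the seed, and the
ground truth (branch label, pseudotime, gene programs) is returned alongside
the counts so downstream stages can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix


@dataclass
class LineageTree:
    """A rooted differentiation hierarchy with homeostatic mass fractions.

    ``fractions`` give the share of the homeostatic population sitting in
    each node's compartment; they must sum to one.
    """

    nodes: list[str]
    root: str
    edges: list[tuple[str, str]]
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        nodes = set(self.nodes)
        if self.root not in nodes:
            raise ValueError(f"root {self.root!r} not among nodes")
        parents: dict[str, str] = {}
        for a, b in self.edges:
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if b in parents:
                raise ValueError(f"node {b!r} has two parents")
            parents[b] = a
        if set(parents) != nodes - {self.root}:
            raise ValueError("tree must be connected with a single root")
        # acyclicity: walking up from every node must reach the root
        for n in self.nodes:
            seen = set()
            while n != self.root:
                if n in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(n)
                n = parents[n]
        if set(self.fractions) != nodes:
            raise ValueError("fractions must be keyed by every node")
        total = float(sum(self.fractions.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions sum to {total}, not 1")
        self._parents = parents

    def parent(self, node: str) -> str | None:
        return self._parents.get(node)

    def path_from_root(self, node: str) -> list[str]:
        path = [node]
        while path[-1] != self.root:
            path.append(self._parents[path[-1]])
        return path[::-1]

    def depth(self, node: str) -> int:
        return len(self.path_from_root(node)) - 1

    @property
    def max_depth(self) -> int:
        return max(self.depth(n) for n in self.nodes)

    @property
    def leaves(self) -> list[str]:
        heads = {a for a, _ in self.edges}
        return [n for n in self.nodes if n not in heads]


def default_hematopoiesis_tree() -> LineageTree:
    """The default 9-node hematopoietic hierarchy.

    HSC -> MPP -> {Lymph, CMP -> {MEP -> Ery, GMP -> {Neu, Mo}}}.  The
    stem compartment holds ~10% of homeostatic mass and the leukemia-prone
    MEP + Ery region holds 10% jointly, so a 10-fold capacity increase in
    that region pushes the leukemic share of the population past one half.
    """
    nodes = ["HSC", "MPP", "Lymph", "CMP", "MEP", "GMP", "Ery", "Neu", "Mo"]
    edges = [("HSC", "MPP"), ("MPP", "Lymph"), ("MPP", "CMP"),
             ("CMP", "MEP"), ("CMP", "GMP"), ("MEP", "Ery"),
             ("GMP", "Neu"), ("GMP", "Mo")]
    fractions = {"HSC": 0.10, "MPP": 0.14, "Lymph": 0.12, "CMP": 0.15,
                 "MEP": 0.05, "GMP": 0.15, "Ery": 0.05, "Neu": 0.12,
                 "Mo": 0.12}
    return LineageTree(nodes, "HSC", edges, fractions)


@dataclass
class GeneProgram:
    """How one gene's mean expression depends on (branch, pseudotime)."""

    kind: str                 # "housekeeping" | "stemness" | "branch"
    base: float               # baseline mean count
    amplitude: float          # program amplitude on top of base
    node: str | None = None   # activating node for branch programs
    midpoint: float = 0.5     # sigmoid activation pseudotime
    width: float = 0.08       # sigmoid width


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic expression matrix."""

    branch: list[str]
    pseudotime: np.ndarray
    tree: LineageTree
    seed: int
    programs: list[GeneProgram] = field(default_factory=list)
    dispersion: float = 0.0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if len(self.branch) != self.pseudotime.size:
            raise ValueError("one branch label per cell required")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def program_means(truth: SyntheticTruth) -> np.ndarray:
    """Recompute the (cells x genes) mean matrix implied by the programs."""
    tree = truth.tree
    t = truth.pseudotime
    n_cells = t.size
    means = np.empty((n_cells, len(truth.programs)))
    # ancestry mask: cell on branch b is "downstream of" node v if v lies on
    # the root -> b path
    paths = {n: set(tree.path_from_root(n)) for n in tree.nodes}
    for j, prog in enumerate(truth.programs):
        if prog.kind == "housekeeping":
            means[:, j] = prog.base
        elif prog.kind == "stemness":
            means[:, j] = prog.base + prog.amplitude * (1.0 - t)
        else:  # branch-specific sigmoid activation along pseudotime
            on = np.fromiter((prog.node in paths[b] for b in truth.branch),
                             dtype=bool, count=n_cells)
            act = _sigmoid((t - prog.midpoint) / prog.width)
            means[:, j] = prog.base + prog.amplitude * act * on
    return means


def simulate_expression(
    tree: LineageTree,
    n_cells: int = 3000,
    n_genes: int = 200,
    dispersion: float = 0.3,
    dropout: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a hematopoiesis-like count matrix with known ground truth.

    Cells are allotted to tree nodes according to the homeostatic fractions;
    each cell gets a latent pseudotime from its node's depth band.  Genes
    belong to one of three programs — housekeeping (constant), stemness
    (declining with pseudotime) or branch-specific (sigmoid activation along
    the branch) — and counts are negative-binomial around the program mean
    (variance mu + dispersion * mu^2) with Bernoulli dropout.
    """
    if n_cells < 10 * len(tree.nodes):
        raise ValueError("need at least 10 cells per tree node")
    if n_genes < 20:
        raise ValueError("need at least 20 genes")
    if dispersion < 0 or not (0.0 <= dropout < 1.0):
        raise ValueError("dispersion must be >= 0 and dropout in [0, 1)")
    rng = np.random.default_rng(seed)

    # deterministic allotment of cells to nodes (largest remainder)
    fracs = np.array([tree.fractions[n] for n in tree.nodes])
    counts = np.floor(fracs * n_cells).astype(int)
    remainder = n_cells - counts.sum()
    order = np.argsort(-(fracs * n_cells - counts))
    counts[order[:remainder]] += 1

    branch: list[str] = []
    pseudotime = np.empty(n_cells)
    depth_span = tree.max_depth + 1
    pos = 0
    for node, c in zip(tree.nodes, counts):
        branch.extend([node] * c)
        d = tree.depth(node)
        pseudotime[pos:pos + c] = (d + rng.uniform(0, 1, c)) / depth_span
        pos += c

    # gene programs: ~20% housekeeping, ~20% stemness, rest branch-specific
    programs: list[GeneProgram] = []
    n_hk = max(2, n_genes // 5)
    n_stem = max(2, n_genes // 5)
    non_root = [n for n in tree.nodes if n != tree.root]
    for j in range(n_genes):
        base = float(rng.lognormal(mean=0.0, sigma=0.3))
        if j < n_hk:
            programs.append(GeneProgram("housekeeping", base=base * 5,
                                        amplitude=0.0))
        elif j < n_hk + n_stem:
            programs.append(GeneProgram("stemness", base=base,
                                        amplitude=float(rng.uniform(10, 30))))
        else:
            node = non_root[int(rng.integers(len(non_root)))]
            # activation centred inside the node's pseudotime band so the
            # program switches on continuously across the branch boundary
            mid = (tree.depth(node) + rng.uniform(0.3, 0.7)) / depth_span
            programs.append(GeneProgram(
                "branch", base=base,
                amplitude=float(rng.uniform(10, 30)), node=node,
                midpoint=float(np.clip(mid, 0.05, 0.95)),
                width=float(rng.uniform(0.06, 0.12))))

    truth = SyntheticTruth(branch, pseudotime, tree, seed, programs,
                           dispersion, dropout)
    mu = program_means(truth)
    if dispersion > 0:
        # NB with variance mu + dispersion * mu^2 via gamma-Poisson mixture
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
        values = rng.poisson(lam).astype(float)
    else:
        values = rng.poisson(mu).astype(float)
    if dropout > 0:
        values *= rng.random(values.shape) >= dropout

    gene_ids = [f"g{j:04d}" for j in range(n_genes)]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(values, gene_ids, cell_ids, labels=branch)
    return matrix, truth


def simulate_random_walk(
    nu: float, dt: float, T: float, n_walkers: int, seed: int = 0
) -> np.ndarray:
    """Isotropic 2-D random walks with per-axis step variance 2*nu*dt.

    Returns an array of shape (n_walkers, n_steps + 1, 2) starting at the
    origin; the continuum limit is Brownian motion with diffusivity nu, so
    the per-axis variance at time T is 2*nu*T.
    """
    if nu < 0 or dt <= 0 or T <= 0:
        raise ValueError("need nu >= 0, dt > 0, T > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    steps = rng.normal(0.0, np.sqrt(2.0 * nu * dt), (n_walkers, n_steps, 2))
    traj = np.zeros((n_walkers, n_steps + 1, 2))
    np.cumsum(steps, axis=1, out=traj[:, 1:, :])
    return traj


def write_truth(truth: SyntheticTruth, cell_ids: list[str], path) -> None:
    """Write the ground-truth TSV (cell_id, branch, pseudotime)."""
    import pandas as pd

    pd.DataFrame({"cell_id": cell_ids, "branch": truth.branch,
                  "pseudotime": truth.pseudotime}).to_csv(
        path, sep="\t", index=False)
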