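"""Cluster cells and abstract them into a directed metric graph.

Nodes of the graph are cell clusters positioned at their centroids in the
reduced component space; edges connect clusters whose cells are mutual
kNN neighbours more often than chance (the PAGA connectivity ratio), are
oriented away from a user-named root cluster, and carry their Euclidean
centroid distance as metric length.  Nodes are classified into initial
(no inflow), terminal (no outflow) and transient sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors


class GraphError(ValueError):
    pass


@dataclass
class CellClustering:
    labels: list[str]                      # one per cell
    centroids: dict[str, np.ndarray]       # label -> reduced-space centroid
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.centroids) < 2:
            raise GraphError("need at least 2 clusters")
        for lab, c in self.centroids.items():
            if not np.all(np.isfinite(c)):
                raise GraphError(f"non-finite centroid for cluster {lab!r}")

    @property
    def cluster_labels(self) -> list[str]:
        return sorted(self.centroids)


def cluster_cells(coords: np.ndarray, k: int, seed: int = 0) -> CellClustering:
    """k-means clustering (k-means++ start, fixed seed) in reduced space."""
    if k < 2:
        raise GraphError("k must be >= 2")
    coords = np.asarray(coords, dtype=float)
    last_err = None
    for attempt in range(5):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=seed + attempt)
        assign = km.fit_predict(coords)
        sizes = np.bincount(assign, minlength=k)
        if np.all(sizes > 0):
            labels = [f"c{a}" for a in assign]
            return adopt_labels(labels, coords)
        last_err = GraphError(f"empty cluster after assignment (seed {seed + attempt})")
    raise last_err


def adopt_labels(labels, coords: np.ndarray) -> CellClustering:
    """Adopt externally supplied per-cell labels; centroids are label means."""
    labels = [str(x) for x in labels]
    coords = np.asarray(coords, dtype=float)
    if len(labels) != len(coords):
        raise GraphError("one label per cell required")
    centroids, counts = {}, {}
    for lab in sorted(set(labels)):
        mask = np.array([x == lab for x in labels])
        centroids[lab] = coords[mask].mean(axis=0)
        counts[lab] = int(mask.sum())
    return CellClustering(labels, centroids, counts)


def knn_edges(coords: np.ndarray, k: int = 15) -> set[tuple[int, int]]:
    """Symmetric kNN edge set over cells (unordered index pairs)."""
    coords = np.asarray(coords, dtype=float)
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(coords)))
    nn.fit(coords)
    _, idx = nn.kneighbors(coords)
    edges: set[tuple[int, int]] = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, j), max(i, j)))
    return edges


def connectivity_graph(
    edges: set[tuple[int, int]], clustering: CellClustering
) -> dict[tuple[str, str], float]:
    """PAGA-style observed/expected connectivity score per cluster pair.

    The expected inter-cluster edge count places the observed number of
    edges uniformly at random over all unordered cell pairs, so for pair
    (A, B) it is |edges| * n_A n_B / C(N, 2).
    """
    labels = clustering.labels
    n = len(labels)
    total_edges = len(edges)
    observed: dict[tuple[str, str], int] = {}
    for i, j in edges:
        a, b = sorted((labels[i], labels[j]))
        if a != b:
            observed[(a, b)] = observed.get((a, b), 0) + 1
    scores: dict[tuple[str, str], float] = {}
    clusters = clustering.cluster_labels
    n_pairs = n * (n - 1) / 2.0
    for ia, a in enumerate(clusters):
        for b in clusters[ia + 1:]:
            expected = total_edges * clustering.counts[a] * clustering.counts[b] / n_pairs
            obs = observed.get((a, b), 0)
            scores[(a, b)] = obs / expected if expected > 0 else 0.0
    return scores


@dataclass
class MetricGraph:
    """Directed cluster graph embedded in the reduced space.

    ``edges`` are (a, b, length, score) tuples oriented root -> leaf; node
    classes are recomputed from edge directions on demand.
    """

    node_labels: list[str]
    positions: dict[str, np.ndarray]
    edges: list[tuple[str, str, float, float]]
    root: str

    def __post_init__(self) -> None:
        nodes = set(self.node_labels)
        for a, b, length, _ in self.edges:
            if a not in nodes or b not in nodes:
                raise GraphError(f"edge ({a}, {b}) references unknown node")
            if length <= 0:
                raise GraphError(f"edge ({a}, {b}) has non-positive length")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def node_classes(self) -> dict[str, set[str]]:
        """Classify nodes: N_I no inflow, N_F no outflow, N_T the rest."""
        heads = {b for _, b, _, _ in self.edges}
        tails = {a for a, _, _, _ in self.edges}
        n_i = {n for n in self.node_labels if n not in heads}
        n_f = {n for n in self.node_labels if n not in tails}
        n_t = set(self.node_labels) - n_i - n_f
        return {"N_I": n_i, "N_T": n_t, "N_F": n_f}

    def out_edges(self, node: str) -> list[int]:
        return [k for k, (a, _, _, _) in enumerate(self.edges) if a == node]

    def in_edges(self, node: str) -> list[int]:
        return [k for k, (_, b, _, _) in enumerate(self.edges) if b == node]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "root": self.root,
            "nodes": [{"id": n, "position": self.positions[n].tolist()}
                      for n in self.node_labels],
            "edges": [{"a": a, "b": b, "length": length, "score": score}
                      for a, b, length, score in self.edges],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetricGraph":
        doc = json.loads(Path(path).read_text())
        return cls(
            node_labels=[n["id"] for n in doc["nodes"]],
            positions={n["id"]: np.asarray(n["position"], dtype=float)
                       for n in doc["nodes"]},
            edges=[(e["a"], e["b"], float(e["length"]), float(e["score"]))
                   for e in doc["edges"]],
            root=doc["root"],
        )

    def to_graphml(self, path: str | Path) -> None:
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
            '<key id="length" for="edge" attr.name="length" attr.type="double"/>',
            '<key id="score" for="edge" attr.name="score" attr.type="double"/>',
            '<graph edgedefault="directed">',
        ]
        lines += [f'<node id="{n}"/>' for n in self.node_labels]
        for a, b, length, score in self.edges:
            lines.append(
                f'<edge source="{a}" target="{b}">'
                f'<data key="length">{length}</data>'
                f'<data key="score">{score}</data></edge>'
            )
        lines += ["</graph>", "</graphml>"]
        Path(path).write_text("\n".join(lines))


def _max_score_spanning_tree(
    nodes: list[str], edges: list[tuple[str, str, float]]
) -> list[tuple[str, str, float]]:
    """Kruskal on descending score."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kept = []
    for a, b, score in sorted(edges, key=lambda e: -e[2]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            kept.append((a, b, score))
    return kept


def build_metric_graph(
    clustering: CellClustering,
    connectivity: dict[tuple[str, str], float],
    root_label: str,
    threshold: float = 0.3,
    keep_cycles: bool = False,
) -> MetricGraph:
    """Threshold connectivity, orient away from the root, compute lengths.

    Edges with score > threshold are kept; if the undirected result has
    cycles and ``keep_cycles`` is false, the maximum-score spanning tree is
    retained.  Edges are then oriented by breadth-first order from the
    root, and lengths are Euclidean centroid distances.
    """
    clusters = clustering.cluster_labels
    if root_label not in clusters:
        raise GraphError(f"root cluster {root_label!r} not found")
    undirected = [(a, b, s) for (a, b), s in connectivity.items()
                  if s > threshold]

    # connectivity check
    parent = {n: n for n in clusters}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in undirected:
        parent[find(a)] = find(b)
    if len({find(n) for n in clusters}) != 1:
        raise GraphError(
            "cluster graph is disconnected at this threshold; lower it"
        )

    if not keep_cycles and len(undirected) > len(clusters) - 1:
        undirected = _max_score_spanning_tree(clusters, undirected)

    # BFS orientation away from the root
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in clusters}
    for a, b, s in undirected:
        adj[a].append((b, s))
        adj[b].append((a, s))
    visited = {root_label}
    queue = [root_label]
    directed: list[tuple[str, str, float, float]] = []
    while queue:
        node = queue.pop(0)
        for nbr, score in sorted(adj[node]):
            if nbr not in visited:
                visited.add(nbr)
                length = float(np.linalg.norm(
                    clustering.centroids[node] - clustering.centroids[nbr]))
                directed.append((node, nbr, length, score))
                queue.append(nbr)
            elif keep_cycles and (nbr, node) not in {
                    (a, b) for a, b, _, _ in directed} and (node, nbr) not in {
                    (a, b) for a, b, _, _ in directed}:
                length = float(np.linalg.norm(
                    clustering.centroids[node] - clustering.centroids[nbr]))
                directed.append((node, nbr, length, score))

    return MetricGraph(clusters, dict(clustering.centroids), directed,
                       root_label)
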