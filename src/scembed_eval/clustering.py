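"""Neighbor-graph construction, unified clustering, and partition agreement.

Partition-agreement metrics (ARI, NMI, HOM, COM, FMI) are computed from the
contingency table directly; entropies use natural log (the base cancels in
every ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from sklearn.neighbors import NearestNeighbors

from scembed_eval.datamodel import EmbeddingSet


@dataclass
class NeighborGraph:
    """Exact k-nearest-neighbor lists (self excluded) with edge distances."""

    neighbors: np.ndarray  # (n, k) int
    distances: np.ndarray  # (n, k) float
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=np.intp)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.neighbors.shape != self.distances.shape:
            raise ValueError("neighbor/distance shape mismatch")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if np.any(self.neighbors == np.arange(self.n_nodes)[:, None]):
            raise ValueError("self-loops are not allowed")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")

    @property
    def n_nodes(self) -> int:
        return self.neighbors.shape[0]

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def edge_set(self, symmetrize: bool = True) -> set[tuple[int, int]]:
        """Undirected edge set; with ``symmetrize`` an edge needs one direction."""
        edges = set()
        for i in range(self.n_nodes):
            for j in self.neighbors[i]:
                edges.add((min(i, int(j)), max(i, int(j))))
        return edges


@dataclass
class Partition:
    """A full labeling of cells into clusters."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def levels(self) -> list:
        return sorted(set(self.labels.tolist()), key=str)

    def __len__(self) -> int:
        return len(self.labels)


def build_neighbor_graph(
    emb: EmbeddingSet, k: int, metric: str = "euclidean"
) -> NeighborGraph:
    """Exact kNN graph; ties broken toward lower cell-id index."""
    n = emb.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    nn = NearestNeighbors(n_neighbors=min(n, k + 2), metric=metric).fit(emb.matrix)
    dist, idx = nn.kneighbors(emb.matrix)
    # enforce deterministic ordering: by (distance, index), self removed
    neighbors = np.empty((n, k), dtype=np.intp)
    distances = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        order = np.lexsort((idx[i], dist[i]))
        cand = [(dist[i][o], idx[i][o]) for o in order if idx[i][o] != i]
        if len(cand) < k:  # heavy duplicate ties: fall back to full scan
            d_all = np.linalg.norm(emb.matrix - emb.matrix[i], axis=1)
            order_all = np.lexsort((np.arange(n), d_all))
            cand = [(d_all[j], j) for j in order_all if j != i]
        distances[i] = [c[0] for c in cand[:k]]
        neighbors[i] = [c[1] for c in cand[:k]]
    return NeighborGraph(neighbors, distances, symmetric=False)


def _to_igraph(graph: NeighborGraph):
    import igraph as ig

    edges = sorted(graph.edge_set())
    return ig.Graph(n=graph.n_nodes, edges=edges, directed=False)


def unified_clustering(
    graph: NeighborGraph, n_target: int, seed: int = 0, max_iter: int = 25
) -> Partition:
    """Leiden community detection with resolution bisected to hit ``n_target``.

    Disconnected graphs are clustered jointly. Returns the labeling whose
    cluster count is closest to ``n_target`` among all resolutions visited.
    """
    import leidenalg

    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if n_target == 1:
        return Partition(np.zeros(graph.n_nodes, dtype=object))
    g = _to_igraph(graph)

    def cluster_at(res: float) -> np.ndarray:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        return np.asarray(part.membership)

    lo, hi = 0.0, 1.0
    best = None
    # grow hi until the cluster count reaches n_target (or give up)
    for _ in range(max_iter):
        labels = cluster_at(hi)
        n_found = len(set(labels))
        if best is None or abs(n_found - n_target) < best[0]:
            best = (abs(n_found - n_target), labels)
        if n_found >= n_target:
            break
        lo, hi = hi, hi * 2
    for _ in range(max_iter):
        if best[0] == 0:
            break
        mid = (lo + hi) / 2
        labels = cluster_at(mid)
        n_found = len(set(labels))
        if abs(n_found - n_target) < best[0]:
            best = (abs(n_found - n_target), labels)
        if n_found < n_target:
            lo = mid
        else:
            hi = mid
    return Partition(np.asarray([f"c{v}" for v in best[1]], dtype=object))


# ---------------------------------------------------------------------------
# Partition agreement
# ---------------------------------------------------------------------------


def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    u_levels = {lvl: i for i, lvl in enumerate(sorted(set(u.tolist()), key=str))}
    v_levels = {lvl: i for i, lvl in enumerate(sorted(set(v.tolist()), key=str))}
    table = np.zeros((len(u_levels), len(v_levels)), dtype=np.int64)
    for a, b in zip(u, v):
        table[u_levels[a], v_levels[b]] += 1
    return table


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def partition_agreement(U: Partition, V: Partition) -> dict[str, float]:
    """ARI, NMI, HOM, COM and FMI between two partitions of the same cells."""
    u, v = np.asarray(U.labels, dtype=object), np.asarray(V.labels, dtype=object)
    if len(u) != len(v):
        raise ValueError("partitions must label the same cells")
    n = len(u)
    table = _contingency(u, v)
    a = table.sum(axis=1)
    b = table.sum(axis=0)

    # --- ARI (pair counts) ---
    sum_ij = comb(table, 2).sum()
    sum_a = comb(a, 2).sum()
    sum_b = comb(b, 2).sum()
    n_pairs = comb(n, 2)
    expected = sum_a * sum_b / n_pairs if n_pairs > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        ari = 1.0  # both partitions trivial (all-singletons or single cluster)
    else:
        ari = float((sum_ij - expected) / (max_index - expected))

    # --- entropies and mutual information (natural log) ---
    h_u, h_v = _entropy(a), _entropy(b)
    p = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        outer = np.outer(a, b) / (n * n)
        terms = np.where(p > 0, p * np.log(p / outer), 0.0)
    mi = float(terms.sum())

    if h_u == 0.0 and h_v == 0.0:
        nmi = 1.0  # both constant: perfect (degenerate) agreement
    elif h_u == 0.0 or h_v == 0.0:
        nmi = 0.0
    else:
        nmi = float(2.0 * mi / (h_u + h_v))

    # H(U|V) = H(U) - I ; H(V|U) = H(V) - I
    hom = 1.0 if h_u == 0.0 else float(1.0 - (h_u - mi) / h_u)
    com = 1.0 if h_v == 0.0 else float(1.0 - (h_v - mi) / h_v)

    # --- FMI ---
    tp = sum_ij
    fp = sum_b - sum_ij  # same predicted cluster, different truth
    fn = sum_a - sum_ij  # same truth, different predicted cluster
    denom = np.sqrt((tp + fp) * (tp + fn))
    fmi = float(tp / denom) if denom > 0 else 0.0

    return {"ari": ari, "nmi": nmi, "hom": hom, "com": com, "fmi": fmi}
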