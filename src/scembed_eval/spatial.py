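"""Spatial-domain metrics on coordinates, labels and counts.

Moran's I and Geary's C are computed per marker gene over a binary symmetric
kNN spatial weight graph; CHAOS and PAS score label coherence in physical
space. Direction transforms (1 - C, 1 - CHAOS, 1 - PAS) are applied here so
all reported values are higher-is-better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.stats import mannwhitneyu
from sklearn.neighbors import NearestNeighbors

from scembed_eval.datamodel import CountMatrix


@dataclass
class SpatialConfig:
    k_spatial: int = 6
    markers_per_domain: int = 10
    target_sum: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_spatial < 1:
            raise ValueError("k_spatial must be >= 1")


def lognormalize(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalization to ``target_sum`` followed by log1p."""
    counts = np.asarray(counts, dtype=np.float64)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * target_sum)


def spatial_weight_graph(coords: np.ndarray, k: int) -> csr_matrix:
    """Binary symmetric kNN adjacency over spatial coordinates (self excluded)."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows, cols = [], []
    for i in range(n):
        for j in idx[i]:
            if j != i:
                rows.append(i)
                cols.append(int(j))
    w = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    w = w.maximum(w.T)  # symmetrize, keep binary
    return w


def morans_i(x: np.ndarray, w: csr_matrix) -> float:
    """Moran's I of values ``x`` over a spatial weight matrix."""
    x = np.asarray(x, dtype=np.float64)
    z = x - x.mean()
    denom = float(np.sum(z**2))
    if denom == 0:
        return float("nan")
    W = float(w.sum())
    num = float(z @ (w @ z))
    return len(x) / W * num / denom


def gearys_c(x: np.ndarray, w: csr_matrix) -> float:
    """Geary's C of values ``x`` over a spatial weight matrix."""
    x = np.asarray(x, dtype=np.float64)
    z = x - x.mean()
    denom = float(np.sum(z**2))
    if denom == 0:
        return float("nan")
    W = float(w.sum())
    coo = w.tocoo()
    num = float(np.sum(coo.data * (x[coo.row] - x[coo.col]) ** 2))
    return (len(x) - 1) / (2.0 * W) * num / denom


def rank_marker_genes(
    logexpr: np.ndarray, domains: np.ndarray, top_n: int
) -> list[int]:
    """One-vs-rest Wilcoxon rank-sum markers per domain; deduplicated union."""
    domains = np.asarray(domains, dtype=object)
    selected: list[int] = []
    for level in sorted(set(domains.tolist()), key=str):
        mask = domains == level
        if mask.sum() == 0 or (~mask).sum() == 0:
            continue
        inside, outside = logexpr[mask], logexpr[~mask]
        stats = np.full(logexpr.shape[1], -np.inf)
        for g in range(logexpr.shape[1]):
            if np.ptp(logexpr[:, g]) == 0:
                continue
            # one-sided: marker = elevated inside the domain
            stat, _ = mannwhitneyu(inside[:, g], outside[:, g], alternative="greater")
            stats[g] = stat
        order = np.argsort(-stats, kind="stable")
        selected.extend(int(g) for g in order[:top_n] if np.isfinite(stats[g]))
    # dedupe preserving order
    seen: set[int] = set()
    return [g for g in selected if not (g in seen or seen.add(g))]


def spatial_autocorrelation(
    counts: CountMatrix | np.ndarray,
    domains,
    coords: np.ndarray,
    cfg: SpatialConfig | None = None,
) -> dict[str, float]:
    """Median marker-gene Moran's I and transformed Geary score (1 - median C).

    Counts are library-normalized and log-transformed; markers are ranked
    one-vs-rest for each predicted domain. Genes constant over all spots are
    skipped with a warning.
    """
    cfg = cfg or SpatialConfig()
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    domains = np.asarray(domains, dtype=object)
    if len(set(domains.tolist())) < 2:
        raise ValueError("spatial autocorrelation requires >= 2 domains")
    logexpr = lognormalize(mat, cfg.target_sum)
    markers = rank_marker_genes(logexpr, domains, cfg.markers_per_domain)
    w = spatial_weight_graph(coords, cfg.k_spatial)
    morans, gearys = [], []
    for g in markers:
        x = logexpr[:, g]
        if np.ptp(x) == 0:
            warnings.warn(f"gene column {g} constant over spots; skipped", stacklevel=2)
            continue
        morans.append(morans_i(x, w))
        gearys.append(gearys_c(x, w))
    if not morans:
        raise ValueError("no usable marker genes for spatial autocorrelation")
    return {
        "moran_score": float(np.median(morans)),
        "geary_score": float(1.0 - np.median(gearys)),
    }


def chaos_score(coords: np.ndarray, labels) -> dict[str, float]:
    """Within-cluster nearest-neighbor compactness in standardized coordinates.

    Raw CHAOS is the mean (over all spots) of the distance to the nearest
    spot sharing the label, after per-axis standardization with population
    variance. Reported score is 1 - raw, floored at 0. Singleton clusters
    contribute 0 with a warning.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 spots")
    std = coords.std(axis=0)  # population (1/n) variance
    std[std == 0] = 1.0
    z = (coords - coords.mean(axis=0)) / std

    total = 0.0
    for level in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == level)
        if len(idx) < 2:
            warnings.warn(f"singleton cluster {level!r} contributes 0", stacklevel=2)
            continue
        sub = z[idx]
        nn = NearestNeighbors(n_neighbors=2).fit(sub)
        dist, _ = nn.kneighbors(sub)
        total += float(dist[:, 1].sum())
    raw = total / n
    return {"chaos_raw": raw, "chaos_score": float(max(0.0, 1.0 - raw))}


def rook_neighbor_lists(coords: np.ndarray) -> list[list[int]]:
    """Rook (4-connected) adjacency for integer-lattice coordinates.

    Border spots get their 2 or 3 in-grid neighbors.
    """
    coords = np.asarray(coords)
    pos = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    out = []
    for r, c in coords:
        r, c = int(r), int(c)
        out.append(
            [
                pos[(rr, cc)]
                for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if (rr, cc) in pos
            ]
        )
    return out


def pas_score(
    coords: np.ndarray,
    labels,
    cfg: SpatialConfig | None = None,
    neighbor_lists: list[list[int]] | None = None,
) -> dict[str, float]:
    """Fraction of spots whose spatial neighborhood disagrees on the label.

    A spot is abnormal iff more than half of its spatial neighbors (self
    excluded; the k_spatial nearest by default, or explicit ``neighbor_lists``
    such as rook adjacency) carry a different label. Reported score is
    1 - fraction.
    """
    cfg = cfg or SpatialConfig()
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    n = len(coords)
    if neighbor_lists is None:
        k = cfg.k_spatial
        if k >= n:
            raise ValueError("k_spatial must be < number of spots")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        neighbor_lists = [[j for j in row if j != i][:k] for i, row in enumerate(idx)]
    abnormal = 0
    for i, neigh in enumerate(neighbor_lists):
        diff = sum(labels[j] != labels[i] for j in neigh)
        abnormal += diff > len(neigh) / 2
    raw = abnormal / n
    return {"pas_raw": raw, "pas_score": float(1.0 - raw)}


def spatial_metric_suite(
    counts, domains, coords, cfg: SpatialConfig | None = None
) -> dict[str, float]:
    cfg = cfg or SpatialConfig()
    out = {}
    if counts is not None:
        out.update(spatial_autocorrelation(counts, domains, coords, cfg))
    out["chaos_score"] = chaos_score(coords, domains)["chaos_score"]
    out["pas_score"] = pas_score(coords, domains, cfg)["pas_score"]
    return out
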