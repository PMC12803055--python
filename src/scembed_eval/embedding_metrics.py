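"""Label- and batch-aware embedding-space metrics.

Covers silhouette on cell-type labels, kNN classifier accuracy under
stratified cross-validation, normalized cLISI/iLISI, batch-removal adapted
silhouette, graph connectivity and kBET. Every score is oriented so that
higher is better; direction metadata lives in the report layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedKFold

from scembed_eval.clustering import build_neighbor_graph
from scembed_eval.datamodel import EmbeddingSet


@dataclass
class BatchMetricConfig:
    """Neighborhood sizes and thresholds for the batch/embedding metrics."""

    k_lisi: int = 50
    k_kbet: int = 50
    alpha_kbet: float = 0.05
    k_gc: int = 15
    k_acc: int = 5
    folds_acc: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_kbet < 1:
            raise ValueError("alpha_kbet must lie in (0,1)")
        for name in ("k_lisi", "k_kbet", "k_gc", "k_acc", "folds_acc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _as_matrix(emb) -> np.ndarray:
    return emb.matrix if isinstance(emb, EmbeddingSet) else np.asarray(emb, float)


def _labels(arr) -> np.ndarray:
    return np.asarray(arr, dtype=object)


def silhouette_label(emb, labels) -> float:
    """Mean silhouette width over cells using the given labels; in [-1, 1].

    Singleton classes contribute s(i) = 0 by convention.
    """
    X = _as_matrix(emb)
    y = _labels(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("silhouette requires at least 2 label levels")
    codes = np.unique(y.astype(str), return_inverse=True)[1]
    return float(np.mean(silhouette_samples(X, codes, metric="euclidean")))


def knn_accuracy(emb, labels, cfg: BatchMetricConfig | None = None) -> float:
    """Stratified K-fold accuracy of a kNN majority-vote classifier.

    Majority-vote ties are resolved by the nearest single neighbor's label.
    Classes smaller than the fold count reduce the fold count (warning).
    """
    cfg = cfg or BatchMetricConfig()
    X = _as_matrix(emb)
    y = _labels(labels)
    _, counts = np.unique(y.astype(str), return_counts=True)
    folds = cfg.folds_acc
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        warnings.warn(
            f"smallest class has {counts.min()} members; using {folds} folds",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y.astype(str)):
        preds = _knn_predict(X[train_idx], y[train_idx], X[test_idx], cfg.k_acc)
        accs.append(float(np.mean(preds == y[test_idx])))
    return float(np.mean(accs))


def _knn_predict(X_train, y_train, X_test, k) -> np.ndarray:
    from sklearn.neighbors import NearestNeighbors

    k = min(k, len(X_train))
    nn = NearestNeighbors(n_neighbors=k).fit(X_train)
    _, idx = nn.kneighbors(X_test)
    preds = np.empty(len(X_test), dtype=object)
    for i, row in enumerate(idx):
        votes = {}
        for j in row:
            votes[y_train[j]] = votes.get(y_train[j], 0) + 1
        top = max(votes.values())
        winners = {lbl for lbl, c in votes.items() if c == top}
        if len(winners) == 1:
            preds[i] = winners.pop()
        else:  # tie: nearest single neighbor among tied labels
            preds[i] = next(y_train[j] for j in row if y_train[j] in winners)
    return preds


def _neighbor_label_matrix(X: np.ndarray, k: int):
    graph = build_neighbor_graph(EmbeddingSet([str(i) for i in range(len(X))], X), k)
    return graph.neighbors


def _lisi_mean(neigh: np.ndarray, y: np.ndarray) -> float:
    """Mean per-cell inverse Simpson index over fixed-k neighborhoods."""
    vals = []
    for i in range(len(y)):
        lbls = y[neigh[i]]
        _, counts = np.unique(lbls.astype(str), return_counts=True)
        p = counts / counts.sum()
        vals.append(1.0 / np.sum(p**2))
    return float(np.mean(vals))


def lisi_scores(
    emb, labels, batch=None, cfg: BatchMetricConfig | None = None
) -> dict[str, float]:
    """Normalized cLISI/iLISI on the k_lisi-nearest neighborhood.

    Raw LISI is the mean inverse Simpson index, in [1, C]; normalized as
    (L-1)/(C-1). ``clisi_score`` reports 1 - normalized (higher = purer
    neighborhoods), ``ilisi_score`` reports the normalized value
    (higher = better batch mixing).
    """
    cfg = cfg or BatchMetricConfig()
    X = _as_matrix(emb)
    y = _labels(labels)
    k = min(cfg.k_lisi, len(X) - 1)
    neigh = _neighbor_label_matrix(X, k)

    out: dict[str, float] = {}
    n_types = len(set(y.tolist()))
    if n_types < 2:
        out["clisi_score"] = 1.0
    else:
        raw = _lisi_mean(neigh, y)
        out["clisi_score"] = float(1.0 - (raw - 1.0) / (n_types - 1.0))

    if batch is None:
        return out
    b = _labels(batch)
    n_batches = len(set(b.tolist()))
    if n_batches < 2:
        warnings.warn("single batch level; ilisi_score reported as 1", stacklevel=2)
        out["ilisi_score"] = 1.0
    else:
        raw = _lisi_mean(neigh, b)
        out["ilisi_score"] = float((raw - 1.0) / (n_batches - 1.0))
    return out


def bras(emb, cell_labels, batch) -> float:
    """Batch-removal adapted silhouette: mean over cell types of 1 - |ASW_batch|.

    Cell types containing a single batch contribute 1.
    """
    X = _as_matrix(emb)
    y = _labels(cell_labels)
    b = _labels(batch)
    contributions = []
    any_multi = False
    for level in sorted(set(y.tolist()), key=str):
        mask = y == level
        b_sub = b[mask]
        if len(set(b_sub.tolist())) < 2 or mask.sum() < 3:
            contributions.append(1.0)
            continue
        any_multi = True
        codes = np.unique(b_sub.astype(str), return_inverse=True)[1]
        asw_batch = float(np.mean(silhouette_samples(X[mask], codes)))
        contributions.append(1.0 - abs(asw_batch))
    if not any_multi:
        warnings.warn("no cell type spans >= 2 batches; BRAS = 1", stacklevel=2)
    return float(np.mean(contributions))


def graph_connectivity(emb, labels, cfg: BatchMetricConfig | None = None) -> float:
    """Mean over labels of the largest-connected-component fraction.

    The kNN subgraph is built within each label's cells (symmetrized).
    """
    cfg = cfg or BatchMetricConfig()
    X = _as_matrix(emb)
    y = _labels(labels)
    fractions = []
    for level in sorted(set(y.tolist()), key=str):
        mask = y == level
        n_c = int(mask.sum())
        if n_c == 1:
            fractions.append(1.0)
            continue
        k = min(cfg.k_gc, n_c - 1)
        graph = build_neighbor_graph(
            EmbeddingSet([f"c{i}" for i in range(n_c)], X[mask]), k
        )
        rows, cols = [], []
        for i in range(n_c):
            for j in graph.neighbors[i]:
                rows.append(i)
                cols.append(int(j))
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_c, n_c))
        adj = adj + adj.T  # symmetrize
        n_comp, comp = connected_components(adj, directed=False)
        largest = np.bincount(comp).max()
        fractions.append(largest / n_c)
    return float(np.mean(fractions))


def kbet(emb, batch, cfg: BatchMetricConfig | None = None) -> float:
    """Fraction of cells whose neighborhood batch mix is not rejected.

    Per cell, a chi-square goodness-of-fit test compares the k_kbet-nearest
    neighborhood batch composition to the global batch frequencies; the score
    is the fraction of cells with p > alpha. Batches whose expected
    neighborhood count falls below 1 are pooled (warning).
    """
    cfg = cfg or BatchMetricConfig()
    X = _as_matrix(emb)
    b = _labels(batch)
    levels, codes = np.unique(b.astype(str), return_inverse=True)
    if len(levels) < 2:
        return 1.0  # df = 0: never rejected
    n = len(b)
    k = min(cfg.k_kbet, n - 1)
    global_freq = np.bincount(codes, minlength=len(levels)) / n
    expected = global_freq * k
    if np.any(expected < 1):
        keep = expected >= 1
        warnings.warn(
            "batches with expected neighborhood count < 1 pooled", stacklevel=2
        )
        pooled_code = np.where(keep[codes], codes, -1)
        levels_idx = np.flatnonzero(keep)
        remap = {int(c): i for i, c in enumerate(levels_idx)}
        codes = np.asarray([remap.get(int(c), len(levels_idx)) for c in pooled_code])
        freq = np.append(global_freq[keep], global_freq[~keep].sum())
        expected = freq * k
    neigh = _neighbor_label_matrix(X, k)
    df = len(expected) - 1
    if df == 0:
        return 1.0
    accept = 0
    for i in range(n):
        observed = np.bincount(codes[neigh[i]], minlength=len(expected))
        stat = np.sum((observed - expected) ** 2 / expected)
        p = float(chi2.sf(stat, df))
        accept += p > cfg.alpha_kbet
    return accept / n


def embedding_metric_suite(
    emb, ann, cfg: BatchMetricConfig | None = None
) -> dict[str, float]:
    """All embedding metrics applicable to the given annotations."""
    cfg = cfg or BatchMetricConfig()
    out: dict[str, float] = {}
    labels = ann.cell_type
    out["asw"] = silhouette_label(emb, labels)
    out["acc_knn"] = knn_accuracy(emb, labels, cfg)
    out.update(lisi_scores(emb, labels, ann.batch, cfg))
    out["gc"] = graph_connectivity(emb, labels, cfg)
    if ann.batch is not None and len(set(ann.batch.tolist())) >= 2:
        out["bras"] = bras(emb, labels, ann.batch)
        out["kbet"] = kbet(emb, ann.batch, cfg)
    return out
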