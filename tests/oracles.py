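"""Independent, loop-based oracle implementations used by the test suite.

Deliberately naive: exhaustive pair counting, plug-in entropies and
all-pairs distance scans, kept free of the library code paths they check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# --- partition agreement -----------------------------------------------------


def pair_counts(u, v):
    """Count pair agreement categories by exhaustive enumeration."""
    n = len(u)
    ss = sd = ds = dd = 0  # same/same, same/diff, diff/same, diff/diff
    for i, j in combinations(range(n), 2):
        su, sv = u[i] == u[j], v[i] == v[j]
        if su and sv:
            ss += 1
        elif su and not sv:
            sd += 1
        elif not su and sv:
            ds += 1
        else:
            dd += 1
    return ss, sd, ds, dd


def ari_oracle(u, v) -> float:
    ss, sd, ds, dd = pair_counts(u, v)
    n = len(u)
    total = n * (n - 1) // 2
    sum_a = ss + sd  # pairs together in u
    sum_b = ss + ds  # pairs together in v
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (ss - expected) / (max_index - expected)


def fmi_oracle(u, v) -> float:
    tp, fn, fp, _ = pair_counts(u, v)
    denom = math.sqrt((tp + fp) * (tp + fn))
    return tp / denom if denom > 0 else 0.0


def _entropy_of(labels) -> float:
    n = len(labels)
    h = 0.0
    for lvl in set(labels):
        p = sum(1 for x in labels if x == lvl) / n
        h -= p * math.log(p)
    return h


def _mutual_information(u, v) -> float:
    n = len(u)
    mi = 0.0
    for lu in set(u):
        for lv in set(v):
            nij = sum(1 for a, b in zip(u, v) if a == lu and b == lv)
            if nij == 0:
                continue
            pi = sum(1 for a in u if a == lu) / n
            pj = sum(1 for b in v if b == lv) / n
            mi += (nij / n) * math.log((nij / n) / (pi * pj))
    return mi


def nmi_oracle(u, v) -> float:
    hu, hv = _entropy_of(u), _entropy_of(v)
    if hu == 0.0 and hv == 0.0:
        return 1.0
    if hu == 0.0 or hv == 0.0:
        return 0.0
    return 2.0 * _mutual_information(u, v) / (hu + hv)


def hom_oracle(u, v) -> float:
    hu = _entropy_of(u)
    if hu == 0.0:
        return 1.0
    return 1.0 - (hu - _mutual_information(u, v)) / hu


def com_oracle(u, v) -> float:
    hv = _entropy_of(v)
    if hv == 0.0:
        return 1.0
    return 1.0 - (hv - _mutual_information(u, v)) / hv


# --- embedding metrics -------------------------------------------------------


def silhouette_oracle(X, labels) -> float:
    X = np.asarray(X, float)
    n = len(X)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = math.inf
        for lvl in set(labels):
            if lvl == labels[i]:
                continue
            others = [j for j in range(n) if labels[j] == lvl]
            b = min(b, np.mean([np.linalg.norm(X[i] - X[j]) for j in others]))
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def knn_oracle(X, k):
    """All-pairs brute-force k nearest neighbors, ties toward lower index."""
    X = np.asarray(X, float)
    n = len(X)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        d = [(np.linalg.norm(X[i] - X[j]), j) for j in range(n) if j != i]
        d.sort()
        out[i] = [j for _, j in d[:k]]
    return out


def lisi_oracle(X, labels, k) -> float:
    neigh = knn_oracle(X, k)
    vals = []
    for i in range(len(X)):
        lbls = [labels[j] for j in neigh[i]]
        total = len(lbls)
        simpson = sum((lbls.count(lvl) / total) ** 2 for lvl in set(lbls))
        vals.append(1.0 / simpson)
    return float(np.mean(vals))


def kbet_oracle(X, batches, k, alpha) -> float:
    from scipy.stats import chi2

    neigh = knn_oracle(X, k)
    levels = sorted(set(batches))
    n = len(X)
    global_freq = {lvl: sum(1 for b in batches if b == lvl) / n for lvl in levels}
    accept = 0
    for i in range(n):
        lbls = [batches[j] for j in neigh[i]]
        stat = 0.0
        for lvl in levels:
            exp = global_freq[lvl] * k
            obs = lbls.count(lvl)
            stat += (obs - exp) ** 2 / exp
        p = chi2.sf(stat, len(levels) - 1)
        accept += p > alpha
    return accept / n


def gc_oracle(X, labels, k) -> float:
    """Largest-component fraction per label via DFS on the brute kNN graph."""
    fractions = []
    for lvl in sorted(set(labels), key=str):
        idx = [i for i in range(len(X)) if labels[i] == lvl]
        m = len(idx)
        if m == 1:
            fractions.append(1.0)
            continue
        sub = np.asarray(X)[idx]
        kk = min(k, m - 1)
        neigh = knn_oracle(sub, kk)
        adj = [set() for _ in range(m)]
        for i in range(m):
            for j in neigh[i]:
                adj[i].add(int(j))
                adj[int(j)].add(i)
        seen = set()
        best = 0
        for start in range(m):
            if start in seen:
                continue
            stack, comp = [start], 0
            seen.add(start)
            while stack:
                node = stack.pop()
                comp += 1
                for nxt in adj[node]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            best = max(best, comp)
        fractions.append(best / m)
    return float(np.mean(fractions))


# --- spatial -----------------------------------------------------------------


def moran_oracle(x, w) -> float:
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / np.sum(z**2)


def geary_oracle(x, w) -> float:
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * (x[i] - x[j]) ** 2 for i in range(n) for j in range(n))
    return (n - 1) / (2 * w.sum()) * num / np.sum(z**2)


def chaos_oracle(coords, labels) -> float:
    coords = np.asarray(coords, float)
    n = len(coords)
    mu = coords.mean(axis=0)
    sd = coords.std(axis=0)
    sd[sd == 0] = 1.0
    z = (coords - mu) / sd
    total = 0.0
    for lvl in set(labels):
        idx = [i for i in range(n) if labels[i] == lvl]
        if len(idx) < 2:
            continue
        for i in idx:
            total += min(np.linalg.norm(z[i] - z[j]) for j in idx if j != i)
    return total / n


def pas_oracle(coords, labels, k) -> float:
    coords = np.asarray(coords, float)
    n = len(coords)
    abnormal = 0
    for i in range(n):
        d = [(np.linalg.norm(coords[i] - coords[j]), j) for j in range(n) if j != i]
        d.sort()
        neigh = [j for _, j in d[:k]]
        diff = sum(labels[j] != labels[i] for j in neigh)
        abnormal += diff > k / 2
    return abnormal / n


# --- few-shot ----------------------------------------------------------------


def cosine_nn_oracle(support, support_labels, queries):
    """Nearest support vector by cosine distance (K=1 prototype equivalence)."""
    support = np.asarray(support, float)
    queries = np.asarray(queries, float)
    preds = []
    for q in queries:
        dists = [
            1 - (q @ s) / (np.linalg.norm(q) * np.linalg.norm(s)) for s in support
        ]
        preds.append(support_labels[int(np.argmin(dists))])
    return np.asarray(preds, dtype=object)


# --- classification ----------------------------------------------------------


def confusion_report_oracle(y_true, y_pred):
    """Accuracy + macro P/R/F1 from an explicit confusion matrix."""
    classes = sorted(set(y_true) | set(y_pred), key=str)
    acc = sum(a == b for a, b in zip(y_true, y_pred)) / len(y_true)
    precisions, recalls = [], []
    for c in classes:
        tp = sum(1 for a, b in zip(y_true, y_pred) if a == c and b == c)
        fp = sum(1 for a, b in zip(y_true, y_pred) if a != c and b == c)
        fn = sum(1 for a, b in zip(y_true, y_pred) if a == c and b != c)
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    p, r = float(np.mean(precisions)), float(np.mean(recalls))
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return {"accuracy": acc, "precision_macro": p, "recall_macro": r, "f1_macro": f1}
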