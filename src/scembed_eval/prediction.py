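"""Label-prediction metrics for few-shot and fine-tuning outputs.

Macro F1 is the harmonic mean of macro precision and macro recall (not the
mean of per-class F1 scores, which some library defaults report). ROC-AUC is
one-vs-rest with an unweighted macro average over class probability columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class PredictionSet:
    """Aligned truth, predictions and class-probability matrix."""

    cell_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    probabilities: np.ndarray  # (n, n_levels), rows sum to 1
    levels: list[str]

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=object)
        self.y_pred = np.asarray(self.y_pred, dtype=object)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        n = len(self.cell_ids)
        if len(self.y_true) != n or len(self.y_pred) != n:
            raise ValueError("labels not aligned with cell ids")
        if self.probabilities.shape != (n, len(self.levels)):
            raise ValueError("probability matrix shape mismatch")
        if np.any(self.probabilities < -1e-12) or np.any(self.probabilities > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")
        if np.any(np.abs(self.probabilities.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("probability rows must sum to 1")


def classification_report(pred: PredictionSet, top_k: int = 3) -> dict[str, float]:
    """Accuracy, macro precision/recall/F1, OvR macro ROC-AUC and top-k accuracy."""
    y_true, y_pred = pred.y_true, pred.y_pred
    n = len(y_true)
    true_levels = set(y_true.tolist())
    if len(true_levels) < 2:
        raise ValueError("need >= 2 classes in true labels")

    accuracy = float(np.mean(y_true == y_pred))

    # per-class precision/recall over classes present in truth or predictions;
    # empty denominators contribute 0 (warning)
    classes = sorted(true_levels | set(y_pred.tolist()), key=str)
    precisions, recalls = [], []
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        if tp + fp == 0:
            warnings.warn(f"class {c!r} never predicted; precision set to 0", stacklevel=2)
            precisions.append(0.0)
        else:
            precisions.append(tp / (tp + fp))
        if tp + fn == 0:
            warnings.warn(f"class {c!r} absent from truth; recall set to 0", stacklevel=2)
            recalls.append(0.0)
        else:
            recalls.append(tp / (tp + fn))
    p_macro = float(np.mean(precisions))
    r_macro = float(np.mean(recalls))
    f1 = 0.0 if p_macro + r_macro == 0 else 2 * p_macro * r_macro / (p_macro + r_macro)

    return {
        "accuracy": accuracy,
        "precision_macro": p_macro,
        "recall_macro": r_macro,
        "f1_macro": float(f1),
        "roc_auc": _macro_ovr_auc(pred),
        "top_k_accuracy": top_k_accuracy(pred, top_k),
    }


def _macro_ovr_auc(pred: PredictionSet) -> float:
    """Unweighted one-vs-rest macro AUC; classes lacking positives or
    negatives in the truth are skipped."""
    aucs = []
    for j, level in enumerate(pred.levels):
        y_bin = (pred.y_true == level).astype(int)
        if y_bin.sum() in (0, len(y_bin)):
            continue
        aucs.append(roc_auc_score(y_bin, pred.probabilities[:, j]))
    if not aucs:
        return float("nan")
    return float(np.mean(aucs))


def top_k_accuracy(pred: PredictionSet, k: int) -> float:
    """Fraction of cells whose true label ranks in the top-k probabilities.

    Probability ties break toward earlier class order.
    """
    level_idx = {lvl: j for j, lvl in enumerate(pred.levels)}
    n, n_levels = pred.probabilities.shape
    k = min(k, n_levels)
    hits = 0
    col_order = np.arange(n_levels)
    for i in range(n):
        true_j = level_idx.get(pred.y_true[i])
        if true_j is None:
            continue
        # sort by probability desc, ties by class order asc
        order = np.lexsort((col_order, -pred.probabilities[i]))
        hits += true_j in set(order[:k].tolist())
    return hits / n


def episode_reports(
    per_episode: list[PredictionSet], top_k: int = 3, pooled: bool = False
) -> dict[str, float]:
    """Aggregate metrics over few-shot trials.

    Default averages each metric across per-episode reports; ``pooled``
    concatenates predictions first.
    """
    if pooled:
        merged = PredictionSet(
            cell_ids=[c for p in per_episode for c in p.cell_ids],
            y_true=np.concatenate([p.y_true for p in per_episode]),
            y_pred=np.concatenate([p.y_pred for p in per_episode]),
            probabilities=_stack_probs(per_episode),
            levels=sorted({lvl for p in per_episode for lvl in p.levels}),
        )
        return classification_report(merged, top_k)
    reports = [classification_report(p, top_k) for p in per_episode]
    return {key: float(np.mean([r[key] for r in reports])) for key in reports[0]}


def _stack_probs(preds: list[PredictionSet]) -> np.ndarray:
    levels = sorted({lvl for p in preds for lvl in p.levels})
    idx = {lvl: j for j, lvl in enumerate(levels)}
    rows = []
    for p in preds:
        block = np.zeros((len(p.cell_ids), len(levels)))
        for j, lvl in enumerate(p.levels):
            block[:, idx[lvl]] = p.probabilities[:, j]
        rows.append(block)
    out = np.vstack(rows)
    out /= out.sum(axis=1, keepdims=True)
    return out
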