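"""Counterfactual perturbation-response prediction and its evaluation.

Pipeline: build counterfactual transcriptomes from a fixed control subset,
embed them (any embedding function), average to condition-level embeddings,
standardize + PCA to a small number of dimensions, fit ridge regression to
observed mean responses, and score held-out conditions with L2 error and
Pearson correlation. An additive baseline sums single-perturbation
responses for double perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from scembed_eval.datamodel import (
    CONTROL_LABEL,
    CellAnnotations,
    SplitAssignment,
    parse_condition,
    perturbation_split,
)


@dataclass
class ConditionTable:
    """Per-condition observed mean responses (change vs control)."""

    condition_ids: list[str]
    targets: dict[str, tuple[str, ...]]
    responses: np.ndarray  # (n_conditions, G)
    train_mask: np.ndarray  # bool per condition

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        if CONTROL_LABEL in self.condition_ids:
            raise ValueError("control must not appear among conditions")
        n = len(self.condition_ids)
        if self.responses.shape[0] != n or len(self.train_mask) != n:
            raise ValueError("condition table misaligned")

    @property
    def n_genes(self) -> int:
        return self.responses.shape[1]

    def response(self, cond: str) -> np.ndarray:
        return self.responses[self.condition_ids.index(cond)]

    @property
    def train_conditions(self) -> list[str]:
        return [c for c, m in zip(self.condition_ids, self.train_mask) if m]

    @property
    def test_conditions(self) -> list[str]:
        return [c for c, m in zip(self.condition_ids, self.train_mask) if not m]


def build_condition_table(
    expr: np.ndarray,
    gene_ids: list[str],
    ann: CellAnnotations,
    split: SplitAssignment | None = None,
    seed: int = 0,
) -> ConditionTable:
    """Observed per-condition mean expression change relative to control."""
    if ann.condition is None:
        raise ValueError("annotations carry no condition labels")
    cond = np.asarray(ann.condition, dtype=object)
    control_mean = expr[cond == CONTROL_LABEL].mean(axis=0)
    levels = sorted({str(c) for c in cond.tolist()} - {CONTROL_LABEL})
    if split is None:
        split = perturbation_split(cond, seed=seed)
    train_set = set(split.train_ids)
    responses = np.vstack([expr[cond == c].mean(axis=0) - control_mean for c in levels])
    return ConditionTable(
        condition_ids=levels,
        targets={c: parse_condition(c) for c in levels},
        responses=responses,
        train_mask=np.asarray([c in train_set for c in levels]),
    )


def construct_counterfactuals(
    expr: np.ndarray,
    gene_ids: list[str],
    ann: CellAnnotations,
    n_control: int = 500,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Counterfactual transcriptomes per condition.

    One fixed seeded control subset is reused for all conditions. For each
    condition only the target genes' columns are overwritten with values
    sampled (seeded) from the condition's observed cells; every other gene
    stays bit-identical to control.
    """
    if ann.condition is None:
        raise ValueError("annotations carry no condition labels")
    cond = np.asarray(ann.condition, dtype=object)
    control_idx = np.flatnonzero(cond == CONTROL_LABEL)
    if len(control_idx) == 0:
        raise ValueError("no control cells present")
    rng = np.random.default_rng(seed)
    take = min(n_control, len(control_idx))
    subset = control_idx[np.sort(rng.choice(len(control_idx), take, replace=False))]
    base = expr[subset]

    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    out: dict[str, np.ndarray] = {}
    for level in sorted({str(c) for c in cond.tolist()} - {CONTROL_LABEL}):
        targets = parse_condition(level)
        for g in targets:
            if g not in gene_pos:
                raise ValueError(f"target gene {g!r} of condition {level!r} not in panel")
        cf = base.copy()
        donor_idx = np.flatnonzero(cond == level)
        draws = rng.integers(0, len(donor_idx), len(subset))
        for g in targets:
            cf[:, gene_pos[g]] = expr[donor_idx[draws], gene_pos[g]]
        out[level] = cf
    return out


@dataclass
class ResponseModel:
    """Standardize -> PCA -> ridge map from condition embeddings to responses."""

    mean_: np.ndarray
    scale_: np.ndarray
    components_: np.ndarray  # (n_pc, d)
    coef_: np.ndarray  # (G, n_pc)
    intercept_: np.ndarray
    ridge_alpha: float

    def transform(self, emb: np.ndarray) -> np.ndarray:
        return ((emb - self.mean_) / self.scale_) @ self.components_.T

    def predict(self, emb: np.ndarray) -> np.ndarray:
        return self.transform(emb) @ self.coef_.T + self.intercept_


def fit_predict_responses(
    condition_embeddings: dict[str, np.ndarray],
    table: ConditionTable,
    n_pc: int = 50,
    ridge_alpha: float = 1.0,
) -> tuple[dict[str, np.ndarray], ResponseModel]:
    """Fit the ridge response model on training conditions, predict the rest.

    Condition embedding = mean over that condition's counterfactual cells
    (arrays of per-cell embeddings are averaged; 1-D vectors are used as-is).
    Standardization and PCA are fitted on training conditions only.
    """
    from sklearn.decomposition import PCA
    from sklearn.linear_model import Ridge

    def _mean(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=np.float64)
        return v.mean(axis=0) if v.ndim == 2 else v

    train = table.train_conditions
    test = table.test_conditions
    if len(train) < 2:
        raise ValueError("need at least 2 training conditions")
    E_train = np.vstack([_mean(condition_embeddings[c]) for c in train])
    Y_train = np.vstack([table.response(c) for c in train])

    mean = E_train.mean(axis=0)
    scale = E_train.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (E_train - mean) / scale

    max_pc = min(n_pc, Z.shape[1], len(train) - 1)
    if max_pc < n_pc:
        warnings.warn(f"n_pc reduced to {max_pc} (few training conditions)", stacklevel=2)
    pca = PCA(n_components=max_pc, svd_solver="full")
    Zr = pca.fit_transform(Z)

    ridge = Ridge(alpha=ridge_alpha)
    ridge.fit(Zr, Y_train)

    model = ResponseModel(
        mean_=mean,
        scale_=scale,
        components_=pca.components_,
        coef_=np.atleast_2d(ridge.coef_),
        intercept_=np.atleast_1d(ridge.intercept_),
        ridge_alpha=ridge_alpha,
    )
    # PCA centers scores on the train mean; fold that into the transform
    model.mean_ = mean + pca.mean_ * scale

    preds = {}
    for c in test:
        preds[c] = model.predict(_mean(condition_embeddings[c])[None, :])[0]
    return preds, model


def additive_baseline(
    table: ConditionTable,
    pair: tuple[str, str],
    mode: str = "observed",
    model: ResponseModel | None = None,
    condition_embeddings: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Predict a double perturbation as the sum of its single responses.

    ``observed`` (default) sums the observed training single responses;
    ``predicted`` sums the ridge model's predictions for the singles.
    """
    g1, g2 = pair
    for g in (g1, g2):
        if g not in table.condition_ids or not table.train_mask[table.condition_ids.index(g)]:
            raise ValueError(f"single perturbation {g!r} missing from training conditions")
    if mode == "observed":
        return table.response(g1) + table.response(g2)
    if mode == "predicted":
        if model is None or condition_embeddings is None:
            raise ValueError("predicted mode needs a fitted model and embeddings")

        def _mean(v):
            v = np.asarray(v, dtype=np.float64)
            return v.mean(axis=0) if v.ndim == 2 else v

        return (
            model.predict(_mean(condition_embeddings[g1])[None, :])[0]
            + model.predict(_mean(condition_embeddings[g2])[None, :])[0]
        )
    raise ValueError(f"unknown mode {mode!r}")


def response_metrics(y_hat: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """L2 norm of the error and Pearson correlation of gene-wise responses."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("responses must be equal-length vectors of length >= 2")
    l2 = float(np.linalg.norm(y_hat - y))
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        warnings.warn("constant response vector; Pearson undefined", stacklevel=2)
        return {"l2": l2, "pearson": float("nan")}
    yc, hc = y - y.mean(), y_hat - y_hat.mean()
    pearson = float(np.sum(hc * yc) / np.sqrt(np.sum(hc**2) * np.sum(yc**2)))
    return {"l2": l2, "pearson": pearson}


def run_perturbation_eval(
    expr: np.ndarray,
    gene_ids: list[str],
    ann: CellAnnotations,
    embed_fn=None,
    n_control: int = 200,
    n_pc: int = 50,
    ridge_alpha: float = 1.0,
    seed: int = 0,
) -> dict:
    """End-to-end perturbation evaluation on an expression table.

    ``embed_fn`` maps a cells x genes matrix to a cells x d embedding
    (identity/expression baseline when ``None``). Returns per-test-condition
    model and additive-baseline metrics plus their means.
    """
    split = perturbation_split(ann.condition, seed=seed)
    table = build_condition_table(expr, gene_ids, ann, split=split)
    counterfactuals = construct_counterfactuals(expr, gene_ids, ann, n_control, seed)
    embed = embed_fn or (lambda m: m)
    cond_emb = {c: np.asarray(embed(cf)) for c, cf in counterfactuals.items()}
    preds, model = fit_predict_responses(cond_emb, table, n_pc, ridge_alpha)

    per_condition = {}
    for c, y_hat in preds.items():
        y = table.response(c)
        row = {"model_" + k: v for k, v in response_metrics(y_hat, y).items()}
        targets = table.targets[c]
        if len(targets) == 2:
            y_add = additive_baseline(table, targets)
            row.update({"additive_" + k: v for k, v in response_metrics(y_add, y).items()})
        per_condition[c] = row

    summary = {}
    for key in {k for row in per_condition.values() for k in row}:
        vals = [row[key] for row in per_condition.values() if key in row]
        summary[key + "_mean"] = float(np.nanmean(vals))
    return {
        "per_condition": per_condition,
        "summary": summary,
        "split": split,
        "model": model,
        "table": table,
    }
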