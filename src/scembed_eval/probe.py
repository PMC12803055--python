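"""Standardized supervised probe and the HVG+PCA classical baseline.

The probe is a small MLP — layer normalization, dropout, a hidden linear
layer with GELU activation, and an output layer — trained with cross-entropy,
an Adam-style optimizer under a cosine learning-rate schedule, and early
stopping on a stratified validation split. Implemented directly in NumPy
with manual gradients so the artifact has no deep-learning dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from scembed_eval.datamodel import (
    CellAnnotations,
    CountMatrix,
    EmbeddingSet,
    SplitAssignment,
    stratified_split,
)
from scembed_eval.prediction import PredictionSet


@dataclass
class ProbeConfig:
    hidden_width: int = 256
    dropout: float = 0.1
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 128
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0,1)")
        for name in ("hidden_width", "learning_rate", "max_epochs", "patience", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0,1)")


# ---------------------------------------------------------------------------
# HVG + PCA baseline
# ---------------------------------------------------------------------------


def hvg_pca_embed(
    counts: CountMatrix,
    split: SplitAssignment,
    n_hvg: int = 2000,
    n_pc: int = 50,
    target_sum: float = 1e4,
) -> EmbeddingSet:
    """Classical baseline: HVG selection -> lognorm -> scale -> PCA.

    Every statistic (HVG set, normalization means/scales, PCA loadings) is
    fitted on the train split only; val/test cells are projected with the
    fitted transform. HVGs are ranked by dispersion (variance/mean) of
    log-normalized expression on train cells.
    """
    from sklearn.decomposition import PCA

    pos = {c: i for i, c in enumerate(counts.cell_ids)}
    train_idx = np.asarray([pos[c] for c in split.train_ids], dtype=np.intp)
    if len(train_idx) == 0:
        raise ValueError("train split is empty")

    X = counts.counts
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    logX = np.log1p(X / totals * target_sum)

    if n_hvg > counts.n_genes:
        warnings.warn(
            f"n_hvg={n_hvg} > {counts.n_genes} genes; using all genes", stacklevel=2
        )
        n_hvg = counts.n_genes
    train_log = logX[train_idx]
    mean = train_log.mean(axis=0)
    var = train_log.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    hvg = np.sort(np.argsort(-dispersion, kind="stable")[:n_hvg])

    sub = logX[:, hvg]
    mu = sub[train_idx].mean(axis=0)
    sd = sub[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    scaled = (sub - mu) / sd

    n_comp = min(n_pc, len(hvg), len(train_idx) - 1) if len(train_idx) > 1 else 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(scaled[train_idx])
    emb = pca.transform(scaled)
    return EmbeddingSet(list(counts.cell_ids), emb)


# ---------------------------------------------------------------------------
# Probe
# ---------------------------------------------------------------------------


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    Phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    return Phi + x * phi


@dataclass
class ProbeModel:
    """Fitted probe parameters plus training history and best checkpoint."""

    params: dict[str, np.ndarray]
    levels: list[str]
    input_dim: int
    config: ProbeConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = _forward(self.params, np.asarray(X, np.float64))
        return _softmax(logits)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


_EPS_LN = 1e-5


def _forward(p: dict, X: np.ndarray, drop_mask: np.ndarray | None = None, cache: dict | None = None):
    """layernorm -> dropout -> hidden affine + GELU -> output affine."""
    mu = X.mean(axis=1, keepdims=True)
    var = X.var(axis=1, keepdims=True)
    xhat = (X - mu) / np.sqrt(var + _EPS_LN)
    h0 = xhat * p["ln_g"] + p["ln_b"]
    if drop_mask is not None:
        h0 = h0 * drop_mask
    a = h0 @ p["W1"] + p["b1"]
    h1 = _gelu(a)
    logits = h1 @ p["W2"] + p["b2"]
    if cache is not None:
        cache.update(X=X, xhat=xhat, var=var, h0=h0, a=a, h1=h1)
    return logits


def _backward(p: dict, cache: dict, dlogits: np.ndarray, drop_mask: np.ndarray | None):
    grads = {}
    h1, a, h0, xhat, var, X = (
        cache["h1"], cache["a"], cache["h0"], cache["xhat"], cache["var"], cache["X"],
    )
    grads["W2"] = h1.T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dh1 = dlogits @ p["W2"].T
    da = dh1 * _gelu_grad(a)
    grads["W1"] = h0.T @ da
    grads["b1"] = da.sum(axis=0)
    dh0 = da @ p["W1"].T
    if drop_mask is not None:
        dh0 = dh0 * drop_mask
    grads["ln_g"] = (dh0 * xhat).sum(axis=0)
    grads["ln_b"] = dh0.sum(axis=0)
    # layernorm input gradient (per-row normalization over features)
    dxhat = dh0 * p["ln_g"]
    d = X.shape[1]
    inv_std = 1.0 / np.sqrt(var + _EPS_LN)
    dx = (
        dxhat - dxhat.mean(axis=1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
    ) * inv_std
    _ = dx  # input gradient unused (embeddings are fixed) but kept for clarity
    return grads


def train_probe(
    emb: EmbeddingSet,
    labels,
    split: SplitAssignment,
    cfg: ProbeConfig | None = None,
) -> ProbeModel:
    """Train the probe on train cells with a stratified internal validation split.

    Cross-entropy loss, Adam with cosine learning-rate decay, early stopping
    after ``patience`` epochs without validation improvement; the returned
    parameters are those of the best (lowest validation loss) epoch.
    """
    cfg = cfg or ProbeConfig()
    labels = np.asarray(labels, dtype=object)
    pos = {c: i for i, c in enumerate(emb.cell_ids)}

    if split.val_ids:
        train_ids, val_ids = list(split.train_ids), list(split.val_ids)
    else:  # carve a stratified validation split out of the train partition
        train_ann = CellAnnotations(
            cell_ids=list(split.train_ids),
            cell_type=labels[[pos[c] for c in split.train_ids]],
        )
        inner = stratified_split(train_ann, test_fraction=cfg.val_fraction, seed=cfg.seed)
        train_ids, val_ids = list(inner.train_ids), list(inner.test_ids)

    tr = np.asarray([pos[c] for c in train_ids], dtype=np.intp)
    va = np.asarray([pos[c] for c in val_ids], dtype=np.intp)
    levels = sorted(set(labels[tr].tolist()), key=str)
    if len(levels) < 2:
        raise ValueError("need >= 2 classes in train")
    lvl_idx = {lvl: i for i, lvl in enumerate(levels)}
    y_tr = np.asarray([lvl_idx[l] for l in labels[tr]])
    y_va = np.asarray([lvl_idx[l] for l in labels[va]])
    X_tr, X_va = emb.matrix[tr], emb.matrix[va]

    d, C, H = emb.dim, len(levels), cfg.hidden_width
    rng = np.random.default_rng(cfg.seed)
    p = {
        "ln_g": np.ones(d),
        "ln_b": np.zeros(d),
        "W1": rng.standard_normal((d, H)) * np.sqrt(2.0 / d),
        "b1": np.zeros(H),
        "W2": rng.standard_normal((H, C)) * np.sqrt(1.0 / H),
        "b2": np.zeros(C),
    }
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v_) for k, v_ in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def eval_loss(X, y) -> float:
        probs = _softmax(_forward(p, X))
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))

    history: list[dict] = []
    best = {"epoch": -1, "val_loss": np.inf, "params": None}
    stale = 0
    for epoch in range(cfg.max_epochs):
        lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.max_epochs))
        order = rng.permutation(len(tr))
        for start in range(0, len(tr), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            mask = None
            if cfg.dropout > 0:
                mask = (rng.random(Xb.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            cache: dict = {}
            logits = _forward(p, Xb, mask, cache)
            probs = _softmax(logits)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = _backward(p, cache, dlogits, mask)
            if any(not np.all(np.isfinite(g)) for g in grads.values()):
                raise FloatingPointError("probe training diverged (non-finite gradient)")
            step += 1
            for k in p:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                p[k] = p[k] - lr * mhat / (np.sqrt(vhat) + eps)

        train_loss = eval_loss(X_tr, y_tr)
        val_loss = eval_loss(X_va, y_va)
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise FloatingPointError("probe training diverged (non-finite loss)")
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": lr})
        if val_loss < best["val_loss"]:
            best = {
                "epoch": epoch,
                "val_loss": val_loss,
                "params": {k: w.copy() for k, w in p.items()},
            }
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    return ProbeModel(
        params=best["params"],
        levels=levels,
        input_dim=d,
        config=cfg,
        history=history,
        best_epoch=best["epoch"],
    )


def probe_predict(
    model: ProbeModel, emb: EmbeddingSet, y_true=None
) -> PredictionSet:
    """Apply the fitted probe; softmax probabilities and argmax labels.

    ``y_true`` fills the truth column when known; otherwise predictions are
    recorded in both slots so the set remains structurally valid.
    """
    if emb.dim != model.input_dim:
        raise ValueError(f"embedding dim {emb.dim} != model input dim {model.input_dim}")
    probs = model.predict_proba(emb.matrix)
    pred_idx = np.argmax(probs, axis=1)
    preds = np.asarray([model.levels[i] for i in pred_idx], dtype=object)
    truth = preds if y_true is None else np.asarray(y_true, dtype=object)
    return PredictionSet(
        cell_ids=list(emb.cell_ids),
        y_true=truth,
        y_pred=preds,
        probabilities=probs,
        levels=list(model.levels),
    )
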