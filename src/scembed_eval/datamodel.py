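"""Shared domain types, h5ad container I/O, and split protocols.

All downstream stages consume the containers defined here. Cell identifier
order is canonical: it is preserved on load and every aligned matrix uses it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: obs/obsm keys used when reading and writing h5ad containers.
DEFAULT_KEYS = {
    "embedding": "X_emb",
    "counts_layer": "counts",
    "cell_type": "cell_type",
    "batch": "batch",
    "condition": "condition",
    "spatial": "spatial",
}

CONTROL_LABEL = "control"


class FormatError(ValueError):
    """Raised when a container violates structural requirements."""


class ValidationError(ValueError):
    """Raised when values violate domain invariants (e.g. non-finite)."""


def _check_unique_ids(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        raise FormatError(f"duplicated {what} identifiers")


@dataclass
class EmbeddingSet:
    """A cells x d real matrix with aligned, unique cell identifiers."""

    cell_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValidationError("embedding matrix must be 2-D")
        if self.matrix.shape[0] != len(self.cell_ids):
            raise FormatError(
                f"embedding rows ({self.matrix.shape[0]}) != cell ids ({len(self.cell_ids)})"
            )
        _check_unique_ids(np.asarray(self.cell_ids), "cell")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("embedding matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def subset(self, ids: list[str]) -> "EmbeddingSet":
        idx = _index_of(self.cell_ids, ids)
        return EmbeddingSet(list(ids), self.matrix[idx])


@dataclass
class CellAnnotations:
    """Per-cell categorical labels and optional spatial coordinates."""

    cell_ids: list[str]
    cell_type: np.ndarray
    batch: np.ndarray | None = None
    condition: np.ndarray | None = None
    spatial_xy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique_ids(np.asarray(self.cell_ids), "cell")
        n = len(self.cell_ids)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if len(self.cell_type) != n:
            raise FormatError("cell_type not aligned with cell_ids")
        if any(not str(v) for v in self.cell_type):
            raise ValidationError("empty cell_type level")
        for name in ("batch", "condition"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=object)
                if len(val) != n:
                    raise FormatError(f"{name} not aligned with cell_ids")
                setattr(self, name, val)
        if self.spatial_xy is not None:
            self.spatial_xy = np.asarray(self.spatial_xy, dtype=np.float64)
            if self.spatial_xy.shape != (n, 2):
                raise FormatError("spatial_xy must be n x 2")
            if not np.all(np.isfinite(self.spatial_xy)):
                raise ValidationError("spatial_xy contains non-finite values")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, ids: list[str]) -> "CellAnnotations":
        idx = _index_of(self.cell_ids, ids)
        return CellAnnotations(
            cell_ids=list(ids),
            cell_type=self.cell_type[idx],
            batch=None if self.batch is None else self.batch[idx],
            condition=None if self.condition is None else self.condition[idx],
            spatial_xy=None if self.spatial_xy is None else self.spatial_xy[idx],
        )


@dataclass
class CountMatrix:
    """A cells x genes non-negative matrix with gene identifiers."""

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique_ids(np.asarray(self.cell_ids), "cell")
        _check_unique_ids(np.asarray(self.gene_ids), "gene")
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("count matrix shape inconsistent with identifiers")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, ids: list[str]) -> "CountMatrix":
        idx = _index_of(self.cell_ids, ids)
        return CountMatrix(list(ids), list(self.gene_ids), self.counts[idx])


@dataclass
class SplitAssignment:
    """Disjoint train/val/test cell-id sets produced by a seeded split."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        tr, va, te = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if tr & va or tr & te or va & te:
            raise ValidationError("split sets are not pairwise disjoint")

    @property
    def all_ids(self) -> list[str]:
        return list(self.train_ids) + list(self.val_ids) + list(self.test_ids)


def _index_of(universe: list[str], wanted: list[str]) -> np.ndarray:
    pos = {c: i for i, c in enumerate(universe)}
    try:
        return np.asarray([pos[c] for c in wanted], dtype=np.intp)
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"unknown cell id {e.args[0]!r}") from e


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------


def write_dataset(
    path: str | Path,
    ann: CellAnnotations,
    embedding: EmbeddingSet | None = None,
    counts: CountMatrix | None = None,
    keys: dict | None = None,
) -> None:
    """Write an h5ad container holding annotations plus embedding and/or counts."""
    import anndata

    keys = {**DEFAULT_KEYS, **(keys or {})}
    if embedding is None and counts is None:
        raise ValueError("at least one of embedding or counts is required")
    n = ann.n_cells
    obs = pd.DataFrame(index=pd.Index(ann.cell_ids, name="cell_id"))
    obs[keys["cell_type"]] = pd.Categorical(ann.cell_type.astype(str))
    if ann.batch is not None:
        obs[keys["batch"]] = pd.Categorical(ann.batch.astype(str))
    if ann.condition is not None:
        obs[keys["condition"]] = pd.Categorical(ann.condition.astype(str))

    if counts is not None:
        if counts.cell_ids != ann.cell_ids:
            raise FormatError("counts cell ids do not match annotations")
        X = counts.counts
        var = pd.DataFrame(index=pd.Index(counts.gene_ids, name="gene_id"))
    else:
        X = np.zeros((n, 1))
        var = pd.DataFrame(index=pd.Index(["_placeholder"], name="gene_id"))

    adata = anndata.AnnData(X=X, obs=obs, var=var)
    if counts is not None:
        adata.layers[keys["counts_layer"]] = counts.counts
    if embedding is not None:
        if embedding.cell_ids != ann.cell_ids:
            raise FormatError("embedding cell ids do not match annotations")
        adata.obsm[keys["embedding"]] = embedding.matrix
    if ann.spatial_xy is not None:
        adata.obsm[keys["spatial"]] = ann.spatial_xy
    adata.uns["scembed_eval"] = {"has_counts": counts is not None}
    adata.write_h5ad(Path(path))


def load_dataset(
    path: str | Path, keys: dict | None = None
) -> tuple[EmbeddingSet | None, CountMatrix | None, CellAnnotations]:
    """Load an h5ad container into the shared domain types.

    All returned objects share the container's cell-id order. Optional
    fields absent from the container stay ``None``.
    """
    import anndata

    keys = {**DEFAULT_KEYS, **(keys or {})}
    adata = anndata.read_h5ad(Path(path))
    cell_ids = [str(c) for c in adata.obs_names]
    _check_unique_ids(np.asarray(cell_ids), "cell")

    if keys["cell_type"] not in adata.obs:
        raise FormatError(f"missing obs key {keys['cell_type']!r}")

    def _obs(key: str) -> np.ndarray | None:
        if key in adata.obs:
            return np.asarray(adata.obs[key].astype(str), dtype=object)
        return None

    ann = CellAnnotations(
        cell_ids=cell_ids,
        cell_type=_obs(keys["cell_type"]),
        batch=_obs(keys["batch"]),
        condition=_obs(keys["condition"]),
        spatial_xy=np.asarray(adata.obsm[keys["spatial"]], dtype=np.float64)
        if keys["spatial"] in adata.obsm
        else None,
    )

    embedding = None
    if keys["embedding"] in adata.obsm:
        emb = np.asarray(adata.obsm[keys["embedding"]], dtype=np.float64)
        if not np.all(np.isfinite(emb)):
            raise ValidationError("embedding matrix contains non-finite values")
        embedding = EmbeddingSet(cell_ids, emb)

    counts = None
    has_counts = bool(adata.uns.get("scembed_eval", {}).get("has_counts", True))
    if keys["counts_layer"] in adata.layers:
        mat = adata.layers[keys["counts_layer"]]
        counts = CountMatrix(cell_ids, [str(g) for g in adata.var_names], _dense(mat))
    elif has_counts and list(adata.var_names) != ["_placeholder"]:
        counts = CountMatrix(cell_ids, [str(g) for g in adata.var_names], _dense(adata.X))

    if embedding is None and counts is None:
        raise FormatError("container holds neither an embedding nor counts")
    return embedding, counts, ann


def _dense(mat) -> np.ndarray:
    import scipy.sparse as sp

    if sp.issparse(mat):
        return np.asarray(mat.todense(), dtype=np.float64)
    return np.asarray(mat, dtype=np.float64)


# ---------------------------------------------------------------------------
# Split protocols
# ---------------------------------------------------------------------------


def stratified_split(
    ann: CellAnnotations,
    test_fraction: float,
    val_fraction: float = 0.0,
    seed: int = 0,
) -> SplitAssignment:
    """Cell-type-stratified train/val/test split.

    Per class the test count is ``round(test_fraction * n_c)`` clipped so at
    least one cell stays in train; every label present in test is therefore
    also present in train. Validation cells are drawn stratified from the
    remaining train pool. Deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(ann.cell_ids, dtype=object)
    labels = np.asarray(ann.cell_type, dtype=object)

    train, val, test = [], [], []
    for level in sorted(set(labels.tolist())):
        members = ids[labels == level]
        n_c = len(members)
        order = rng.permutation(n_c)
        members = members[order]
        if n_c < 2:
            warnings.warn(
                f"class {level!r} has a single cell; kept entirely in train",
                stacklevel=2,
            )
            n_test = 0
        else:
            n_test = int(np.round(test_fraction * n_c))
            n_test = min(n_test, n_c - 1)  # >=1 train cell per class
        test.extend(members[:n_test])
        remain = members[n_test:]
        n_val = int(np.round(val_fraction * len(remain)))
        n_val = min(n_val, len(remain) - 1) if len(remain) > 1 else 0
        val.extend(remain[:n_val])
        train.extend(remain[n_val:])

    # canonical ordering: input cell order
    pos = {c: i for i, c in enumerate(ann.cell_ids)}
    key = pos.__getitem__
    return SplitAssignment(
        train_ids=sorted(map(str, train), key=key),
        val_ids=sorted(map(str, val), key=key),
        test_ids=sorted(map(str, test), key=key),
        seed=seed,
    )


def parse_condition(label: str) -> tuple[str, ...]:
    """Parse a condition label into its target genes; () for control."""
    label = str(label)
    if label == CONTROL_LABEL:
        return ()
    parts = tuple(p for p in label.split("+") if p)
    if not 1 <= len(parts) <= 2:
        raise FormatError(f"unparseable condition label {label!r}")
    return parts


def perturbation_split(
    conditions: np.ndarray | list[str], seed: int = 0
) -> SplitAssignment:
    """Split perturbation conditions into train/test condition-id sets.

    With double perturbations present: train = all singles plus a seeded
    floor(half) of the doubles; test = remaining doubles. Singles only:
    75% train / 25% test. Returned ids are *condition* labels; control is
    excluded (it is available to both phases by construction).
    """
    levels = sorted({str(c) for c in conditions} - {CONTROL_LABEL})
    if not levels:
        raise ValueError("no perturbation conditions found")
    singles = [c for c in levels if len(parse_condition(c)) == 1]
    doubles = [c for c in levels if len(parse_condition(c)) == 2]
    rng = np.random.default_rng(seed)
    if doubles:
        n_train_d = len(doubles) // 2
        order = rng.permutation(len(doubles))
        train_d = [doubles[i] for i in sorted(order[:n_train_d])]
        test_d = [doubles[i] for i in sorted(order[n_train_d:])]
        train = singles + train_d
        test = test_d
    else:
        n_train = int(np.round(0.75 * len(singles)))
        order = rng.permutation(len(singles))
        train = [singles[i] for i in sorted(order[:n_train])]
        test = [singles[i] for i in sorted(order[n_train:])]
    return SplitAssignment(train_ids=train, val_ids=[], test_ids=test, seed=seed)
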