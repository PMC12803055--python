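"""Seeded synthetic datasets with known ground truth.

Every generator is a pure function of its spec (seed included), so all
metric and protocol tests have oracle-checkable inputs without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scembed_eval.datamodel import (
    CONTROL_LABEL,
    CellAnnotations,
    CountMatrix,
    EmbeddingSet,
)


@dataclass
class MixtureSpec:
    """Gaussian-mixture embedding fixture: cell-type clusters + batch shifts.

    ``type_separation`` is the pairwise distance between class means in units
    of the within-class standard deviation; ``batch_shift`` is the norm of the
    constant per-batch offset added in embedding space.
    """

    n_cells: int = 600
    n_types: int = 3
    n_batches: int = 1
    dim: int = 10
    type_separation: float = 6.0
    batch_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_types", "n_batches", "dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.type_separation < 0 or self.batch_shift < 0:
            raise ValueError("separation and shift must be >= 0")


@dataclass
class PerturbFixtureSpec:
    """Additive perturbation fixture: double effects = sum of singles + noise."""

    n_genes: int = 100
    single_genes: list = field(default_factory=lambda: [f"gene{i}" for i in range(8)])
    double_pairs: list = field(default_factory=list)
    effect_scale: float = 1.0
    interaction_scale: float = 0.0
    n_cells_per_condition: int = 30
    embed_dim: int = 32
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_scale < 0 or self.interaction_scale < 0:
            raise ValueError("scales must be >= 0")
        singles = set(self.single_genes)
        for g1, g2 in self.double_pairs:
            if g1 not in singles or g2 not in singles:
                raise ValueError(f"double pair ({g1},{g2}) not within single_genes")


def _simplex_means(n_types: int, dim: int, separation: float, rng) -> np.ndarray:
    """Class means at exact pairwise distance ``separation``.

    A regular simplex embedded in a random orthonormal frame; requires
    dim >= n_types - 1.
    """
    if n_types == 1:
        return np.zeros((1, dim))
    if dim < n_types - 1:
        raise ValueError("dim must be >= n_types - 1 for equidistant means")
    # vertices of a regular simplex with unit pairwise distance
    eye = np.eye(n_types)
    verts = (eye - eye.mean(axis=0)) / np.sqrt(2.0)
    # random orthonormal map into R^dim
    q, _ = np.linalg.qr(rng.standard_normal((dim, n_types)))
    return separation * verts @ q[:, :n_types].T


def make_mixture_embeddings(spec: MixtureSpec) -> tuple[EmbeddingSet, CellAnnotations]:
    """Draw cells from isotropic unit-variance Gaussians around simplex means.

    Each batch adds a fixed random offset of norm ``batch_shift``. Cell types
    and batches are assigned round-robin so counts are balanced.
    """
    rng = np.random.default_rng(spec.seed)
    means = _simplex_means(spec.n_types, spec.dim, spec.type_separation, rng)
    batch_dirs = rng.standard_normal((spec.n_batches, spec.dim))
    batch_dirs /= np.linalg.norm(batch_dirs, axis=1, keepdims=True)
    batch_offsets = spec.batch_shift * batch_dirs

    types = np.arange(spec.n_cells) % spec.n_types
    batches = (np.arange(spec.n_cells) // spec.n_types) % spec.n_batches
    X = means[types] + batch_offsets[batches] + rng.standard_normal((spec.n_cells, spec.dim))

    ids = [f"cell{i}" for i in range(spec.n_cells)]
    ann = CellAnnotations(
        cell_ids=ids,
        cell_type=np.asarray([f"type{t}" for t in types], dtype=object),
        batch=np.asarray([f"batch{b}" for b in batches], dtype=object)
        if spec.n_batches > 1
        else None,
    )
    return EmbeddingSet(ids, X), ann


def make_spatial_fixture(
    grid_rows: int,
    grid_cols: int,
    domain_layout: str = "stripes",
    n_domains: int = 2,
    n_marker_genes_per_domain: int = 5,
    n_background_genes: int = 20,
    base_rate: float = 5.0,
    marker_rate: float = 50.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, CellAnnotations]:
    """Spatial grid with contiguous domains and domain-marker count profiles.

    One spot per grid node with integer coordinates. ``noise`` is the
    fraction of spots whose domain label is randomly reassigned in the count
    model (labels stay truthful); 0 means markers are perfectly domain-tied.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise ValueError("grid must be at least 2x2")
    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(np.arange(grid_rows), np.arange(grid_cols), indexing="ij")
    coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    n = len(coords)

    if domain_layout == "stripes":
        band = grid_rows / n_domains
        domains = np.minimum((coords[:, 0] // band).astype(int), n_domains - 1)
    elif domain_layout == "checkerboard":
        domains = ((coords[:, 0] + coords[:, 1]) % 2).astype(int)
        n_domains = 2
    elif domain_layout == "blocks":
        half_r, half_c = grid_rows / 2, grid_cols / 2
        domains = (2 * (coords[:, 0] >= half_r) + (coords[:, 1] >= half_c)).astype(int)
        n_domains = 4
    else:
        raise ValueError(f"unknown layout {domain_layout!r}")

    expr_domains = domains.copy()
    if noise > 0:
        flip = rng.random(n) < noise
        expr_domains[flip] = rng.integers(0, n_domains, flip.sum())

    n_markers = n_domains * n_marker_genes_per_domain
    n_genes = n_markers + n_background_genes
    rates = np.full((n, n_genes), base_rate)
    for d in range(n_domains):
        g0 = d * n_marker_genes_per_domain
        rates[expr_domains == d, g0 : g0 + n_marker_genes_per_domain] = marker_rate
    counts = rng.poisson(rates).astype(float)

    ids = [f"spot{i}" for i in range(n)]
    genes = [
        f"marker_d{d}_{j}"
        for d in range(n_domains)
        for j in range(n_marker_genes_per_domain)
    ] + [f"bg{j}" for j in range(n_background_genes)]
    ann = CellAnnotations(
        cell_ids=ids,
        cell_type=np.asarray([f"domain{d}" for d in domains], dtype=object),
        spatial_xy=coords,
    )
    return CountMatrix(ids, genes, counts), ann


def make_perturbation_fixture(spec: PerturbFixtureSpec) -> dict:
    """Additive perturbation dataset in log-normalized expression space.

    Ground truth: single effects ``delta_g ~ N(0, effect_scale^2)`` per gene;
    double effects are the sum of the two single effects plus an interaction
    term scaled by ``interaction_scale``. Per-cell expression is the condition
    mean plus Gaussian noise. A seeded linear map produces a pseudo-embedding
    ``E = X @ W + noise`` so the downstream regression is identifiable.

    Returns a dict with keys ``expression`` (CountMatrix-like table of
    log-space values), ``annotations``, ``embedding``, ``ground_truth``
    (condition -> effect vector) and ``control_mean``.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    mu0 = rng.normal(1.0, 0.5, G)

    gene_ids = [f"gene{i}" for i in range(G)]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    unknown = [g for g in spec.single_genes if g not in gene_pos]
    if unknown:
        raise ValueError(f"single_genes not in gene panel: {unknown}")
    target_idx = [gene_pos[g] for g in spec.single_genes]

    # Each single effect is dense over non-target genes but touches no target
    # gene other than its own, and the own-gene effect is bounded away from
    # zero: the counterfactual construction (which overwrites only target
    # columns) then encodes each perturbation faithfully and additively.
    effects: dict[str, np.ndarray] = {}
    for g in spec.single_genes:
        delta = rng.normal(0.0, spec.effect_scale, G)
        delta[target_idx] = 0.0
        own = spec.effect_scale * rng.uniform(1.0, 2.0) * rng.choice([-1.0, 1.0])
        delta[gene_pos[g]] = own
        effects[g] = delta
    for g1, g2 in spec.double_pairs:
        eps = np.zeros(G)
        if spec.interaction_scale > 0:
            eps = rng.normal(0.0, spec.interaction_scale, G)
            eps[target_idx] = 0.0
        effects[f"{g1}+{g2}"] = effects[g1] + effects[g2] + eps

    conditions = [CONTROL_LABEL] + list(spec.single_genes) + [
        f"{g1}+{g2}" for g1, g2 in spec.double_pairs
    ]
    rows, labels = [], []
    for cond in conditions:
        mean = mu0 + effects.get(cond, np.zeros(G))
        cells = mean + rng.normal(0.0, spec.noise, (spec.n_cells_per_condition, G))
        rows.append(cells)
        labels.extend([cond] * spec.n_cells_per_condition)
    X = np.vstack(rows)
    n = X.shape[0]

    W = np.random.default_rng(spec.seed + 1).standard_normal((G, spec.embed_dim)) / np.sqrt(G)
    E = X @ W + rng.normal(0.0, 0.01, (n, spec.embed_dim))

    ids = [f"cell{i}" for i in range(n)]
    # expression values live in log-normalized space; may be negative
    ann = CellAnnotations(
        cell_ids=ids,
        cell_type=np.asarray(["cell"] * n, dtype=object),
        condition=np.asarray(labels, dtype=object),
    )
    return {
        "expression": {"cell_ids": ids, "gene_ids": gene_ids, "values": X},
        "annotations": ann,
        "embedding": EmbeddingSet(ids, E),
        "embedding_map": W,
        "ground_truth": effects,
        "control_mean": mu0,
    }
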