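"""N-way K-shot episode sampling and prototypical inference.

Episodes are serializable so several embedding methods can consume
byte-identical support/query sets. Inference is prototype-based: class mean
of support embeddings, cosine distance, softmax over negative distances.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from scembed_eval.datamodel import CellAnnotations, EmbeddingSet


@dataclass
class EpisodeSpec:
    """One N-way K-shot trial: chosen classes, support ids, query ids."""

    episode_id: int
    classes: list[str]
    support_ids: dict[str, list[str]]  # class -> K cell ids
    query_ids: list[str]
    query_labels: list[str]
    seed: int

    def __post_init__(self) -> None:
        support_flat = [c for ids in self.support_ids.values() for c in ids]
        if set(support_flat) & set(self.query_ids):
            raise ValueError("support and query sets overlap")
        sizes = {len(v) for v in self.support_ids.values()}
        if len(sizes) > 1:
            raise ValueError("unequal support sizes across classes")
        if not set(self.query_labels) <= set(self.classes):
            raise ValueError("query labels outside episode classes")


@dataclass
class Prototypes:
    levels: list[str]
    vectors: np.ndarray  # (n_classes, d)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape[0] != len(self.levels):
            raise ValueError("one prototype vector per class required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite prototype")


def sample_episodes(
    ann: CellAnnotations,
    n_way: int,
    k_shot: int,
    n_trials: int,
    query_per_class: int = 50,
    seed: int = 0,
) -> list[EpisodeSpec]:
    """Sample seeded episodes. Classes need >= k_shot + 1 cells to be eligible."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(ann.cell_ids, dtype=object)
    labels = np.asarray(ann.cell_type, dtype=object)
    by_class = {
        str(lvl): ids[labels == lvl]
        for lvl in sorted(set(labels.tolist()), key=str)
    }
    eligible = [c for c, members in by_class.items() if len(members) >= k_shot + 1]
    if len(eligible) < n_way:
        raise ValueError(
            f"need {n_way} classes with >= {k_shot + 1} cells, found {len(eligible)}"
        )
    episodes = []
    for t in range(n_trials):
        classes = sorted(rng.choice(eligible, size=n_way, replace=False).tolist())
        support: dict[str, list[str]] = {}
        query_ids: list[str] = []
        query_labels: list[str] = []
        for cls in classes:
            members = by_class[cls]
            perm = rng.permutation(len(members))
            chosen = members[perm]
            support[cls] = [str(c) for c in chosen[:k_shot]]
            held_out = chosen[k_shot : k_shot + query_per_class]
            query_ids.extend(str(c) for c in held_out)
            query_labels.extend([cls] * len(held_out))
        episodes.append(
            EpisodeSpec(
                episode_id=t,
                classes=classes,
                support_ids=support,
                query_ids=query_ids,
                query_labels=query_labels,
                seed=seed,
            )
        )
    return episodes


def write_episodes(path: str | Path, episodes: list[EpisodeSpec]) -> None:
    payload = [asdict(e) for e in episodes]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_episodes(path: str | Path) -> list[EpisodeSpec]:
    payload = json.loads(Path(path).read_text())
    return [EpisodeSpec(**e) for e in payload]


def compute_prototypes(support_emb: EmbeddingSet, support_labels) -> Prototypes:
    """Class prototypes: mean support embedding per class (level order)."""
    labels = np.asarray(support_labels, dtype=object)
    levels = sorted(set(labels.tolist()), key=str)
    vectors = np.vstack(
        [support_emb.matrix[labels == lvl].mean(axis=0) for lvl in levels]
    )
    return Prototypes([str(lvl) for lvl in levels], vectors)


def prototype_predict(
    support_emb: EmbeddingSet, support_labels, query_emb: EmbeddingSet
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Cosine-prototype classification with softmax over negative distances.

    Returns (predicted labels, class-probability matrix, class levels).
    Argmax ties break toward the first class in level order.
    """
    labels = np.asarray(support_labels, dtype=object)
    if len(set(labels.tolist())) < 2:
        raise ValueError("support must cover at least 2 classes")
    protos = compute_prototypes(support_emb, labels)
    Z = query_emb.matrix
    P = protos.vectors
    z_norm = np.linalg.norm(Z, axis=1)
    p_norm = np.linalg.norm(P, axis=1)
    if np.any(z_norm == 0) or np.any(p_norm == 0):
        raise ValueError("zero-norm embedding: cosine distance undefined")
    cos = (Z @ P.T) / np.outer(z_norm, p_norm)
    dist = 1.0 - cos
    logits = -dist
    logits -= logits.max(axis=1, keepdims=True)
    expd = np.exp(logits)
    probs = expd / expd.sum(axis=1, keepdims=True)
    pred_idx = np.argmax(probs, axis=1)  # argmax takes first max: level order
    preds = np.asarray([protos.levels[i] for i in pred_idx], dtype=object)
    return preds, probs, protos.levels


def run_episode(
    emb: EmbeddingSet, episode: EpisodeSpec
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Evaluate one episode on an embedding; returns preds, probs, levels, truth."""
    support_ids = [c for cls in episode.classes for c in episode.support_ids[cls]]
    support_labels = np.asarray(
        [cls for cls in episode.classes for _ in episode.support_ids[cls]],
        dtype=object,
    )
    support = emb.subset(support_ids)
    query = emb.subset(episode.query_ids)
    preds, probs, levels = prototype_predict(support, support_labels, query)
    return preds, probs, levels, np.asarray(episode.query_labels, dtype=object)
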