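import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scembed_eval.datamodel import CellAnnotations, CountMatrix, EmbeddingSet
from scembed_eval.synthetic import MixtureSpec, make_mixture_embeddings


@pytest.fixture
def small_mixture():
    """300 cells, 3 well-separated types, 10-D."""
    return make_mixture_embeddings(
        MixtureSpec(n_cells=300, n_types=3, dim=10, type_separation=12.0, seed=11)
    )


@pytest.fixture
def batched_mixture():
    """2 batches with a moderate constant shift."""
    return make_mixture_embeddings(
        MixtureSpec(
            n_cells=400, n_types=2, n_batches=2, dim=8,
            type_separation=10.0, batch_shift=4.0, seed=5,
        )
    )


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(0)
    ids = [f"c{i}" for i in range(20)]
    emb = EmbeddingSet(ids, rng.standard_normal((20, 4)))
    counts = CountMatrix(ids, [f"g{j}" for j in range(6)], rng.poisson(3, (20, 6)).astype(float))
    ann = CellAnnotations(
        cell_ids=ids,
        cell_type=np.asarray(["A"] * 10 + ["B"] * 10, dtype=object),
        batch=np.asarray(["b1", "b2"] * 10, dtype=object),
        spatial_xy=rng.random((20, 2)),
    )
    return emb, counts, ann
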