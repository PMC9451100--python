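import numpy as np
import pytest

from toxmlpath.datamodel import MultiLabelDataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dataset(rng, n=30, dim=6, L=4, prevalences=None):
    """Small random dataset with at least one positive per label."""
    if prevalences is None:
        prevalences = np.linspace(0.2, 0.6, L)
    X = rng.normal(size=(n, dim))
    Y = (rng.uniform(size=(n, L)) < prevalences).astype(int)
    for l in range(L):  # guarantee at least two positives so bags exist
        if Y[:, l].sum() < 2:
            Y[rng.choice(n, 2, replace=False), l] = 1
    return MultiLabelDataset(
        features=X,
        labels=Y,
        gene_ids=[f"g{i}" for i in range(dim)],
        label_names=[f"l{i}" for i in range(L)],
        sample_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)
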