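import numpy as np
import pandas as pd
import pytest

from pdd.dataset import AV, CategoricalDataset, build_address_table
from pdd.synthetic import fig1_spec, generate


def random_dataset(rng, m=40, attrs=("A1", "A2", "A3", "A4"), alphabet="xyz", labeled=False):
    """Small uniform-random categorical dataset for oracle comparisons."""
    eids = list(range(1, m + 1))
    cells = pd.DataFrame(
        {a: rng.choice(list(alphabet), size=m) for a in attrs}, index=eids
    )
    labels = None
    if labeled:
        labels = {e: str(c) for e, c in zip(eids, rng.choice(["u", "v"], size=m))}
    return CategoricalDataset(eids, list(attrs), cells, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fig1_dataset():
    dataset, manifest = generate(fig1_spec(seed=1))
    return dataset, manifest


@pytest.fixture(scope="session")
def fig1_table(fig1_dataset):
    dataset, _ = fig1_dataset
    return build_address_table(dataset)
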