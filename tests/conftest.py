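import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from structsep import (
    LabeledDataset,
    ProteinRecord,
    SyntheticConfig,
    generate_dataset,
    load_kidera_table,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def kidera():
    return load_kidera_table()


@pytest.fixture(scope="session")
def kidera_dict():
    """Kidera table as residue -> list, for the brute-force APF oracle."""
    from structsep.sequence_io import CANONICAL_ORDER

    table = load_kidera_table()
    return {k: table.values[i].tolist() for i, k in enumerate(CANONICAL_ORDER)}


@pytest.fixture
def tiny_dataset():
    """Three-class toy dataset with hand-written sequences."""
    records = [
        ProteinRecord("a1", "AAAARRRR", "alpha"),
        ProteinRecord("a2", "AARRARAR", "alpha"),
        ProteinRecord("b1", "GGGGLLLL", "beta"),
        ProteinRecord("b2", "GLGLGLGL", "beta"),
        ProteinRecord("m1", "AAGGRRLL", "mixed"),
        ProteinRecord("m2", "AGRLAGRL", "mixed"),
    ]
    return LabeledDataset(records, ["alpha", "beta", "mixed"])


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but non-trivial synthetic dataset shared across tests."""
    config = SyntheticConfig(
        n_per_class=20, length_range=(60, 150), seed=11, delta=0.5
    )
    dataset, truth = generate_dataset(config)
    return dataset, truth
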