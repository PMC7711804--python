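"""Shared fixtures: synthetic study data, encoded datasets, a trained bundle.

The synthetic set uses the study conditions throughout: 250 immunogens +
250 non-immunogens, lengths 30-200, compositional signal 0.8, ACC lag 8.
Session scope keeps the expensive encodings and the three-member bundle
shared across test modules.
"""

import numpy as np
import pytest

from accvax.data import (SplitSpec, generate_synthetic_dataset,
                         length_stratified_split)
from accvax.encoding import build_feature_matrix, default_descriptor_table
from accvax.predictor import fit_vaxijen_predictor


@pytest.fixture(scope="session")
def table():
    return default_descriptor_table()


@pytest.fixture(scope="session")
def synthetic_records():
    return generate_synthetic_dataset(
        n_pos=250, n_neg=250, length_range=(30, 200), signal_strength=0.8, seed=1)


@pytest.fixture(scope="session")
def synthetic_split(synthetic_records):
    return length_stratified_split(synthetic_records, SplitSpec(seed=1))


@pytest.fixture(scope="session")
def train_dataset(synthetic_split, table):
    return build_feature_matrix(synthetic_split[0], table, lag_max=8)


@pytest.fixture(scope="session")
def test_dataset(synthetic_split, table):
    return build_feature_matrix(synthetic_split[1], table, lag_max=8)


@pytest.fixture(scope="session")
def small_dataset(table):
    """A smaller labeled set for cross-validation-heavy tests."""
    records = generate_synthetic_dataset(
        n_pos=60, n_neg=60, length_range=(30, 80), signal_strength=0.8, seed=2)
    return build_feature_matrix(records, table, lag_max=8)


@pytest.fixture(scope="session")
def bundle(train_dataset, table):
    return fit_vaxijen_predictor(train_dataset, seed=1, table=table, lag_max=8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))
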