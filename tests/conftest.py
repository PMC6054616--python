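"""Shared fixtures: the default simulated experiment, computed once."""

import pytest

from fluorostage import generate_dataset, normalize_dataset
from fluorostage.classify import classify_dataset
from fluorostage.peaks import fit_dataset

#: Seed of the reference simulated experiment used across the suite.
DEFAULT_SEED = 17


@pytest.fixture(scope="session")
def default_dataset():
    """60 spectra per group at default presets and noise."""
    return generate_dataset(n_per_group=60, seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def normalized_dataset(default_dataset):
    return normalize_dataset(default_dataset)


@pytest.fixture(scope="session")
def peaks_table(normalized_dataset):
    """Five-band Gaussian decomposition of every default spectrum."""
    return fit_dataset(normalized_dataset)


@pytest.fixture(scope="session")
def staging_result(normalized_dataset):
    """Default 50/10 PCA-LDA staging run."""
    return classify_dataset(normalized_dataset, seed=DEFAULT_SEED)
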