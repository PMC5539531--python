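import numpy as np
import pytest

from flavormine.data import normalize_apply, normalize_fit
from flavormine.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the default 90x20 fused dataset (5 brands x 18 samples)."""
    return generate_dataset(GeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def scaled_dataset(default_dataset):
    table, truth = default_dataset
    scaler = normalize_fit(table)
    return normalize_apply(scaler, table), truth


@pytest.fixture(scope="session")
def crisp_dataset():
    """Nearly noise-free draw: classes are separable in the informative subspace."""
    return generate_dataset(GeneratorConfig(within_class_sd=0.1), seed=23)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
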