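import numpy as np
import pandas as pd
import pytest

from lncnet.expression import ExpressionMatrix
from lncnet.synthetic import SyntheticConfig, generate_expression


@pytest.fixture(scope="session")
def small_config():
    """Compact planted-module dataset: 5 modules over 60+30 genes, 20 samples."""
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def noise_free_config():
    return SyntheticConfig(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_expression(small_config)


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    return generate_expression(noise_free_config)


@pytest.fixture()
def toy_matrix():
    """3 genes x 6 samples, nothing planted."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.gamma(2.0, 5.0, size=(3, 6)),
        index=["cod0", "cod1", "lnc0"],
        columns=[f"s{i}" for i in range(6)],
    )
    biotype = pd.Series(
        {"cod0": "coding", "cod1": "coding", "lnc0": "lncRNA"}
    )
    return ExpressionMatrix(values, biotype)
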