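import numpy as np
import pytest

from shortstop import synthetic_data as sd
from shortstop.pipeline import site_model_rows_for


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic population (175 birds, 68 sites, seed 0)."""
    return sd.generate(sd.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Detection-to-regression-table products for the default population."""
    return site_model_rows_for(default_dataset)


@pytest.fixture(scope="session")
def default_rows(default_analysis):
    return default_analysis["rows"]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
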