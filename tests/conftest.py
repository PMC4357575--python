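import numpy as np
import pandas as pd
import pytest

from frailtycompare.deficits import default_codebook
from frailtycompare.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-row synthetic cohort shared by cheap tests."""
    table, truth = generate(GeneratorConfig(n=300, seed=7))
    return table


@pytest.fixture(scope="session")
def default_cohort():
    """The default-size (n=4000) synthetic cohort at a fixed seed."""
    table, truth = generate(GeneratorConfig(seed=1))
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
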