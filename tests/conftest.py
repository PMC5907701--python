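import numpy as np
import pytest

from betaridge import RunConfig, generate_protein
from betaridge.pipeline import ProteinData


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_protein():
    """One deterministic synthetic protein reused by read-only tests."""
    return generate_protein("fix", 80, seed=1234)


@pytest.fixture(scope="session")
def small_protein_data(small_protein):
    p = small_protein
    return ProteinData(p.name, p.cmap, p.ss_profile, p.truth, p.ss_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
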