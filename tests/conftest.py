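import numpy as np
import pytest

from msiplex import generate_scaffold, load_default_pdfs, populate_sample
from msiplex.scaffold import ScaffoldConfig


@pytest.fixture(scope="session")
def small_scaffold():
    """A compact two-crypt tissue scene shared by read-only tests."""
    config = ScaffoldConfig(width=512, height=512, crypt_count=2, seed=42)
    return generate_scaffold(config)


@pytest.fixture(scope="session")
def default_pdfs():
    return load_default_pdfs()


@pytest.fixture(scope="session")
def small_scaffold_organelles(small_scaffold, default_pdfs):
    rng = np.random.default_rng(1)
    return populate_sample(small_scaffold, default_pdfs, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
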