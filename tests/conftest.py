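import numpy as np
import pytest
from hypothesis import settings

from thermoraac import GeneratorSpec, builtin_scheme, generate
from thermoraac.sequence_io import AMINO_ACIDS

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def susko():
    return builtin_scheme("susko19")


@pytest.fixture(scope="session")
def dayhoff():
    return builtin_scheme("dayhoff6")


@pytest.fixture(scope="session")
def identity():
    return builtin_scheme("identity20")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_sequence(rng):
    """Factory for random sequences over the 20-letter alphabet."""

    def make(length: int) -> str:
        return "".join(rng.choice(list(AMINO_ACIDS), size=length))

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A small, well-separated synthetic dataset for pipeline-level tests."""
    return generate(GeneratorSpec(n_pos=25, n_neg=25, length_range=(60, 140), seed=11))
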