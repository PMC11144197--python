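import random

import pytest

from telovar import ModelParams, ReadRecord


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def noise_free_model():
    """Symmetric two-allele model with no degeneracy."""
    return ModelParams(p_x_wt=0.5, p_x_var=0.5, rho=0.5, degeneracy=0.0)


def make_read(bases: str, read_id: str = "r") -> ReadRecord:
    return ReadRecord(read_id, bases)


@pytest.fixture
def read_factory():
    return make_read
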