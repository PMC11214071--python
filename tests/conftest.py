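import numpy as np
import pytest

from plmlora import ArchConfig, TokenSequence, build_model


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchConfig(d_model=16, n_layers=2, n_heads=2, ffn_dim=32, max_len=64, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_arch):
    return build_model(tiny_arch)


@pytest.fixture()
def seq16():
    return TokenSequence.from_string("ACDEFGHIKLMNPQRS")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
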