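import numpy as np
import pytest

from plastimod import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def neutral_params():
    """Two equal demes, no selection, light continuous migration."""
    return ModelParams.symmetric(N=100, s=0.0, p=0.0, e=1, intro_prob=0.0)


@pytest.fixture
def balanced_params():
    """Symmetric opposing selection with limited continuous migration: the
    regime that maintains modifier polymorphism."""
    return ModelParams.symmetric(N=200, s=0.03, p=1.0, e=4, r=0.5, intro_prob=0.001)
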