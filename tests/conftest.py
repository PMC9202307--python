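import numpy as np
import pytest

from alchemsmc import (
    GaussianLadder,
    Lambda0MoveSpec,
    SMCConfig,
    SoftCorePair,
    TorsionalToy,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def torsional():
    return TorsionalToy(a=3.0, b=0.0)


@pytest.fixture
def ladder():
    return GaussianLadder(s0=2.0, s1=1.0)


@pytest.fixture
def pair_system():
    return SoftCorePair()


def small_config(**overrides) -> SMCConfig:
    """A cheap engine configuration for unit-level end-to-end runs."""
    defaults = dict(
        n_walkers=200,
        oversample_factor=5,
        propagation_block=20,
        max_propagation_blocks=20,
        rng_seed=0,
    )
    defaults.update(overrides)
    return SMCConfig(**defaults)


@pytest.fixture
def torsion_move():
    return Lambda0MoveSpec(kind="torsion")


@pytest.fixture
def direct_move():
    return Lambda0MoveSpec(kind="direct")
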