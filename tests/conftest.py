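import numpy as np
import pytest

from chiradsorb import LatticeState, MCSettings, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def racemic_params():
    """Zero-field, non-interacting parameters at 460 K."""
    return ModelParams(temperature=460.0)


@pytest.fixture
def asp_params():
    """Achiral-surface parameters at 460 K with a 2.31 kJ/mol exchange energy."""
    return ModelParams(temperature=460.0, exch_energy=2310.0)


@pytest.fixture
def fast_settings():
    """Cheap sampler settings for smoke-level MC tests."""
    return MCSettings(seed=11, burn_in_sweeps=100, measure_sweeps=400, batches=10)


def random_lattice(side: int, seed: int) -> LatticeState:
    return LatticeState.random_racemic(side, np.random.default_rng(seed))
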