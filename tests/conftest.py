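import numpy as np
import pytest

from torquetweezers.params import BeadParams, ModelParams, SimConfig


@pytest.fixture
def params():
    """Low-salt DNA defaults: A=48 nm, C=110 nm, P=20 nm, 7.9 kbp."""
    return ModelParams()


@pytest.fixture
def bead():
    return BeadParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_sim_config(**kwargs):
    defaults = dict(seed=20260929, frame_rate=60.0, dwell=100.0,
                    n_molecules=10, force=2.0,
                    turn_schedule=tuple(range(-30, 31)))
    defaults.update(kwargs)
    return SimConfig(**defaults)
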