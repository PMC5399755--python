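import numpy as np
import pytest

from osmodrop.simulate import SwimSimParams, constant_rate, simulate_swim_video


@pytest.fixture(scope="session")
def quiet_swim():
    """20 s swim recording with no turns (plus its ground truth)."""
    params = SwimSimParams(duration_s=20.0, seed=7)
    return simulate_swim_video(params)


@pytest.fixture(scope="session")
def turning_swim():
    """60 s recording with turns at a constant 15/min (plus ground truth)."""
    params = SwimSimParams(duration_s=60.0,
                           turn_rate_fn=constant_rate(15.0), seed=21)
    return simulate_swim_video(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
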