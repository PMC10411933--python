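import math

import numpy as np
import pytest

from aimkin.performer import PerformerParams, simulate_trial
from aimkin.task import TrialSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return PerformerParams()


def make_spec(distance=1.0, angle=0.0, context="point"):
    a = math.radians(angle)
    return TrialSpec(
        context=context,
        target_angle=float(angle),
        target_distance=float(distance),
        target_position=(distance * math.cos(a), distance * math.sin(a)),
    )


@pytest.fixture
def noiseless_trial(rng):
    """A deterministic trial with exactly one correction (undershoot 0.8
    leaves the cursor 0.2 au short of a 1-au target of radius 0.1)."""
    params = PerformerParams().noiseless(undershoot_frac=0.8)
    return simulate_trial(params, make_spec(), None, rng)
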