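import numpy as np
import pytest

from muforce import MotorUnitDecomposition, benchmark_scene
from muforce.simulate import CYCLE_S, TRAIN_CYCLES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trapezoid_scene():
    """One seeded contract/relax scene shared across the session."""
    return benchmark_scene("trapezoid", seed=0, G=7, snr_db=10.0)


@pytest.fixture(scope="session")
def trained(trapezoid_scene):
    """A full decomposition trained on the scene's first three cycles,
    MVC-calibrated on the training split."""
    rec, _force, _truth = trapezoid_scene
    train = rec.slice_time(0, TRAIN_CYCLES * CYCLE_S)
    results = MotorUnitDecomposition(train).fit(seed=0)
    return results.calibrate_mvc(train)
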