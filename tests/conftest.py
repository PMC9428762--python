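import numpy as np
import pytest

from heelpad.synthetic import GaitParams, KVParams, simulate_stance


@pytest.fixture
def central_kv() -> KVParams:
    """Material parameters at the healthy-group central values."""
    return KVParams(E=265.5, eta=66.59, h0=14.85)


@pytest.fixture
def recovery_gait() -> GaitParams:
    """Gait used for noise-free recovery studies.

    The slow unloading (1.4 s stance, peak at 40%) keeps the model
    stress non-negative even at the most compliant/viscous parameter
    combinations exercised by the recovery grid, so the forward
    simulation never clips.
    """
    return GaitParams(stance_duration=1.4, loading_fraction=0.4)


@pytest.fixture
def clean_recording(central_kv, recovery_gait):
    return simulate_stance(central_kv, recovery_gait)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
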