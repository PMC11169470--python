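import numpy as np
import pytest

from ilvis import trajectory_sim as ts
from ilvis.mea_preprocess import RecordingSet
from ilvis.synthetic_mea import SurrogateSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def line3():
    """Tiny hand-checkable line: p=(1,2,3), d=(0.01,0.02,0.03)."""
    return ts.LineSpec(intercepts=np.array([1.0, 2.0, 3.0]),
                       gradients=np.array([0.01, 0.02, 0.03]))


@pytest.fixture
def traj100():
    """The default study trajectory: D=100, half the dimensions squared."""
    line = ts.make_line(100, seed=0)
    return ts.make_trajectory(line, seed=1000, label="T1")


@pytest.fixture(scope="session")
def surrogate_recordings():
    """Three short surrogate MEA timepoints with rising firing rate."""
    spec = SurrogateSpec(duration_s=20.0, spike_rates_hz=(1.0, 3.0, 6.0), seed=7)
    return generate(spec)


@pytest.fixture
def zero_recording():
    return RecordingSet(signals=np.zeros((3, 25_000)), fs=5000.0, timepoint=1)
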