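import numpy as np
import pytest

from reachval.trajectory_io import REQUIRED_MARKERS, TrialRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    n=50,
    fs=100.0,
    sensor="gold",
    rng=None,
    motion=None,
    target=(300.0, 0.0, 100.0),
):
    """Small valid recording; random-walk markers unless ``motion`` given."""
    rng = rng or np.random.default_rng(0)
    times = np.arange(n) / fs
    markers = {}
    for name in REQUIRED_MARKERS:
        if motion is not None:
            markers[name] = motion(name, times)
        else:
            base = rng.uniform(-200, 200, 3)
            markers[name] = base + np.cumsum(rng.normal(0, 1.0, (n, 3)), axis=0)
    return TrialRecording(
        subject_id="S01",
        sensor=sensor,
        condition="spontaneous",
        assessed_side="right",
        times=times,
        markers=markers,
        target=np.asarray(target, float),
    )


@pytest.fixture
def small_recording(rng):
    return make_recording(rng=rng)
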