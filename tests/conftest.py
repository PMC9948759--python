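import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_trace(segments, t0=0.0, x0=0.0):
    """Build a (times, positions) polyline from (velocity µm/min, duration s)
    segments — the hand-constructed input format for classification tests."""
    times, positions = [t0], [x0]
    for v, dur in segments:
        times.append(times[-1] + dur)
        positions.append(positions[-1] + v / 60.0 * dur)
    return np.array(times), np.array(positions)
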