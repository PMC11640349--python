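import numpy as np
import pytest

import tdsliking as tl
from tdsliking.sensory_io import PressEvent, Trial


def build_trial(presses, duration=1.0, pid="p01", idx=1, normalized=False):
    """Trial from (time, kind, value) tuples plus start/stop bookkeeping."""
    events = [PressEvent(0.0, "start")]
    events += [PressEvent(t, kind, val) for t, kind, val in presses]
    events += [PressEvent(duration, "stop")]
    tr = Trial(pid, idx, events, duration_s=duration)
    tr.normalized = normalized
    return tr


def tds_trial(presses, duration=1.0, normalized=True, pid="p01", idx=1):
    """Normalized TDS trial from (time, attribute) tuples."""
    return build_trial(
        [(t, "tds_select", a) for t, a in presses],
        duration=duration, normalized=normalized, pid=pid, idx=idx,
    )


def liking_trial(presses, duration=1.0, normalized=True, pid="p01", idx=1):
    """Normalized liking trial from (time, score) tuples."""
    return build_trial(
        [(t, "liking_score", s) for t, s in presses],
        duration=duration, normalized=normalized, pid=pid, idx=idx,
    )


@pytest.fixture(scope="session")
def panel_log():
    """Default 31 x 3 strawberry-like synthetic panel."""
    return tl.simulate_panel(seed=1)


@pytest.fixture(scope="session")
def participants(panel_log):
    return tl.participant_average(panel_log)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_curve_pairs(n_pairs, m=7, seed=0, attributes=None):
    """Random valid CurvePairs on a small grid (for readout tests)."""
    attrs = attributes or tl.AttributeSet()
    g = np.random.default_rng(seed)
    grid = tl.TimeGrid(m)
    pairs = []
    for _ in range(n_pairs):
        props = g.dirichlet(np.ones(attrs.n), size=m) * g.uniform(0.5, 1.0)
        lik = g.uniform(0.0, 9.0, size=m)
        pairs.append(tl.CurvePair(
            tl.TDSCurveSet(grid, attrs, props),
            tl.LikingCurve(grid, lik),
        ))
    return pairs
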