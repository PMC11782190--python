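import numpy as np
import pytest

from orthomorph.signal_prep import Recording


def make_recording(t, sbp, pp=45.0, rr=None, participant_id="T"):
    """Recording with explicit beat times/SBP; DBP a fixed offset below SBP."""
    t = np.asarray(t, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    if rr is None:
        rr = np.diff(t, prepend=t[0] - 0.8)
        rr = np.clip(rr, 0.3, None)
    return Recording(participant_id, t, sbp, sbp - pp, rr)


def flat_recording(level=120.0, t0=-70.0, t1=125.0, step=0.8, jitter=None, rng=None):
    """Beats at (optionally jittered) regular intervals, constant SBP."""
    t = np.arange(t0, t1, step)
    if jitter:
        rng = np.random.default_rng(rng)
        t = t + rng.uniform(-jitter, jitter, size=t.size)
        t = np.sort(t)
    sbp = np.full(t.size, float(level))
    return make_recording(t, sbp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
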