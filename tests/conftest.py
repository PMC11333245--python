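import numpy as np
import pytest

import sleephrv as sh
from sleephrv.series import BeatSeries


@pytest.fixture(scope="session")
def non_recording():
    """One full synthetic non-pregnancy recording (7 h, seed 1)."""
    cfg = sh.config_for_group("non", duration_h=7.0, seed=1)
    hyp = sh.generate_hypnogram(cfg)
    beats = sh.generate_rr(cfg, hyp)
    return cfg, hyp, beats


@pytest.fixture(scope="session")
def regular_beats():
    """Beats at exactly 1.0 s spacing for 6 h."""
    return BeatSeries(np.arange(0.0, 6 * 3600 + 1, 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def rsa_beats(duration_s=3600.0, mean_rr=0.9, amp=0.05, freq=0.25):
    """Beats whose RR follows mean + amp*sin(2*pi*freq*t)."""
    times = [0.0]
    t = 0.0
    while t < duration_s:
        t += mean_rr + amp * np.sin(2 * np.pi * freq * t)
        times.append(t)
    return BeatSeries(np.asarray(times))
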