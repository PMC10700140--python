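import numpy as np
import pytest

import boutwise as bw
from boutwise import normalize


@pytest.fixture(scope="session")
def default_train():
    return bw.generate_lick_train(6, seed=11)


@pytest.fixture(scope="session")
def phasic_session(default_train):
    """A moderate-rate synthetic session with the default phasic kernel."""
    raw, truth = bw.generate_photometry_session(
        default_train, params=bw.KernelParams(), seed=7, rate=101.73
    )
    return default_train, raw, truth


@pytest.fixture(scope="session")
def phasic_trace4(phasic_session):
    """The phasic session normalized against its 10-min baseline at 4 Hz."""
    _, raw, _ = phasic_session
    trace = bw.zscore_trace(bw.fit_isosbestic_baseline(raw, (0.0, 600.0)))
    return normalize.resample_and_smooth(trace, target_rate=4.0)


def make_trace(z, rate=4.0, t0=0.0, baseline_window=(0.0, 1.0)):
    """Wrap a plain z array into a NormalizedTrace for direct unit tests."""
    z = np.asarray(z, dtype=float)
    time = t0 + np.arange(len(z)) / rate
    return normalize.NormalizedTrace(
        time=time,
        signal=z.copy(),
        f_normalized=np.zeros_like(z),
        rate=rate,
        baseline_window=baseline_window,
        z=z,
        mu=0.0,
        sigma=1.0,
    )


def lick_train(times, duration=None, source="b1"):
    times = np.asarray(times, dtype=float)
    if duration is None:
        duration = (times[-1] + 1.0) if len(times) else 0.0
    return bw.EventTrain(
        times,
        np.full(len(times), "lick", dtype=object),
        np.full(len(times), source, dtype=object),
        float(duration),
    )
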