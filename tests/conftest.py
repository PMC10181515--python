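import dataclasses

import numpy as np
import pytest

from apneascreen.preprocessing import Frame, RRSeries
from apneascreen.records import SignalTrace
from apneascreen.synthetic import for_group, synth_record


def modulated_frame(freq_hz: float, depth: float = 0.1, base_rr: float = 0.9,
                    noise: float = 0.0, seed: int = 0, central_minute: int = 2) -> Frame:
    """Frame whose RR segment carries a pure sinusoidal modulation."""
    rng = np.random.default_rng(seed)
    t0 = 60.0 * (central_minute - 2)
    t = t0
    times = []
    while t < t0 + 310:
        rr = base_rr * (1 + depth * np.sin(2 * np.pi * freq_hz * t))
        if noise:
            rr *= np.exp(noise * rng.standard_normal())
        times.append(t)
        t += rr
    rrs = RRSeries.from_beat_times(np.array(times[1:]))
    grid = t0 + np.arange(300.0)
    spo2 = SignalTrace(np.zeros(300), fs=1.0, times=grid)
    return Frame(central_minute=central_minute,
                 rr_segment=rrs.restrict(t0, t0 + 300),
                 spo2_segment=spo2, label=0)


@pytest.fixture(scope="session")
def short_desat_record():
    cfg = dataclasses.replace(for_group("desaturating", seed=11), duration_min=20)
    return synth_record(cfg)


@pytest.fixture(scope="session")
def short_control_record():
    cfg = dataclasses.replace(for_group("control", seed=12), duration_min=20)
    return synth_record(cfg)


@pytest.fixture(scope="session")
def cvhr_frame():
    return modulated_frame(0.02, depth=0.12, noise=0.01)


@pytest.fixture(scope="session")
def e2e_cohort():
    """Three-phenotype cohort used by the end-to-end tests (scaled-down
    recording length to keep the suite fast)."""
    from apneascreen.synthetic import synth_cohort

    return synth_cohort(6, 6, 4, seed=42, duration_min=60)


@pytest.fixture(scope="session")
def e2e_features(e2e_cohort):
    from apneascreen.pipeline import extract_cohort_features

    return extract_cohort_features(e2e_cohort, m=8, tau=5)
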