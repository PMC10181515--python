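"""Seeded generator of labelled synthetic overnight recordings.

The generator emulates the statistical signatures the screening features
measure, not cardiorespiratory physiology:

* apneic minutes carry a brady-tachycardia oscillation of the RR series
  (cyclic variation of heart rate, period 20-60 s, i.e. 0.017-0.05 Hz);
* normal minutes carry respiratory sinus arrhythmia (~0.25 Hz) instead;
* for desaturating subjects each apneic event triggers a saw-tooth SpO2
  desaturation starting 10-30 s after event onset (slow drop, fast
  resaturation); non-desaturating subjects get rare/shallow dips so their
  oxygen-desaturation index stays below half their AHI;
* normal SpO2 is a stable 96-99% baseline with sensor noise, quantized to
  0.1% steps.

Apneic minutes are placed by a two-state Markov chain whose stationary
apneic fraction matches ``target_ahi / 60``, with multi-minute runs for
patients to create the consecutive-event clusters that motivate the
5-minute variance feature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import RRSeries
from .records import MinuteLabels, SignalTrace, SubjectRecord

#: SpO2 dips at least this deep (%) count toward the desaturation index
ODI_DIP_THRESHOLD = 3.0


@dataclass
class PhenotypeConfig:
    group: str = "control"
    target_ahi: float = 2.0            # events/h proxy (apneic minutes per hour)
    cvhr_period_s: float = 40.0        # brady-tachycardia cycle, 20-60 s
    cvhr_depth: float = 0.12           # fractional RR modulation in apneic minutes
    desat_depth_pct: float = 4.0       # typical desaturation depth, %
    desat_prob: float = 1.0            # chance an apneic event desaturates
    deep_dip_prob: float = 0.1        # non-desaturating: chance of a >=3% dip
    shallow_depth_pct: float = 1.5     # non-desaturating: sub-threshold dip depth
    desat_onset_delay_s: tuple[float, float] = (10.0, 30.0)
    desat_drop_s: float = 15.0         # duration of the slow linear drop
    resat_rate: float = 0.6            # fast resaturation, %/s
    baseline_spo2: float = 97.0        # % in [96, 99]
    rsa_freq_hz: float = 0.25
    rsa_depth: float = 0.04
    base_rr_s: float = 0.95
    rr_noise: float = 0.03             # lognormal sigma of beat-to-beat jitter
    spo2_noise: float = 0.15           # sensor noise SD, %
    spo2_fs: float = 1.0
    apnea_run_min: float = 4.0         # mean apneic run length, minutes
    duration_min: int = 480
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_ahi <= 60:
            raise ValueError("target_ahi must be in [0, 60] (minutes-per-hour proxy)")
        if not 20 <= self.cvhr_period_s <= 60:
            raise ValueError("cvhr_period_s must lie in [20, 60] s")
        if not 96 <= self.baseline_spo2 <= 99:
            raise ValueError("baseline_spo2 must lie in [96, 99] %")
        lo, hi = self.desat_onset_delay_s
        if not 10 <= lo <= hi <= 30:
            raise ValueError("desaturation onset delay must lie in [10, 30] s")


def for_group(group: str, seed: int = 0, **overrides) -> PhenotypeConfig:
    """Default configuration for one of the three phenotypes."""
    base = {
        "control": dict(target_ahi=2.0, apnea_run_min=1.0, desat_prob=0.3),
        "desaturating": dict(target_ahi=45.0, desat_prob=0.9),
        "non_desaturating": dict(target_ahi=40.0, desat_prob=0.0, deep_dip_prob=0.1),
    }[group]
    base.update(overrides)
    return PhenotypeConfig(group=group, seed=seed, **base)


def _markov_labels(cfg: PhenotypeConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.duration_min
    p = cfg.target_ahi / 60.0
    if p == 0:
        return np.zeros(n, dtype=int)
    run = max(cfg.apnea_run_min, 1.0)
    p_exit = 1.0 / run                       # apneic -> normal
    p_enter = min(1.0, p_exit * p / max(1e-12, 1.0 - p))
    labels = np.zeros(n, dtype=int)
    state = int(rng.random() < p)
    for i in range(n):
        labels[i] = state
        if state:
            state = 0 if rng.random() < p_exit else 1
        else:
            state = 1 if rng.random() < p_enter else 0
    return labels


def _apneic_events(labels: np.ndarray, period: float, guard_s: float = 0.0) -> list[float]:
    """Event onset times: one event per CVHR cycle inside each apneic run.

    ``guard_s`` keeps the last event's span (onset delay + desaturation)
    inside the labelled run — the run ends when breathing resumes, so the
    nadir of the final desaturation falls near the run end, not after it.
    """
    events = []
    n = labels.size
    i = 0
    while i < n:
        if labels[i]:
            j = i
            while j < n and labels[j]:
                j += 1
            t = 60.0 * i
            end = max(60.0 * j - guard_s, t + 1.0)
            while t < end:
                events.append(t)
                t += period
            i = j
        else:
            i += 1
    return events


def _rr_series(cfg: PhenotypeConfig, labels: np.ndarray, rng: np.random.Generator) -> RRSeries:
    total = 60.0 * cfg.duration_min
    omega_cvhr = 2 * np.pi / cfg.cvhr_period_s
    omega_rsa = 2 * np.pi * cfg.rsa_freq_hz
    phase_c = rng.uniform(0, 2 * np.pi)
    phase_r = rng.uniform(0, 2 * np.pi)
    times = []
    t = rng.uniform(0, cfg.base_rr_s)
    n_min = labels.size
    while t < total:
        minute = min(int(t // 60.0), n_min - 1)
        if labels[minute]:
            mod = cfg.cvhr_depth * np.sin(omega_cvhr * t + phase_c)
        else:
            mod = cfg.rsa_depth * np.sin(omega_rsa * t + phase_r)
        rr = cfg.base_rr_s * (1.0 + mod) * np.exp(cfg.rr_noise * rng.standard_normal())
        rr = max(rr, 0.25)
        times.append(t)
        t += rr
    return RRSeries.from_beat_times(np.array(times))


def _spo2_trace(
    cfg: PhenotypeConfig, labels: np.ndarray, rng: np.random.Generator
) -> tuple[SignalTrace, int]:
    """Baseline + noise + per-event saw-tooth desaturations.

    Returns the trace and the number of dips deep enough (>= 3%) to count
    toward the oxygen-desaturation index.
    """
    n = int(60.0 * cfg.duration_min * cfg.spo2_fs)
    t = np.arange(n) / cfg.spo2_fs
    dip = np.zeros(n)
    deep_dips = 0
    guard = cfg.desat_onset_delay_s[1] + cfg.desat_drop_s
    for onset in _apneic_events(labels, cfg.cvhr_period_s, guard_s=guard):
        u = rng.random()
        if u < cfg.desat_prob:
            depth = max(0.5, cfg.desat_depth_pct + 0.8 * rng.standard_normal())
        elif u < cfg.desat_prob + cfg.deep_dip_prob:
            depth = ODI_DIP_THRESHOLD + abs(0.5 * rng.standard_normal())
        elif cfg.group == "non_desaturating" and rng.random() < 0.5:
            depth = cfg.shallow_depth_pct * rng.uniform(0.5, 1.0)
        else:
            continue
        if depth >= ODI_DIP_THRESHOLD:
            deep_dips += 1
        delay = rng.uniform(*cfg.desat_onset_delay_s)
        t_on = onset + delay
        drop_end = t_on + cfg.desat_drop_s
        resat_end = drop_end + depth / cfg.resat_rate
        rel = t - t_on
        event = np.zeros(n)
        dropping = (rel >= 0) & (t < drop_end)
        event[dropping] = -depth * rel[dropping] / cfg.desat_drop_s
        rising = (t >= drop_end) & (t < resat_end)
        event[rising] = -depth + cfg.resat_rate * (t[rising] - drop_end)
        dip = np.minimum(dip, event)
    v = cfg.baseline_spo2 + dip + cfg.spo2_noise * rng.standard_normal(n)
    v = np.clip(np.round(v, 1), 50.5, 100.0)  # oximeter quantization, 0.1% steps
    return SignalTrace(v, fs=cfg.spo2_fs), deep_dips


def render_ecg(rr: RRSeries, fs: float = 100.0, noise: float = 0.01,
               seed: int = 0) -> SignalTrace:
    """Render a stylized ECG by placing a QRS-like template at each beat."""
    rng = np.random.default_rng(seed)
    duration = rr.beat_times[-1] + 1.0
    n = int(duration * fs)
    x = noise * rng.standard_normal(n)
    tt = np.arange(-0.05, 0.05, 1 / fs)
    template = (
        1.0 * np.exp(-(tt**2) / (2 * 0.008**2))       # R
        - 0.15 * np.exp(-((tt + 0.025) ** 2) / (2 * 0.008**2))  # Q
        - 0.2 * np.exp(-((tt - 0.025) ** 2) / (2 * 0.008**2))   # S
    )
    beat_times = np.concatenate([[rr.beat_times[0] - rr.intervals[0]], rr.beat_times])
    for bt in beat_times:
        i0 = int(round((bt - 0.05) * fs))
        for k, val in enumerate(template):
            if 0 <= i0 + k < n:
                x[i0 + k] += val
    # slow T-wave-ish baseline wander
    x += 0.05 * np.sin(2 * np.pi * 0.3 * np.arange(n) / fs)
    return SignalTrace(x, fs=fs)


def synth_record(cfg: PhenotypeConfig, *, with_ecg: bool = False) -> SubjectRecord:
    """Generate one labelled overnight recording from a phenotype config."""
    rng = np.random.default_rng(cfg.seed)
    labels = _markov_labels(cfg, rng)
    rr = _rr_series(cfg, labels, rng)
    spo2, deep_dips = _spo2_trace(cfg, labels, rng)
    hours = cfg.duration_min / 60.0
    ahi_manual = float(60.0 * labels.mean())
    odi_manual = deep_dips / hours
    if cfg.group == "non_desaturating" and not odi_manual < ahi_manual / 2:
        raise ValueError(
            f"non-desaturating config produced ODI={odi_manual:.1f} "
            f">= AHI/2={ahi_manual / 2:.1f}; lower deep_dip_prob"
        )
    ecg = None
    if with_ecg:
        ecg = render_ecg(rr, seed=cfg.seed + 1)
    return SubjectRecord(
        id=f"{cfg.group[:4]}_{cfg.seed}",
        spo2=spo2,
        labels=MinuteLabels(labels),
        ecg=ecg,
        rr=rr,
        group=cfg.group,
        ahi_manual=ahi_manual,
        odi_manual=odi_manual,
    )


def synth_cohort(
    n_control: int,
    n_desat: int,
    n_nondesat: int,
    seed: int = 0,
    duration_min: int = 480,
) -> list[SubjectRecord]:
    """Independent subjects with per-subject parameter jitter."""
    rng = np.random.default_rng(seed)
    records = []
    specs = (
        [("control", i) for i in range(n_control)]
        + [("desaturating", i) for i in range(n_desat)]
        + [("non_desaturating", i) for i in range(n_nondesat)]
    )
    ahi_range = {
        "control": (0.5, 4.0),
        "desaturating": (30.0, 58.0),
        "non_desaturating": (26.0, 50.0),
    }
    for group, i in specs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = for_group(
            group,
            seed=sub_seed,
            target_ahi=float(rng.uniform(*ahi_range[group])),
            cvhr_period_s=float(rng.uniform(25.0, 55.0)),
            baseline_spo2=float(rng.uniform(96.0, 99.0)),
            duration_min=duration_min,
        )
        rec = synth_record(cfg)
        rec.id = f"{group[:4]}{i:02d}"
        records.append(rec)
    return records


def jittered(cfg: PhenotypeConfig, seed: int) -> PhenotypeConfig:
    """A copy of ``cfg`` with a new seed (convenience for replicates)."""
    return replace(cfg, seed=seed)
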