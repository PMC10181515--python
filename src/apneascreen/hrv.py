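"""HRV features per 5-minute RR frame: filter bank, cepstrum and DFA.

Each frame contributes 73 named heart-rate-variability features:

* ``FbHRV1..FbHRV34`` — log normalized band powers of a 34-band filter
  bank applied to the periodogram of the 1 Hz-resampled tachogram.  The
  HRV spectrum lives in 0-0.5 Hz; the first band (~0-0.015 Hz) contains
  the cyclic variation of heart rate (CVHR, 0.01-0.04 Hz) that accompanies
  repetitive apneas, and the respiratory sinus arrhythmia (~0.25 Hz) falls
  near band 17.
* ``CC1..CC20`` — the first 20 real-cepstrum coefficients of the same
  resampled tachogram (CC1 is the quefrency-0 element, the mean
  log-magnitude of the spectrum).
* ``alpha1``/``alpha2`` — detrended-fluctuation-analysis scaling
  exponents over scales of 10-40 beats (short-range) and 70-194 beats
  (long-range).  Uncorrelated series give alpha ~ 0.5, 1/f noise ~ 1.0,
  Brownian-like signals ~ 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocessing import Frame, RRSeries

SPECTRAL_FLOOR = 1e-12

HRV_FEATURE_NAMES: list[str] = (
    [f"FbHRV{i}" for i in range(1, 35)]
    + [f"CC{i}" for i in range(1, 21)]
    + ["alpha1", "alpha2"]
)


@dataclass
class Periodogram:
    """DFT periodogram S(k) = |X_N(k)|^2 / N over bins k = 0..N//2."""

    power: np.ndarray
    bin_freqs: np.ndarray
    n_samples: int


@dataclass
class FilterBankOutput:
    """Log normalized power in M contiguous equal-width bands of (0, f_N]."""

    values: np.ndarray
    band_edges: np.ndarray


@dataclass
class DfaExponents:
    alpha1: float
    alpha2: float | None
    fluctuation_curve: tuple[np.ndarray, np.ndarray]


def periodogram(x: np.ndarray, fs: float = 1.0) -> Periodogram:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("periodogram of an empty sequence")
    if not np.isfinite(x).all():
        raise ValueError("periodogram input must be finite")
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return Periodogram(power=power, bin_freqs=freqs, n_samples=n)


def filterbank(p: Periodogram, m: int) -> FilterBankOutput:
    """Log normalized band powers over M equal-width bands of (0, f_Nyquist].

    The DC bin is excluded; each remaining bin is assigned to the band
    containing its frequency, band powers are normalized by total power and
    floored at a small constant before taking the log, so an empty band
    reports ``ln(1e-12)`` rather than ``-inf``.
    """
    if m < 1:
        raise ValueError("need at least one band")
    power = p.power[1:]
    freqs = p.bin_freqs[1:]
    total = power.sum()
    if total <= 0:
        raise ValueError("filterbank of a zero-power spectrum")
    f_nyq = p.bin_freqs[-1]
    width = f_nyq / m
    # bin at frequency f belongs to band ceil(f/width); right edges inclusive
    idx = np.clip(np.ceil(freqs / width - 1e-12).astype(int) - 1, 0, m - 1)
    band_power = np.bincount(idx, weights=power, minlength=m)
    ratios = np.maximum(band_power / total, SPECTRAL_FLOOR)
    edges = np.linspace(0.0, f_nyq, m + 1)
    return FilterBankOutput(values=np.log(ratios), band_edges=edges)


def resample_tachogram(
    rr: RRSeries, t0: float, t1: float, fs: float = 1.0
) -> np.ndarray:
    """Evenly resample an RR segment on [t0, t1) and subtract its mean.

    Cubic interpolation of interval value against beat time, evaluated on a
    uniform ``fs`` grid; edges beyond the observed beats are held at the
    boundary values.
    """
    if len(rr) < 4:
        raise ValueError("too few beats to resample")
    grid = np.arange(t0, t1, 1.0 / fs)
    spline = CubicSpline(rr.beat_times, rr.intervals, bc_type="natural")
    out = spline(np.clip(grid, rr.beat_times[0], rr.beat_times[-1]))
    return out - out.mean()


def hrv_spectral_features(frame: Frame, m: int = 34, fs: float = 1.0) -> FilterBankOutput:
    """34-band filter bank of the frame's tachogram periodogram."""
    if len(frame.rr_segment) < 64:
        raise ValueError("frame has fewer than 64 beats; flag unusable")
    t0 = 60.0 * (frame.central_minute - 2)
    x = resample_tachogram(frame.rr_segment, t0, t0 + 300.0, fs=fs)
    return filterbank(periodogram(x, fs=fs), m)


def real_cepstrum(x: np.ndarray) -> np.ndarray:
    """real(IDFT(log |DFT(x)|)) with the magnitude floored before the log."""
    x = np.asarray(x, dtype=float)
    mag = np.maximum(np.abs(np.fft.fft(x)), SPECTRAL_FLOOR)
    return np.fft.ifft(np.log(mag)).real


def cepstrum20(frame: Frame, n_coeff: int = 20, fs: float = 1.0) -> np.ndarray:
    """First ``n_coeff`` real-cepstrum coefficients of the resampled tachogram."""
    if len(frame.rr_segment) < 64:
        raise ValueError("frame has fewer than 64 beats; flag unusable")
    t0 = 60.0 * (frame.central_minute - 2)
    x = resample_tachogram(frame.rr_segment, t0, t0 + 300.0, fs=fs)
    c = real_cepstrum(x)
    if c.size < n_coeff:
        raise ValueError("segment too short for the requested cepstrum length")
    return c[:n_coeff]


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def _fluctuation(profile: np.ndarray, t: int) -> float:
    """RMS residual of per-window linear detrending, 50% overlapping windows."""
    n = profile.size
    step = max(1, t // 2)
    starts = np.arange(0, n - t + 1, step)
    segs = profile[starts[:, None] + np.arange(t)[None, :]]
    x = np.arange(t, dtype=float)
    design = np.column_stack([x, np.ones(t)])
    hat = design @ np.linalg.pinv(design)  # projection onto linear trends
    resid = segs - segs @ hat.T
    return float(np.sqrt(np.mean(resid**2)))


def dfa_fluctuations(x: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """F(t) for each scale t: integrate the mean-subtracted series, detrend."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - x.mean())
    return np.array([_fluctuation(profile, int(t)) for t in scales])


def _scale_grid(lo: int, hi: int, n: int = 10) -> np.ndarray:
    g = np.unique(np.round(np.geomspace(lo, hi, n)).astype(int))
    return g[(g >= lo) & (g <= hi)]


def dfa(
    rr: RRSeries | np.ndarray,
    short_range: tuple[int, int] = (10, 40),
    long_range: tuple[int, int] | None = (70, 194),
) -> DfaExponents:
    """DFA-1 scaling exponents of an interval series.

    The series is integrated after mean subtraction; windows of t beats
    (50% overlap) are linearly detrended and F(t) is the RMS residual.
    alpha is the least-squares slope of log F(t) against log t over the
    requested scale range.  ``alpha2`` is ``None`` when the series is
    shorter than the smallest usable long-range scale.
    """
    x = rr.intervals if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if x.size < 100:
        raise ValueError("DFA needs at least 100 intervals")

    def slope(lo: int, hi: int) -> tuple[float, np.ndarray, np.ndarray]:
        scales = _scale_grid(lo, min(hi, x.size))
        f = dfa_fluctuations(x, scales)
        good = f > 0
        coef = np.polyfit(np.log(scales[good]), np.log(f[good]), 1)
        return float(coef[0]), scales, f

    a1, s1, f1 = slope(*short_range)
    if long_range is not None and x.size >= long_range[0] * 2:
        a2, s2, f2 = slope(*long_range)
        scales = np.concatenate([s1, s2])
        fl = np.concatenate([f1, f2])
    else:
        a2, scales, fl = None, s1, f1
    return DfaExponents(alpha1=a1, alpha2=a2, fluctuation_curve=(scales, fl))


def hrv_features(frame: Frame, rqa_values: np.ndarray | None = None) -> dict[str, float]:
    """Assemble the 34 + 20 + 2 spectral/cepstral/DFA features of one frame.

    RQA features (17 more) come from :mod:`apneascreen.rqa` and are merged
    by the pipeline; pass them here to get the full named 73-vector.
    """
    fb = hrv_spectral_features(frame)
    cc = cepstrum20(frame)
    d = dfa(frame.rr_segment)
    out = {f"FbHRV{i + 1}": float(v) for i, v in enumerate(fb.values)}
    out.update({f"CC{i + 1}": float(v) for i, v in enumerate(cc)})
    out["alpha1"] = d.alpha1
    out["alpha2"] = d.alpha2 if d.alpha2 is not None else np.nan
    if rqa_values is not None:
        from .rqa import RQA_FEATURE_NAMES

        out.update({n: float(v) for n, v in zip(RQA_FEATURE_NAMES, rqa_values)})
    return out
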