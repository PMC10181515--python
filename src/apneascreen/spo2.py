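"""Oximetry features: 1-min/5-min variances and a 20-band filter bank.

Apneic events drive saw-tooth oxygen desaturations, which raise the
short-term variance of the SpO2 trace and concentrate spectral power at
the event-repetition frequency (roughly 0.01-0.04 Hz, inside the first
band of the 20-band bank over 0-0.5 Hz).  Every 5-minute frame yields 22
features assigned to its central minute: ``varSAT1m`` (central-minute
variance), ``varSAT5m`` (frame variance) and ``FbSAT1..FbSAT20``.
"""

from __future__ import annotations

import numpy as np

from .hrv import FilterBankOutput, filterbank, periodogram
from .preprocessing import Frame

SPO2_FEATURE_NAMES: list[str] = ["varSAT1m", "varSAT5m"] + [
    f"FbSAT{i}" for i in range(1, 21)
]


def spo2_variances(frame: Frame, min_valid_fraction: float = 0.5) -> tuple[float, float]:
    """Sample variance of the cleaned SpO2 over the central minute and frame.

    Uses the n-1 denominator.  Requires at least ``min_valid_fraction`` of
    the nominal samples in both windows (artifact removal leaves gaps).
    """
    seg = frame.spo2_segment
    t = seg.sample_times
    v = seg.samples
    c0 = 60.0 * frame.central_minute
    central = (t >= c0) & (t < c0 + 60.0)
    n_min = min_valid_fraction * 60.0 * seg.fs
    n_frame = min_valid_fraction * 300.0 * seg.fs
    if central.sum() < n_min or v.size < n_frame:
        raise ValueError(
            f"frame {frame.central_minute}: too few valid SpO2 samples "
            f"({int(central.sum())} central, {v.size} total)"
        )
    var1 = float(np.var(v[central], ddof=1))
    var5 = float(np.var(v, ddof=1))
    return var1, var5


def _to_1hz(frame: Frame) -> np.ndarray:
    """Anti-alias decimation of the frame's SpO2 to a 1 Hz grid.

    Valid samples are averaged within each second; seconds emptied by
    artifact removal are filled by linear interpolation from their
    neighbors.
    """
    seg = frame.spo2_segment
    t0 = 60.0 * (frame.central_minute - 2)
    sec = np.floor(seg.sample_times - t0).astype(int)
    n = 300
    sec = np.clip(sec, 0, n - 1)
    sums = np.bincount(sec, weights=seg.samples, minlength=n)
    counts = np.bincount(sec, minlength=n)
    out = np.full(n, np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    if not has.all():
        idx = np.arange(n)
        out[~has] = np.interp(idx[~has], idx[has], out[has])
    return out


def spo2_spectral_features(frame: Frame, m: int = 20) -> FilterBankOutput:
    """20-band log normalized band powers of the 1 Hz SpO2 periodogram."""
    x = _to_1hz(frame)
    x = x - x.mean()
    p = periodogram(x, fs=1.0)
    if p.power[1:].sum() <= 0:
        raise ValueError(f"frame {frame.central_minute}: zero-power SpO2 segment")
    return filterbank(p, m)


def spo2_features(frame: Frame) -> dict[str, float]:
    """Assemble the 22 named oximetry features of one frame."""
    var1, var5 = spo2_variances(frame)
    fb = spo2_spectral_features(frame)
    out = {"varSAT1m": var1, "varSAT5m": var5}
    out.update({f"FbSAT{i + 1}": float(v) for i, v in enumerate(fb.values)})
    return out
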