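"""ECG-to-RR extraction, artifact handling and 5-minute framing.

The pipeline works on 5-minute analysis frames shifted in 1-minute steps;
every quantity computed on a frame is assigned to its central (third)
minute, so a recording of N labelled minutes yields N - 4 frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import SignalTrace, SubjectRecord


@dataclass
class RRSeries:
    """Beat-to-beat interval series derived from ECG R-peaks.

    ``beat_times[i]`` is the time of beat ``i+1`` terminating interval
    ``intervals[i]``; times are seconds from the start of the recording.
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    cleaned: bool = False

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.intervals.shape != self.beat_times.shape:
            raise ValueError("intervals and beat_times must have equal length")
        if self.intervals.size and (self.intervals <= 0).any():
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_times: np.ndarray) -> "RRSeries":
        beat_times = np.asarray(beat_times, dtype=float)
        if beat_times.size and (np.diff(beat_times) <= 0).any():
            raise ValueError("beat times must be strictly increasing")
        return cls(intervals=np.diff(beat_times), beat_times=beat_times[1:])

    def __len__(self) -> int:
        return self.intervals.size

    def restrict(self, t0: float, t1: float) -> "RRSeries":
        """Intervals whose terminating beat falls in [t0, t1)."""
        m = (self.beat_times >= t0) & (self.beat_times < t1)
        return RRSeries(self.intervals[m], self.beat_times[m], cleaned=self.cleaned)


@dataclass
class Frame:
    """One 5-minute analysis window labelled by its central minute."""

    central_minute: int
    rr_segment: RRSeries
    spo2_segment: SignalTrace
    label: int
    usable: bool = True
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins style)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: SignalTrace) -> np.ndarray:
    """Detect R-peak times (s) in a single-lead ECG.

    Classic energy-based QRS detector: 5-15 Hz band-pass, derivative,
    squaring, 150 ms moving-window integration, then adaptive signal/noise
    thresholding with a 200 ms refractory period and a search-back pass for
    missed beats.  Returns strictly increasing beat times; a flat or
    all-NaN trace yields an empty array.
    """
    x = np.asarray(ecg.samples, dtype=float)
    fs = ecg.fs
    x = np.nan_to_num(x, nan=0.0)
    if x.size < int(fs) or np.ptp(x) == 0:
        return np.array([])

    nyq = fs / 2
    lo, hi = 5 / nyq, min(15 / nyq, 0.99)
    b, a = sps.butter(2, [lo, hi], btype="band")
    filt = sps.filtfilt(b, a, x)
    deriv = np.gradient(filt)
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # candidate local maxima of the integrated signal
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        return np.array([])

    spki = float(np.percentile(mwi[peaks], 75))  # running signal estimate
    npki = float(np.percentile(mwi[peaks], 25))  # running noise estimate
    beats: list[int] = []
    missed: list[int] = []
    for p in peaks:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            beats.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            missed.append(p)
            npki = 0.125 * mwi[p] + 0.875 * npki

    # search-back: if a gap exceeds 1.66x the running RR, re-examine the
    # skipped candidates at half threshold
    if len(beats) >= 2:
        final = [beats[0]]
        for p in beats[1:]:
            rr_run = np.median(np.diff(final[-8:])) if len(final) >= 2 else None
            if rr_run is not None and (p - final[-1]) > 1.66 * rr_run:
                thr_half = (npki + 0.25 * (spki - npki)) / 2
                gap = [q for q in missed if final[-1] + refractory < q < p - refractory]
                for q in gap:
                    if mwi[q] > thr_half:
                        final.append(q)
            final.append(p)
        beats = final

    beat_idx = np.array(sorted(set(beats)), dtype=int)
    # refine each beat to the local ECG maximum (R peak) near the MWI peak
    half = int(round(0.075 * fs))
    refined = []
    for i in beat_idx:
        a0, a1 = max(0, i - half), min(x.size, i + half + 1)
        refined.append(a0 + int(np.argmax(np.abs(filt[a0:a1]))))
    refined = np.array(sorted(set(refined)), dtype=int)
    keep = [refined[0]] if refined.size else []
    for i in refined[1:]:
        if i - keep[-1] >= refractory:
            keep.append(i)
    return ecg.start_offset + np.array(keep, dtype=float) / fs


# ---------------------------------------------------------------------------
# RR artifact filtering (adaptive plausibility band)
# ---------------------------------------------------------------------------

def clean_rr(
    rr: RRSeries,
    *,
    n_sigmas: float = 3.0,
    basal_tolerance_s: float = 0.020,
    window: int = 40,
) -> RRSeries:
    """Remove implausible RR intervals with an adaptive filter.

    Each interval is compared against a plausibility band built from the
    previously *accepted* intervals: running robust mean (median) +/-
    (``n_sigmas`` x robust SD + ``basal_tolerance_s``), over the last
    ``window`` accepted beats.  The band follows gradual drifts of the
    series but rejects sudden ectopic-like excursions.  Flagged intervals
    are removed, not interpolated.  The operation is idempotent.
    """
    if len(rr) < 10:
        warnings.warn("fewer than 10 RR intervals: cleaning skipped")
        return RRSeries(rr.intervals, rr.beat_times, cleaned=True)

    x = rr.intervals
    accepted = list(x[:5])  # bootstrap the running estimate
    keep = np.zeros(x.size, dtype=bool)
    keep[:5] = True
    for i in range(5, x.size):
        ref = np.array(accepted[-window:])
        center = np.median(ref)
        sd = 1.4826 * np.median(np.abs(ref - center))
        band = n_sigmas * sd + basal_tolerance_s
        if abs(x[i] - center) <= band:
            keep[i] = True
            accepted.append(x[i])
    return RRSeries(x[keep], rr.beat_times[keep], cleaned=True)


# ---------------------------------------------------------------------------
# SpO2 artifact removal
# ---------------------------------------------------------------------------

def clean_spo2(spo2: SignalTrace) -> SignalTrace:
    """Drop artifact samples (zeros and values below 50%), subtract the mean.

    Sensor drop-outs show up as zero saturation and readings under 50% are
    physiologically implausible; both are removed.  The recording mean of
    the remaining samples is then subtracted, so the cleaned trace is a
    zero-mean deviation signal with explicit (gapped) sample times.
    """
    v = np.asarray(spo2.samples, dtype=float)
    t = spo2.sample_times
    valid = np.isfinite(v) & (v != 0) & (v >= 50.0)
    if not valid.any():
        raise ValueError("SpO2 trace unusable: every sample is an artifact")
    v = v[valid]
    return SignalTrace(v - v.mean(), fs=spo2.fs, times=t[valid])


# ---------------------------------------------------------------------------
# Framing
# ---------------------------------------------------------------------------

def make_frames(
    record: SubjectRecord,
    *,
    rr: RRSeries | None = None,
    spo2: SignalTrace | None = None,
    min_valid_fraction: float = 0.5,
) -> list[Frame]:
    """Cut a record into 5-minute frames shifted by 1 minute.

    ``rr`` and ``spo2`` default to the record's own (assumed cleaned)
    series.  The frame for central minute ``c`` spans minutes
    ``[c-2, c+3)``; its label is the label of minute ``c``.  Frames whose
    SpO2 window retains less than ``min_valid_fraction`` of its nominal
    samples are flagged unusable instead of being silently dropped.
    """
    if rr is None:
        rr = record.rr
    if spo2 is None:
        spo2 = record.spo2
    n = record.n_minutes
    if n < 5 or rr is None:
        return []
    labels = record.labels.labels
    spo2_t = spo2.sample_times
    frames = []
    for c in range(2, n - 2):
        t0, t1 = 60.0 * (c - 2), 60.0 * (c + 3)
        seg_rr = rr.restrict(t0, t1)
        m = (spo2_t >= t0) & (spo2_t < t1)
        seg_spo2 = SignalTrace(spo2.samples[m], fs=spo2.fs, times=spo2_t[m])
        frame = Frame(
            central_minute=c,
            rr_segment=seg_rr,
            spo2_segment=seg_spo2,
            label=int(labels[c]),
        )
        nominal = 300.0 * spo2.fs
        if seg_spo2.samples.size < min_valid_fraction * nominal:
            frame.usable = False
            frame.flags.append("spo2_low_valid_fraction")
        frames.append(frame)
    return frames


def rr_from_record(record: SubjectRecord) -> RRSeries:
    """Cleaned RR series for a record: use the provided one or derive from ECG."""
    if record.rr is not None:
        rr = record.rr
    else:
        beat_times = detect_r_peaks(record.ecg)
        rr = RRSeries.from_beat_times(beat_times)
    return rr if rr.cleaned else clean_rr(rr)
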