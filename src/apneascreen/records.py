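"""Subject records, cohort containers and learning/test split construction.

A subject is one overnight recording: a single-lead ECG (or a precomputed
RR-interval series), an SpO2 trace, one apnea/non-apnea label per minute,
and an optional phenotype tag.  Three phenotypes are distinguished:

* ``control`` — healthy sleepers (AHI below 5),
* ``desaturating`` — OSA patients whose apneic events are accompanied by
  oxygen desaturations,
* ``non_desaturating`` — OSA patients whose oxygen desaturation index is
  less than half their apnea-hypopnea index, i.e. apneic events mostly
  without a marked SpO2 drop.

Minute indexing is 0-based and half-open: label ``k`` covers the time span
``[60k, 60(k+1))`` seconds from the start of the recording.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("control", "desaturating", "non_desaturating", "unknown")


@dataclass
class SignalTrace:
    """A sampled physiological signal (mV for ECG, % for SpO2).

    ``times`` is optional; when absent the trace is uniformly sampled at
    ``fs`` starting from ``start_offset``.  Cleaning steps that remove
    artifact samples produce traces with explicit (gapped) ``times``.
    """

    samples: np.ndarray
    fs: float
    start_offset: float = 0.0
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.samples.shape:
                raise ValueError("times and samples must have equal length")

    @property
    def sample_times(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return self.start_offset + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        """Nominal duration in seconds (uniform traces only)."""
        return self.samples.size / self.fs


@dataclass
class MinuteLabels:
    """One apnea(1)/non-apnea(0) label per whole minute of the recording."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (non-apnea) or 1 (apnea)")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_apnea(self) -> int:
        return int(self.labels.sum())

    @property
    def n_normal(self) -> int:
        return int((self.labels == 0).sum())


@dataclass
class SubjectRecord:
    id: str
    spo2: SignalTrace
    labels: MinuteLabels
    ecg: SignalTrace | None = None
    rr: "object | None" = None  # RRSeries; untyped to avoid a cycle
    group: str = "unknown"
    ahi_manual: float | None = None
    odi_manual: float | None = None

    def __post_init__(self) -> None:
        if self.ecg is None and self.rr is None:
            raise ValueError(f"record {self.id!r}: need at least one of ecg/rr")
        if self.group not in GROUPS:
            raise ValueError(f"record {self.id!r}: unknown group {self.group!r}")
        if (
            self.group == "non_desaturating"
            and self.ahi_manual is not None
            and self.odi_manual is not None
            and not self.odi_manual < self.ahi_manual / 2
        ):
            raise ValueError(
                f"record {self.id!r}: non-desaturating phenotype requires "
                f"ODI < AHI/2 (got ODI={self.odi_manual}, AHI={self.ahi_manual})"
            )

    @property
    def n_minutes(self) -> int:
        return len(self.labels)


@dataclass
class CohortSplit:
    """Learning set plus named test sets.

    Under the three-phenotype scheme the test sets are T1 (held-out
    desaturators), T2 (all non-desaturators) and T3 (held-out controls
    plus T1 plus T2).  Under the 8-subject cross-validation scheme each
    fold is a separate CohortSplit with a single test set named ``test``.
    """

    l_set: list[str]
    t_sets: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# File I/O: plain-text fixture format
# ---------------------------------------------------------------------------

def _read_trace_csv(path: Path) -> SignalTrace:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError(f"{path}: expected columns time_s,value, got {list(df.columns)}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    fs = 1.0 / np.median(dt)
    return SignalTrace(samples=df["value"].to_numpy(float), fs=fs, start_offset=float(t[0]))


def _write_trace_csv(trace: SignalTrace, path: Path) -> None:
    df = pd.DataFrame({"time_s": trace.sample_times, "value": trace.samples})
    df.to_csv(path, index=False, float_format="%.17g")


def read_record(
    spo2_path: str | Path,
    labels_path: str | Path,
    *,
    ecg_path: str | Path | None = None,
    rr_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> SubjectRecord:
    """Read a subject from the CSV fixture layout.

    ``spo2_path`` and ``ecg_path`` are ``time_s,value`` CSVs; ``rr_path``
    is a one-column file of beat times in seconds; the labels file has one
    integer 0/1 per line; ``meta_path`` is an optional JSON sidecar with
    ``id``, ``group``, ``ahi_manual``, ``odi_manual``.
    """
    from .preprocessing import RRSeries  # deferred: avoids import cycle

    spo2_path, labels_path = Path(spo2_path), Path(labels_path)
    for p in (spo2_path, labels_path):
        if not p.exists():
            raise FileNotFoundError(p)
    spo2 = _read_trace_csv(spo2_path)
    labels = MinuteLabels(np.loadtxt(labels_path, dtype=int, ndmin=1))

    n_expected = int(spo2.duration // 60)
    if len(labels) != n_expected:
        raise ValueError(
            f"{labels_path}: {len(labels)} labels but SpO2 covers "
            f"{n_expected} whole minutes ({spo2.duration:.1f} s)"
        )

    ecg = _read_trace_csv(Path(ecg_path)) if ecg_path else None
    rr = None
    if rr_path:
        beat_times = np.loadtxt(rr_path, dtype=float, ndmin=1)
        rr = RRSeries.from_beat_times(beat_times)

    meta: dict = {}
    if meta_path:
        meta = json.loads(Path(meta_path).read_text())
    return SubjectRecord(
        id=str(meta.get("id", spo2_path.stem)),
        spo2=spo2,
        labels=labels,
        ecg=ecg,
        rr=rr,
        group=meta.get("group", "unknown"),
        ahi_manual=meta.get("ahi_manual"),
        odi_manual=meta.get("odi_manual"),
    )


def write_record(record: SubjectRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write a record in the CSV fixture layout; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["spo2"] = out_dir / f"{record.id}_spo2.csv"
    _write_trace_csv(record.spo2, paths["spo2"])

    paths["labels"] = out_dir / f"{record.id}_labels.txt"
    np.savetxt(paths["labels"], record.labels.labels, fmt="%d")

    if record.ecg is not None:
        paths["ecg"] = out_dir / f"{record.id}_ecg.csv"
        _write_trace_csv(record.ecg, paths["ecg"])
    if record.rr is not None:
        paths["rr"] = out_dir / f"{record.id}_rr.txt"
        bt = record.rr.beat_times
        first = bt[0] - record.rr.intervals[0]  # reader re-derives intervals
        np.savetxt(paths["rr"], np.concatenate([[first], bt]), fmt="%.17g")

    meta = {
        "id": record.id,
        "group": record.group,
        "ahi_manual": record.ahi_manual,
        "odi_manual": record.odi_manual,
    }
    paths["meta"] = out_dir / f"{record.id}_meta.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return paths


def read_wfdb_record(record_path: str | Path) -> SubjectRecord:
    """Optional adapter for the Physionet Apnea-ECG layout (.dat/.hea/.apn).

    Requires the ``wfdb`` package; the pipeline itself only consumes
    :class:`SubjectRecord`, so this reader is never needed for synthetic
    or CSV data.
    """
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading Physionet Apnea-ECG records requires the optional "
            "'wfdb' package; install it or convert to the CSV layout"
        ) from exc
    record_path = str(record_path)
    rec = wfdb.rdrecord(record_path)  # pragma: no cover
    ann = wfdb.rdann(record_path, "apn")  # pragma: no cover
    sig = rec.p_signal[:, 0]  # pragma: no cover
    labels = np.array([1 if s == "A" else 0 for s in ann.symbol])  # pragma: no cover
    ecg = SignalTrace(sig, fs=rec.fs)  # pragma: no cover
    spo2 = SignalTrace(np.full(int(60 * len(labels)), np.nan), fs=1.0)  # pragma: no cover
    return SubjectRecord(id=rec.record_name, spo2=spo2, labels=MinuteLabels(labels), ecg=ecg)  # pragma: no cover


# ---------------------------------------------------------------------------
# Cohort splits
# ---------------------------------------------------------------------------

def make_hugcdn_split(cohort: list[SubjectRecord], seed: int = 0) -> CohortSplit:
    """Split a three-phenotype cohort into the L-set and T1/T2/T3 test sets.

    The learning set takes a random half of the controls and a random half
    of the desaturating patients (``floor(n/2)`` each); T1 is the held-out
    desaturators, T2 is every non-desaturating patient, and T3 combines the
    held-out controls with T1 and T2.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {g: [] for g in GROUPS}
    for rec in cohort:
        by_group[rec.group].append(rec.id)
    controls = sorted(by_group["control"])
    desats = sorted(by_group["desaturating"])
    nondesats = sorted(by_group["non_desaturating"])
    if len(controls) < 2 or len(desats) < 2:
        raise ValueError(
            "split scheme needs at least 2 control and 2 desaturating "
            f"subjects (got {len(controls)} and {len(desats)})"
        )

    def half(ids: list[str]) -> tuple[list[str], list[str]]:
        ids = list(ids)
        rng.shuffle(ids)
        k = len(ids) // 2
        return sorted(ids[:k]), sorted(ids[k:])

    l_ctrl, held_ctrl = half(controls)
    l_desat, t1 = half(desats)
    t3 = sorted(held_ctrl + t1 + nondesats)
    return CohortSplit(
        l_set=sorted(l_ctrl + l_desat),
        t_sets={"T1": t1, "T2": sorted(nondesats), "T3": t3},
    )


def enumerate_physionet_folds(cohort: list[SubjectRecord]) -> list[CohortSplit]:
    """All train/test folds for the 5-patient / 3-control scheme.

    Training always holds 3 OSA patients and 2 controls; the remaining 3
    subjects form the test set, giving C(5,3)*C(3,2) = 30 folds.
    """
    osa = sorted(r.id for r in cohort if r.group != "control")
    ctrl = sorted(r.id for r in cohort if r.group == "control")
    if len(osa) != 5 or len(ctrl) != 3:
        raise ValueError(
            f"fold scheme requires exactly 5 OSA and 3 control subjects, "
            f"got {len(osa)} OSA and {len(ctrl)} control"
        )
    folds = []
    for train_osa in itertools.combinations(osa, 3):
        for train_ctrl in itertools.combinations(ctrl, 2):
            train = sorted(train_osa + train_ctrl)
            test = sorted(set(osa + ctrl) - set(train))
            folds.append(CohortSplit(l_set=train, t_sets={"test": test}))
    return folds
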