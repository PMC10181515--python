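"""End-to-end wiring: records -> features -> selection -> LDA -> diagnosis.

The feature matrix has one row per usable central minute with 73 named HRV
features, 22 named SpO2 features, the minute label, and the subject id.
Database presets fix the recurrence embedding and the selection scheme:
``physionet`` uses (m=7, tau=4) with the 30 enumerated folds, ``hugcdn``
uses (m=8, tau=5) with 200 random-split iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnosis as dx
from .classify import lda_fit, lda_score, roc_and_operating_point, undersample
from .hrv import HRV_FEATURE_NAMES, hrv_features
from .preprocessing import clean_spo2, make_frames, rr_from_record
from .records import CohortSplit, SubjectRecord, enumerate_physionet_folds, make_hugcdn_split
from .rqa import EMBEDDING_PRESETS, RQA_FEATURE_NAMES, rqa_features
from .selection import SelectionResult, select_features
from .spo2 import SPO2_FEATURE_NAMES, spo2_features

ALL_FEATURE_NAMES = HRV_FEATURE_NAMES + RQA_FEATURE_NAMES + SPO2_FEATURE_NAMES


def feature_family(which: str) -> list[str]:
    """Feature name list for a family switch: hrv (73), spo2 (22), both (95)."""
    hrv_all = HRV_FEATURE_NAMES + RQA_FEATURE_NAMES
    return {"hrv": hrv_all, "spo2": list(SPO2_FEATURE_NAMES), "both": hrv_all + list(SPO2_FEATURE_NAMES)}[which]


@dataclass
class RunConfig:
    preset: str = "hugcdn"            # fixes (m, tau) and the selection scheme
    features: str = "both"            # hrv | spo2 | both
    seed: int = 0
    n_iter: int = 200                 # random-split iterations (hugcdn scheme)
    max_k: int | None = None          # cap on the error-curve length
    out_dir: Path | None = None

    @property
    def embedding(self) -> tuple[int, int]:
        return EMBEDDING_PRESETS[self.preset]


def extract_features(
    record: SubjectRecord, m: int = 8, tau: int = 5
) -> pd.DataFrame:
    """Per-minute feature matrix of one record (usable frames only)."""
    rr = rr_from_record(record)
    spo2 = clean_spo2(record.spo2)
    rows = []
    for frame in make_frames(record, rr=rr, spo2=spo2):
        if not frame.usable:
            continue
        try:
            feats = hrv_features(frame)
            feats.update(rqa_features(frame, m=m, tau=tau))
            feats.update(spo2_features(frame))
        except ValueError:
            continue  # frame too short/degenerate after cleaning
        feats["label"] = frame.label
        feats["minute"] = frame.central_minute
        feats["subject"] = record.id
        rows.append(feats)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df[["subject", "minute", "label"] + list(ALL_FEATURE_NAMES)]
    return df


def extract_cohort_features(
    cohort: list[SubjectRecord], m: int = 8, tau: int = 5
) -> pd.DataFrame:
    parts = [extract_features(rec, m=m, tau=tau) for rec in cohort]
    parts = [p for p in parts if not p.empty]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


@dataclass
class EvaluationReport:
    selection: SelectionResult
    per_segment: dict[str, dict]           # test-set name -> metrics dict
    ahi: dx.AhiReport | None = None
    bland_altman: dx.BlandAltman | None = None
    recording_metrics: dict[float, tuple[float, float, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        out = {
            "selection": self.selection.to_json_dict(),
            "per_segment": self.per_segment,
        }
        if self.ahi is not None:
            out["ahi"] = {
                "subjects": self.ahi.subject_ids,
                "ahi_automatic": self.ahi.ahi_automatic.tolist(),
                "ahi_manual": self.ahi.ahi_manual.tolist(),
                "groups": self.ahi.groups,
            }
        if self.bland_altman is not None:
            ba = self.bland_altman
            out["bland_altman"] = {
                "bias": ba.bias, "sd": ba.sd, "limits": list(ba.limits),
                "ci_of_bias": list(ba.ci_of_bias),
            }
        if self.recording_metrics:
            out["recording_metrics"] = {
                str(k): list(v) for k, v in self.recording_metrics.items()
            }
        return out


def _segment_metrics_dict(m) -> dict:
    return {
        "accuracy": m.accuracy, "sensitivity": m.sensitivity,
        "specificity": m.specificity, "auc": m.auc,
        "threshold": m.threshold_at_op,
    }


def run_pipeline(
    cohort: list[SubjectRecord],
    config: RunConfig,
    features_df: pd.DataFrame | None = None,
    split: CohortSplit | None = None,
) -> EvaluationReport:
    """Execute selection, training, per-segment and per-recording evaluation.

    The operating threshold is tuned on the learning-set ROC and frozen
    before any test subject is scored.  Per-recording diagnosis converts
    each test subject's predicted apneic minutes into an AHI proxy and
    compares it against the manual AHI.
    """
    m, tau = config.embedding
    if features_df is None:
        features_df = extract_cohort_features(cohort, m=m, tau=tau)
    if features_df.empty:
        raise ValueError("no usable frames in the cohort")
    feature_names = feature_family(config.features)

    if config.preset == "physionet":
        folds = enumerate_physionet_folds(cohort)
        if split is None:
            split = folds[0]
        scheme, sel_folds, n_iter = "folds", folds, len(folds)
        lset_ids = set(split.l_set)
    else:
        if split is None:
            split = make_hugcdn_split(cohort, seed=config.seed)
        scheme, sel_folds, n_iter = "random_split", None, config.n_iter
        lset_ids = set(split.l_set)

    lset_df = features_df[features_df["subject"].isin(lset_ids)]
    sel = select_features(
        lset_df, feature_names, scheme=scheme, n_iter=n_iter,
        seed=config.seed, folds=sel_folds, max_k=config.max_k,
    )
    chosen = sel.chosen

    rng = np.random.default_rng(config.seed + 1000)
    xt, yt = lset_df[chosen].to_numpy(float), lset_df["label"].to_numpy(int)
    xt_b, yt_b = undersample(xt, yt, rng)
    model = lda_fit(xt_b, yt_b, feature_names=chosen)

    # freeze the corner operating point on the learning-set ROC
    l_scores = lda_score(model, xt)
    l_metrics = roc_and_operating_point(l_scores, yt)
    threshold = l_metrics.threshold_at_op

    per_segment = {"L": _segment_metrics_dict(l_metrics)}
    for name, ids in split.t_sets.items():
        tdf = features_df[features_df["subject"].isin(set(ids))]
        if tdf.empty or np.unique(tdf["label"]).size < 2:
            continue
        scores = lda_score(model, tdf[chosen].to_numpy(float))
        metrics = roc_and_operating_point(scores, tdf["label"].to_numpy(int), threshold=threshold)
        per_segment[name] = _segment_metrics_dict(metrics)

    # per-recording diagnosis on the widest test set available
    report = EvaluationReport(selection=sel, per_segment=per_segment)
    eval_ids = split.t_sets.get("T3") or split.t_sets.get("test") or []
    by_id = {rec.id: rec for rec in cohort}
    subj, ahi_a, ahi_m, groups = [], [], [], []
    for sid in eval_ids:
        sdf = features_df[features_df["subject"] == sid]
        rec = by_id.get(sid)
        if sdf.empty or rec is None or rec.ahi_manual is None:
            continue
        pred = (lda_score(model, sdf[chosen].to_numpy(float)) >= threshold).astype(int)
        subj.append(sid)
        ahi_a.append(dx.estimate_ahi(pred))
        ahi_m.append(rec.ahi_manual)
        groups.append(rec.group)
    if len(subj) >= 2:
        report.ahi = dx.AhiReport.build(subj, np.array(ahi_a), np.array(ahi_m), groups)
        report.bland_altman = dx.bland_altman(np.array(ahi_a), np.array(ahi_m))
        if any(g == "control" for g in groups) and any(g != "control" for g in groups):
            report.recording_metrics = {
                lim: report.ahi.metrics_at(lim) for lim in dx.AHI_LIMITS
            }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=1))
        features_df.to_csv(out / "features.csv", index=False)
    return report
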