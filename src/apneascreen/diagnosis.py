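"""Per-recording OSA diagnosis from per-minute predictions.

The automatic apnea-hypopnea index (AHI) proxy is the average number of
predicted apneic minutes per hour of recording, bounded by construction to
[0, 60] events/h.  Subjects are called OSA when the proxy exceeds a
clinical limit (5, 10 or 15 events/h), and agreement with the manually
scored AHI is summarized with Bland-Altman bias and limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

#: z for the central 95% of a normal distribution
Z95 = float(norm.ppf(0.975))

AHI_LIMITS = (5.0, 10.0, 15.0)


def estimate_ahi(predictions: np.ndarray) -> float:
    """60 x (apneic minutes) / (total minutes) from per-minute 0/1 flags."""
    p = np.asarray(predictions).astype(int)
    if p.size == 0:
        raise ValueError("cannot estimate AHI from zero minutes")
    return 60.0 * p.sum() / p.size


def classify_recording(ahi: float, limit: float) -> str:
    """'osa' when the index strictly exceeds the limit, else 'normal'."""
    if ahi < 0:
        raise ValueError("AHI must be non-negative")
    return "osa" if ahi > limit else "normal"


def recording_metrics(
    decisions: list[str], truth_is_patient: list[bool]
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in % over subjects.

    Sensitivity is computed over true patients (any OSA phenotype),
    specificity over true controls.
    """
    dec = np.asarray([d == "osa" for d in decisions])
    truth = np.asarray(truth_is_patient, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("need both patients and controls for recording metrics")
    tp = int((dec & truth).sum())
    tn = int((~dec & ~truth).sum())
    acc = 100.0 * (tp + tn) / truth.size
    sens = 100.0 * tp / truth.sum()
    spec = 100.0 * tn / (~truth).sum()
    return acc, sens, spec


@dataclass
class BlandAltman:
    bias: float
    sd: float
    limits: tuple[float, float]
    ci_of_bias: tuple[float, float]
    points: np.ndarray  # (n, 2): (mean, difference) per subject


def agreement_limits(bias: float, sd: float, z: float = Z95) -> tuple[float, float]:
    """95% limits of agreement bias +/- z*sd (z = Phi^-1(0.975))."""
    return bias - z * sd, bias + z * sd


def bland_altman(ahi_a: np.ndarray, ahi_m: np.ndarray) -> BlandAltman:
    """Agreement between automatic and manual AHI.

    Differences d_i = AHI_a,i - AHI_m,i; bias = mean(d); sd uses the n-1
    denominator; limits of agreement = bias +/- 1.96*sd and the CI of the
    bias is bias +/- 1.96*sd/sqrt(n).
    """
    a = np.asarray(ahi_a, dtype=float)
    m = np.asarray(ahi_m, dtype=float)
    if a.shape != m.shape or a.size < 2:
        raise ValueError("need two equal-length series of at least 2 subjects")
    d = a - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half_ci = Z95 * sd / np.sqrt(d.size)
    return BlandAltman(
        bias=bias,
        sd=sd,
        limits=agreement_limits(bias, sd),
        ci_of_bias=(bias - half_ci, bias + half_ci),
        points=np.column_stack([(a + m) / 2, d]),
    )


@dataclass
class AhiReport:
    """Per-subject automatic vs manual AHI with decisions at each limit."""

    subject_ids: list[str]
    ahi_automatic: np.ndarray
    ahi_manual: np.ndarray
    groups: list[str]
    decisions: dict[float, list[str]]

    @classmethod
    def build(
        cls,
        subject_ids: list[str],
        ahi_automatic: np.ndarray,
        ahi_manual: np.ndarray,
        groups: list[str],
    ) -> "AhiReport":
        ahi_automatic = np.asarray(ahi_automatic, dtype=float)
        decisions = {
            lim: [classify_recording(a, lim) for a in ahi_automatic]
            for lim in AHI_LIMITS
        }
        return cls(subject_ids, ahi_automatic, np.asarray(ahi_manual, float), groups, decisions)

    def metrics_at(self, limit: float) -> tuple[float, float, float]:
        truth = [g != "control" for g in self.groups]
        return recording_metrics(self.decisions[limit], truth)
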