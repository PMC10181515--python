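"""Two-step feature selection: repeated sub-sampling SFS plus error curve.

Step one runs sequential forward selection (wrapped around the balanced
LDA classifier) on many random patient-disjoint train/validation splits of
the learning set and ranks features by how often they are selected.  Step
two re-draws splits and traces the mean validation misclassification error
as features enter in rank order; the selected subset is the prefix at the
first error minimum.

Patient disjointness is enforced throughout: the minutes of one subject
never appear on both sides of a split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import lda_fit, lda_score, undersample

#: default iteration counts per scheme
N_ITER_RANDOM_SPLIT = 200


@dataclass
class SelectionResult:
    ranking: list[str]
    frequencies: dict[str, int]
    error_curve: np.ndarray
    k_star: int
    chosen: list[str]
    k_star_1se: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "ranking": self.ranking,
            "frequencies": self.frequencies,
            "error_curve": self.error_curve.tolist(),
            "k_star": self.k_star,
            "chosen": self.chosen,
            "k_star_1se": self.k_star_1se,
        }


def _xy(df: pd.DataFrame, features: list[str]) -> tuple[np.ndarray, np.ndarray]:
    return df[features].to_numpy(float), df["label"].to_numpy(int)


def _fit_predict_acc(
    train: pd.DataFrame, valid: pd.DataFrame, features: list[str],
    rng: np.random.Generator,
) -> float:
    """Validation accuracy of a balanced fit; NaN for degenerate splits
    (a side missing a class, or fewer than 2 samples per class)."""
    xt, yt = _xy(train, features)
    try:
        xt, yt = undersample(xt, yt, rng)
        model = lda_fit(xt, yt)
    except ValueError:
        return float("nan")
    xv, yv = _xy(valid, features)
    pred = (lda_score(model, xv) >= 0).astype(int)
    return float((pred == yv).mean())


def sfs_once(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    feature_names: list[str],
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Greedy sequential forward selection against validation accuracy.

    At every step the feature whose addition maximizes validation accuracy
    joins the subset; selection stops at the first step with no
    improvement and returns the best subset seen.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.unique(valid["label"]).size < 2:
        raise ValueError("validation set has a single class")
    chosen: list[str] = []
    best_acc = -np.inf
    remaining = list(feature_names)
    while remaining:
        accs = np.array([
            _fit_predict_acc(train, valid, chosen + [f], rng) for f in remaining
        ])
        accs = np.where(np.isnan(accs), -np.inf, accs)
        i = int(np.argmax(accs))
        if accs[i] <= best_acc or not np.isfinite(accs[i]):
            break
        best_acc = float(accs[i])
        chosen.append(remaining.pop(i))
    return chosen


def _random_subject_splits(
    df: pd.DataFrame, n_iter: int, rng: np.random.Generator
):
    subjects = np.array(sorted(df["subject"].unique()))
    if subjects.size < 4:
        raise ValueError("random-split scheme needs at least 4 subjects")
    for _ in range(n_iter):
        perm = rng.permutation(subjects)
        half = subjects.size // 2
        tr, va = set(perm[:half]), set(perm[half:])
        yield df[df["subject"].isin(tr)], df[df["subject"].isin(va)]


def _fold_splits(df: pd.DataFrame, folds):
    for fold in folds:
        tr = set(fold.l_set)
        va = set(fold.t_sets["test"])
        yield df[df["subject"].isin(tr)], df[df["subject"].isin(va)]


def _iterate_splits(df: pd.DataFrame, scheme: str, n_iter: int,
                    rng: np.random.Generator, folds=None):
    if scheme == "random_split":
        yield from _random_subject_splits(df, n_iter, rng)
    elif scheme == "folds":
        if folds is None:
            raise ValueError("scheme 'folds' requires the fold list")
        yield from _fold_splits(df, folds)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")


def rank_features(
    lset: pd.DataFrame,
    feature_names: list[str],
    scheme: str = "random_split",
    n_iter: int = N_ITER_RANDOM_SPLIT,
    seed: int = 0,
    folds=None,
) -> tuple[list[str], dict[str, int], dict[str, float]]:
    """Rank features by selection frequency over repeated splits.

    ``scheme='random_split'`` splits the learning-set subjects into two
    random halves per iteration (200 iterations by default);
    ``scheme='folds'`` iterates a pre-enumerated fold list (the 30-fold
    5-patient/3-control scheme).  Ties are broken by mean selection step
    (earlier wins), then by name.
    """
    rng = np.random.default_rng(seed)
    freq: dict[str, int] = {f: 0 for f in feature_names}
    step_sum: dict[str, float] = {f: 0.0 for f in feature_names}
    for train, valid in _iterate_splits(lset, scheme, n_iter, rng, folds):
        try:
            subset = sfs_once(train, valid, feature_names, rng)
        except ValueError:  # degenerate draw (single-class side): skip
            continue
        for step, f in enumerate(subset):
            freq[f] += 1
            step_sum[f] += step
    mean_step = {
        f: (step_sum[f] / freq[f] if freq[f] else np.inf) for f in feature_names
    }
    ranking = sorted(feature_names, key=lambda f: (-freq[f], mean_step[f], f))
    return ranking, freq, mean_step


def error_curve_and_select(
    lset: pd.DataFrame,
    ranking: list[str],
    scheme: str = "random_split",
    n_iter: int = N_ITER_RANDOM_SPLIT,
    seed: int = 0,
    folds=None,
    frequencies: dict[str, int] | None = None,
    max_k: int | None = None,
) -> SelectionResult:
    """Mean validation error for growing rank prefixes; pick the minimum.

    Uses an independent stream of random splits.  ``k_star`` is the first
    k achieving the minimum mean error; ``k_star_1se`` additionally reports
    the first k within one standard error of it.  ``max_k`` caps the curve
    length (useful when the tail of the ranking is pure noise).
    """
    if not ranking:
        raise ValueError("empty ranking")
    k_max = len(ranking) if max_k is None else min(max_k, len(ranking))
    rng = np.random.default_rng(seed)
    rows = []
    for train, valid in _iterate_splits(lset, scheme, n_iter, rng, folds):
        row = []
        for k in range(1, k_max + 1):
            acc = _fit_predict_acc(train, valid, ranking[:k], rng)
            row.append(1.0 - acc)
        rows.append(row)
    errors = np.array(rows)
    valid_rows = ~np.isnan(errors).all(axis=1)
    errors = errors[valid_rows]
    if errors.size == 0:
        raise ValueError("every split draw was degenerate; cannot build curve")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        curve = np.nanmean(errors, axis=0)
    curve = np.where(np.isnan(curve), np.inf, curve)
    k_star = int(np.argmin(curve)) + 1
    if errors.shape[0] > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = np.nanstd(errors, axis=0, ddof=1) / np.sqrt(errors.shape[0])
        se = np.where(np.isnan(se), 0.0, se)
    else:
        se = np.zeros_like(curve)
    within = np.flatnonzero(curve <= curve[k_star - 1] + se[k_star - 1])
    k_1se = int(within[0]) + 1 if within.size else k_star
    return SelectionResult(
        ranking=list(ranking),
        frequencies=frequencies or {},
        error_curve=curve,
        k_star=k_star,
        chosen=list(ranking[:k_star]),
        k_star_1se=k_1se,
    )


def select_features(
    lset: pd.DataFrame,
    feature_names: list[str],
    scheme: str = "random_split",
    n_iter: int = N_ITER_RANDOM_SPLIT,
    seed: int = 0,
    folds=None,
    max_k: int | None = None,
) -> SelectionResult:
    """Full two-step procedure: frequency ranking then error-curve choice."""
    ranking, freq, _ = rank_features(
        lset, feature_names, scheme=scheme, n_iter=n_iter, seed=seed, folds=folds
    )
    return error_curve_and_select(
        lset, ranking, scheme=scheme, n_iter=n_iter, seed=seed + 1,
        folds=folds, frequencies=freq, max_k=max_k,
    )
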