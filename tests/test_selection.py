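import numpy as np
import pandas as pd
import pytest

from apneascreen.selection import (
    error_curve_and_select,
    rank_features,
    select_features,
    sfs_once,
)


def planted_cohort(
    n_subjects=20, frames_per_subject=40, n_informative=3, n_noise=17,
    effect=1.6, seed=0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-minute features where only the first ``n_informative`` carry class
    signal; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    rows = []
    names = [f"inf{i}" for i in range(n_informative)] + [
        f"noise{i}" for i in range(n_noise)
    ]
    for s in range(n_subjects):
        labels = (rng.random(frames_per_subject) < 0.5).astype(int)
        x = rng.standard_normal((frames_per_subject, n_informative + n_noise))
        x[:, :n_informative] += effect * labels[:, None]
        for i in range(frames_per_subject):
            row = {"subject": f"s{s:02d}", "minute": i, "label": int(labels[i])}
            row.update({n: x[i, j] for j, n in enumerate(names)})
            rows.append(row)
    return pd.DataFrame(rows), names


def _split(df):
    subjects = sorted(df["subject"].unique())
    half = len(subjects) // 2
    return (df[df["subject"].isin(subjects[:half])],
            df[df["subject"].isin(subjects[half:])])


class TestSfsOnce:
    def test_perfectly_separating_feature_wins_alone(self):
        rng = np.random.default_rng(0)
        n = 200
        labels = np.repeat([0, 1], n // 2)
        df = pd.DataFrame({
            "subject": ["a"] * (n // 2) + ["b"] * (n // 2),
            "label": labels,
            "A": labels * 10.0 + rng.normal(0, 0.1, n),
            "B": rng.standard_normal(n),
        })
        train, valid = df.iloc[::2], df.iloc[1::2]
        assert sfs_once(train, valid, ["A", "B"], seed=0) == ["A"]

    def test_pure_noise_selects_little_at_chance(self):
        df, names = planted_cohort(n_informative=0, n_noise=8,
                                   n_subjects=8, frames_per_subject=120, seed=1)
        train, valid = _split(df)
        subset = sfs_once(train, valid, names, seed=1)
        assert len(subset) <= 3

    def test_deterministic_under_seed(self):
        df, names = planted_cohort(seed=2, n_subjects=6)
        train, valid = _split(df)
        assert sfs_once(train, valid, names, 5) == sfs_once(train, valid, names, 5)

    def test_single_class_validation_fails(self):
        df, names = planted_cohort(seed=3, n_subjects=4)
        train, valid = _split(df)
        with pytest.raises(ValueError, match="single class"):
            sfs_once(train, valid.assign(label=1), names, 0)


class TestRankFeatures:
    def test_informative_features_rank_on_top(self):
        df, names = planted_cohort(seed=4)
        ranking, freq, _ = rank_features(df, names, n_iter=30, seed=4)
        assert set(ranking[:3]) == {"inf0", "inf1", "inf2"}

    def test_ranking_is_permutation_sorted_by_frequency(self):
        df, names = planted_cohort(seed=5, n_subjects=8)
        ranking, freq, _ = rank_features(df, names, n_iter=10, seed=5)
        assert sorted(ranking) == sorted(names)
        freqs = [freq[f] for f in ranking]
        assert freqs == sorted(freqs, reverse=True)

    def test_fold_scheme_uses_every_fold(self):
        from apneascreen.records import CohortSplit

        df, names = planted_cohort(seed=6, n_subjects=6, n_noise=5)
        subjects = sorted(df["subject"].unique())
        folds = [
            CohortSplit(l_set=subjects[:3], t_sets={"test": subjects[3:]}),
            CohortSplit(l_set=subjects[3:], t_sets={"test": subjects[:3]}),
        ]
        ranking, freq, _ = rank_features(df, names, scheme="folds", folds=folds, seed=6)
        assert sum(freq.values()) >= 2  # at least one pick per fold

    def test_too_few_subjects_fails(self):
        df, names = planted_cohort(seed=7, n_subjects=3)
        with pytest.raises(ValueError, match="at least 4"):
            rank_features(df, names, n_iter=2, seed=7)


class TestErrorCurve:
    def test_planted_signal_selects_compact_subset(self):
        df, names = planted_cohort(seed=8)
        result = select_features(df, names, n_iter=20, seed=8)
        assert result.k_star <= 5
        assert set(result.chosen) & {"inf0", "inf1", "inf2"}
        # curve drops from k=1 to the informative-set size region
        assert result.error_curve[result.k_star - 1] <= result.error_curve[0]

    def test_selected_fewer_than_offered(self):
        df, names = planted_cohort(seed=9, n_noise=12)
        result = select_features(df, names, n_iter=10, seed=9)
        assert len(result.chosen) < len(names)

    def test_k1_curve(self):
        df, names = planted_cohort(seed=10, n_subjects=6)
        result = error_curve_and_select(df, ["inf0"], n_iter=5, seed=10)
        assert result.error_curve.size == 1 and result.k_star == 1

    def test_deterministic_under_master_seed(self):
        df, names = planted_cohort(seed=11, n_subjects=8)
        a = select_features(df, names, n_iter=8, seed=11)
        b = select_features(df, names, n_iter=8, seed=11)
        assert a.ranking == b.ranking and a.chosen == b.chosen
        np.testing.assert_array_equal(a.error_curve, b.error_curve)

    def test_empty_ranking_fails(self):
        df, names = planted_cohort(seed=12, n_subjects=6)
        with pytest.raises(ValueError, match="empty"):
            error_curve_and_select(df, [], n_iter=2, seed=12)


def test_degenerate_splits_are_skipped_not_fatal():
    """Splits whose training side has almost no minority-class frames (a
    real risk with short recordings) are skipped, not crashed on."""
    rng = np.random.default_rng(0)
    rows = []
    for s in range(6):
        n = 30
        # controls: at most one apneic frame each
        labels = np.zeros(n, int)
        if s >= 3:
            labels[: n // 2] = 1
        for i in range(n):
            rows.append({"subject": f"s{s}", "minute": i, "label": int(labels[i]),
                         "f0": rng.standard_normal() + labels[i],
                         "f1": rng.standard_normal()})
    df = pd.DataFrame(rows)
    result = select_features(df, ["f0", "f1"], n_iter=20, seed=1)
    assert result.k_star >= 1
    assert np.isfinite(result.error_curve).any()


def test_patient_disjointness_of_random_splits():
    """No subject's minutes may sit on both sides of a split."""
    from apneascreen.selection import _random_subject_splits

    df, _ = planted_cohort(seed=13, n_subjects=9)
    rng = np.random.default_rng(13)
    for train, valid in _random_subject_splits(df, 10, rng):
        assert not set(train["subject"]) & set(valid["subject"])
        assert set(train["subject"]) | set(valid["subject"]) == set(df["subject"])
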