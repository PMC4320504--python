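"""Statistics tests: rank-sum oracle, logistic regression, ROC, confusion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thermofit.stats import (
    classify_regions,
    fit_region_classifier,
    group_compare,
    normality_test,
    region_stats,
    roc_cutoff,
)


def enumerate_exact_p(x, y):
    """Brute-force two-sided rank-sum p over all C(n1+n2, n1) assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    # midrank mean is (N+1)/2 regardless of ties
    dev = abs(obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= dev - 1e-9:
            count += 1
    return count / total


class TestNormalityTest:
    def test_null_behaviour_on_gaussian_draws(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            _, p = normality_test(rng.standard_normal(50))
            hits += p > 0.05
        assert hits >= 36  # >= 90% of seeds retain normality

    def test_detects_folded_skewed_distribution(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            _, p = normality_test(np.abs(rng.standard_normal(50)))
            hits += p < 0.05
        assert hits >= 36

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            normality_test(np.full(10, 1.0))
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        r, z, p = group_compare([1, 2, 3], [1, 2, 3])
        assert p == 1.0
        assert z is None

    def test_fully_separated_three_vs_three(self):
        r, z, p = group_compare([1, 2, 3], [10, 11, 12])
        assert r == 6.0  # minimum possible rank sum
        assert z is None
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_exact_p_matches_enumeration_with_and_without_ties(self):
        rng = np.random.default_rng(11)
        cases = [
            (rng.normal(size=5), rng.normal(size=7)),
            (rng.normal(size=6), rng.normal(size=6) + 1.0),
            (np.array([1.0, 2.0, 2.0, 3.0]), np.array([2.0, 4.0, 4.0])),
            (np.array([1, 1, 1, 2.0]), np.array([1, 2, 2.0])),
        ]
        for x, y in cases:
            _, z, p = group_compare(x, y)
            assert z is None
            assert p == pytest.approx(enumerate_exact_p(x, y), abs=1e-12)

    def test_exact_p_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        y = rng.normal(size=9) + 0.5
        _, _, p = group_compare(x, y)
        want = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(want, abs=1e-12)

    def test_large_samples_use_z_and_detect_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 1.0, size=60)
        y = rng.normal(0.0, 1.0, size=55)
        _, z, p = group_compare(x, y)
        assert z is not None and z > 0
        assert p < 0.05

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, z, p = group_compare(np.ones(12), np.ones(15))
        assert p == 1.0


class TestRegionStats:
    def test_tidy_table_flags_shifted_parameter(self):
        rng = np.random.default_rng(8)
        n = 40
        df = pd.DataFrame(
            {
                "group": ["PsA"] * n + ["HC"] * n,
                "lt": rng.normal(5, 2, 2 * n),
                "a": rng.normal(0.5, 0.2, 2 * n),
                "d": np.r_[rng.normal(0.3, 0.1, n), rng.normal(-0.3, 0.1, n)],
                "k": rng.normal(0.4, 0.3, 2 * n),
            }
        )
        stats = {s.parameter: s for s in region_stats(df, "pooled")}
        assert stats["d"].significant
        assert not stats["lt"].significant


class TestLogisticClassifier:
    @staticmethod
    def _frame(features, labels):
        df = pd.DataFrame(features, columns=["lt", "a", "d", "k"])
        df["group"] = np.where(labels == 1, "PsA", "HC")
        return df

    def test_null_features_give_small_wald(self):
        quiet = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 4))
            y = (np.arange(60) < 30).astype(int)
            model = fit_region_classifier(self._frame(X, y))
            for k in ("lt", "a", "d", "k"):
                total += 1
                quiet += model.p_values[k] > 0.05
        assert quiet / total >= 0.90  # ~5% nominal false-positive rate

    def test_perfect_separation_flagged(self):
        X = np.zeros((20, 4))
        y = (np.arange(20) < 10).astype(int)
        X[:, 2] = y  # d column exactly equals the label
        X[:, [0, 1, 3]] = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.warns(UserWarning, match="separation"):
            model = fit_region_classifier(self._frame(X, y))
        assert model.separated

    def test_recovers_analytic_log_odds_slope(self):
        # equal-variance Gaussian classes: slope = (mu1 - mu0) / sigma^2
        rng = np.random.default_rng(77)
        n = 600
        mu1, mu0, sigma = 1.0, 0.0, 1.0
        x = np.r_[rng.normal(mu1, sigma, n), rng.normal(mu0, sigma, n)]
        y = np.r_[np.ones(n), np.zeros(n)].astype(int)
        X = rng.normal(size=(2 * n, 4)) * 0.01
        X[:, 3] = x  # signal lives in the k column
        model = fit_region_classifier(self._frame(X, y))
        slope = (mu1 - mu0) / sigma**2
        assert abs(model.coef["k"] - slope) <= 3 * model.se["k"]
        assert model.odds_ratios["k"] == pytest.approx(np.exp(model.coef["k"]))

    def test_too_few_records_rejected(self):
        X = np.random.default_rng(0).normal(size=(3, 4))
        y = np.array([1, 0, 0])
        with pytest.raises(ValueError):
            fit_region_classifier(self._frame(X, y))


class TestRoc:
    def test_separable_case_cutoff_and_auc(self):
        probs = np.array([0.1] * 9 + [0.9] * 11)
        labels = np.array([0] * 9 + [1] * 11)
        roc = roc_cutoff(probs, labels)
        assert roc.auc == 1.0
        assert roc.cutoff == pytest.approx(0.9)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(4)
        probs = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        roc = roc_cutoff(probs, labels)
        assert abs(roc.auc - 0.5) < 0.05

    def test_constant_scores_auc_exactly_half(self):
        probs = np.full(30, 0.4)
        labels = np.r_[np.ones(15), np.zeros(15)].astype(int)
        assert roc_cutoff(probs, labels).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_cutoff(np.linspace(0, 1, 5), np.ones(5, dtype=int))

    def test_auc_equals_ranksum_probability(self):
        """AUC must equal the Mann-Whitney U / (n1 n2) on the same scores."""
        rng = np.random.default_rng(9)
        probs = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        roc = roc_cutoff(probs, labels)
        u = sps.mannwhitneyu(
            probs[labels == 1], probs[labels == 0], alternative="two-sided"
        ).statistic
        n1 = (labels == 1).sum()
        n0 = (labels == 0).sum()
        assert roc.auc == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestConfusionMatrix:
    def test_perfect_separation_diagonal(self):
        probs = np.array([0.9] * 5 + [0.1] * 5)
        labels = np.array([1] * 5 + [0] * 5)
        cm = classify_regions(probs, labels, cutoff=0.5)
        assert cm.correct_pct == {"PsA": 100.0, "HC": 100.0}

    def test_zero_cutoff_predicts_everything_positive(self):
        probs = np.linspace(0.1, 0.9, 10)
        labels = np.array([1] * 5 + [0] * 5)
        cm = classify_regions(probs, labels, cutoff=0.0)
        assert cm.matrix[1, 0] == 100.0 and cm.matrix[1, 1] == 0.0

    def test_eight_of_nine_controls_correct(self):
        probs = np.array([0.9] * 11 + [0.2] * 8 + [0.8])
        labels = np.array([1] * 11 + [0] * 9)
        cm = classify_regions(probs, labels, cutoff=0.4)
        assert cm.correct_pct["HC"] == pytest.approx(88.888888888, abs=1e-6)
        assert cm.correct_pct["PsA"] == 100.0
        assert cm.matrix.sum(axis=1) == pytest.approx([100.0, 100.0])
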