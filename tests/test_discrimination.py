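import itertools

import numpy as np
import pytest
from scipy import stats

from frailtycompare.discrimination import (
    auc_mann_whitney,
    concordance_contrast,
    delong_contrast,
    harrell_c,
    hosmer_lemeshow,
    spearman_agreement,
)


def _brute_force_auc(scores, labels):
    """Direct pair enumeration: P(score_case > score_control) + half ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = wins = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                wins += 1
            elif a == b:
                wins += 0.5
    return wins / total


class TestAUC:
    def test_perfect_and_random_orderings(self):
        labels = np.r_[np.zeros(5), np.ones(5)].astype(int)
        assert auc_mann_whitney(np.arange(10.0), labels)[0] == 1.0
        assert auc_mann_whitney(-np.arange(10.0), labels)[0] == 0.0
        assert auc_mann_whitney(np.zeros(10), labels)[0] == 0.5

    def test_matches_brute_force_with_ties(self, rng):
        scores = rng.integers(0, 6, 80).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 80)
        if labels.sum() in (0, 80):
            labels[0] = 1 - labels[0]
        auc, _ = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_trapezoid(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=500) + rng.integers(0, 2, 500)
        labels = rng.integers(0, 2, 500)
        auc, _ = auc_mann_whitney(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            auc_mann_whitney(np.arange(5.0), np.ones(5, dtype=int))


class TestDeLong:
    def test_tiny_sample_brute_force_variance(self):
        # n = 6: the structural components can be enumerated by hand
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        auc, var = auc_mann_whitney(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        v10 = np.array([np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                                 for b in neg]) for a in pos])
        v01 = np.array([np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                                 for a in pos]) for b in neg])
        assert auc == pytest.approx(v10.mean(), abs=1e-15)
        var_hand = v10.var(ddof=1) / 3 + v01.var(ddof=1) / 3
        assert var == pytest.approx(var_hand, abs=1e-15)

    def test_identical_scores_give_null_contrast(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        cmp = delong_contrast(scores, scores, labels)
        assert cmp.z == 0.0 and cmp.p == 1.0
        assert cmp.auc_a == cmp.auc_b

    def test_detects_a_strictly_better_predictor(self, rng):
        n = 600
        labels = rng.integers(0, 2, n)
        signal = labels + rng.normal(0, 0.7, n)
        noise = rng.normal(0, 1, n)
        cmp = delong_contrast(signal, noise, labels)
        assert cmp.auc_a > cmp.auc_b
        assert cmp.p < 0.001

    def test_antisymmetric_in_the_two_predictors(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        ab = delong_contrast(a, b, labels)
        ba = delong_contrast(b, a, labels)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p == pytest.approx(ba.p, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a shape"):
            delong_contrast(np.zeros(5), np.zeros(6), np.zeros(5, dtype=int))


class TestHarrellC:
    def test_equals_auc_without_censoring(self, rng):
        n = 300
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        # all subjects observed; binary outcome encoded as short/long times
        times = np.where(labels == 1, 1.0, 2.0)
        events = np.ones(n, dtype=int)
        c = harrell_c(times, events, scores).c_index
        auc, _ = auc_mann_whitney(scores, labels)
        assert c == pytest.approx(auc, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        n = 400
        times = rng.exponential(2.0, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        scores = -np.log(times) + rng.normal(0, 1, n)
        c = harrell_c(times, events, scores).c_index
        # lifelines orders by predicted survival time (negated risk)
        ref = concordance_index(times, -scores, events)
        assert c == pytest.approx(ref, abs=1e-12)

    def test_censored_after_event_pairs_usable(self):
        # subject 0 fractures at t=1; subject 1 censored at t=1 is known to
        # survive past the event, so the pair is usable
        times = np.array([1.0, 1.0, 2.0])
        events = np.array([1, 0, 1])
        scores = np.array([3.0, 1.0, 2.0])
        res = harrell_c(times, events, scores)
        # pairs: (0,1) usable conc, (0,2) usable conc, (2,1) not usable
        # (1 censored before 2's event)
        assert res.n_concordant == 2
        assert res.c_index == 1.0

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no usable pairs"):
            harrell_c(np.array([1.0, 2.0]), np.array([0, 0]),
                      np.array([1.0, 2.0]))


class TestConcordanceContrast:
    def test_identical_scores_null(self, rng):
        n = 150
        times = rng.exponential(2.0, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        s = rng.normal(size=n)
        ra, rb, p = concordance_contrast(times, events, s, s, n_boot=50, seed=1)
        assert ra.c_index == rb.c_index
        assert p == 1.0

    def test_informative_beats_noise(self, rng):
        n = 400
        risk = rng.normal(size=n)
        times = rng.exponential(np.exp(-risk))
        events = np.ones(n, dtype=int)
        noise = rng.normal(size=n)
        ra, rb, p = concordance_contrast(times, events, risk, noise,
                                         n_boot=200, seed=2)
        assert ra.c_index > 0.65 > rb.c_index
        assert p < 0.01
        assert ra.ci95[0] < ra.c_index < ra.ci95[1]

    def test_deterministic_given_seed(self, rng):
        n = 120
        times = rng.exponential(1.0, n)
        events = rng.integers(0, 2, n)
        events[0] = 1
        a, b = rng.normal(size=n), rng.normal(size=n)
        r1 = concordance_contrast(times, events, a, b, n_boot=100, seed=9)
        r2 = concordance_contrast(times, events, a, b, n_boot=100, seed=9)
        assert r1[2] == r2[2] and r1[0].ci95 == r2[0].ci95


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        # observed counts exactly match expected within each risk block
        levels = np.arange(1, 10) / 10.0  # 0.1 .. 0.9, integer expected counts
        p = np.repeat(levels, 10)
        y = np.concatenate([
            np.r_[np.ones(round(pi * 10)), np.zeros(10 - round(pi * 10))]
            for pi in levels
        ]).astype(int)
        res = hosmer_lemeshow(p, y)
        assert res.hl_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_gross_miscalibration_detected(self, rng):
        p_true = rng.uniform(0.05, 0.95, 2000)
        y = (rng.random(2000) < p_true).astype(int)
        res = hosmer_lemeshow(p_true**3, y)  # badly distorted probabilities
        assert res.p < 1e-6

    def test_df_is_groups_minus_two(self, rng):
        p = rng.uniform(0.2, 0.8, 500)
        y = (rng.random(500) < p).astype(int)
        res = hosmer_lemeshow(p, y, n_groups=10)
        assert res.df == res.group_table.shape[0] - 2

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            hosmer_lemeshow(np.linspace(0.1, 0.9, 10),
                            np.zeros(10, dtype=int))

    def test_concentrated_probabilities_rejected(self):
        with pytest.raises(ValueError, match="concentrated"):
            hosmer_lemeshow(np.full(100, 0.3), np.zeros(100, dtype=int))


class TestSpearman:
    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 6, 400).astype(float)
        y = rng.integers(0, 4, 400).astype(float) + 0.3 * x
        ours = spearman_agreement(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert ours.spearman_rho == pytest.approx(ref_rho, abs=1e-12)
        assert ours.p == pytest.approx(ref_p, rel=1e-6)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        r1 = spearman_agreement(x, y).spearman_rho
        r2 = spearman_agreement(np.exp(x), y**3).spearman_rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_perfect_agreement(self):
        x = np.arange(20.0)
        res = spearman_agreement(x, 2 * x + 1)
        assert res.spearman_rho == 1.0
        assert res.p == 0.0

    def test_ci_behaviour(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(0, 1, 200)
        res = spearman_agreement(x, y)
        lo, hi = res.ci95
        assert lo < res.spearman_rho < hi
        assert res.n == 200

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_agreement(np.ones(20), np.arange(20.0))
        with pytest.raises(ValueError, match="at least 10"):
            spearman_agreement(np.arange(5.0), np.arange(5.0))
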