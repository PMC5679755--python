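"""ROC/AUC inference, confusion statistics, exact tests, power calculation."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from mirsig import (
    PowerSpec,
    classify_threshold,
    compare_auc_paired,
    fisher_exact_2x2,
    mann_whitney_auc,
    power_auc_superiority,
    roc_auc_delong,
    tiered_strategy,
    wilcoxon_paired,
)
from mirsig.evaluation import hanley_mcneil_var, youden_from_sweep


class TestAuc:
    def test_perfect_separation(self):
        assert mann_whitney_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_enumerated_pairs(self):
        # cases score {2, 4}, controls {1, 3}: 3 of 4 pairs concordant
        assert mann_whitney_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_all_ties_give_half(self):
        assert mann_whitney_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_mann_whitney_u_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n0 = rng.integers(3, 30, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # induce ties
            y = np.array([1] * n1 + [0] * n0)
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            assert mann_whitney_auc(scores, y) == pytest.approx(u / (n1 * n0))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([1, 2], [1, 1])

    @given(
        scores=st.lists(
            st.integers(min_value=-5, max_value=5), min_size=4, max_size=30
        ),
        split=st.integers(min_value=2, max_value=28),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_property_matches_independent_roc_implementation(self, scores, split):
        """AUC identity holds for arbitrary tied integer scores (independent
        oracle: sklearn's trapezoidal ROC area)."""
        from sklearn.metrics import roc_auc_score

        assume(2 <= split <= len(scores) - 2)
        y = np.array([0] * split + [1] * (len(scores) - split))
        assert mann_whitney_auc(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )


class TestDeLong:
    def test_ci_contains_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=80) + np.repeat([0, 1], 40)
        roc = roc_auc_delong(scores, np.repeat([0, 1], 40))
        assert roc.ci[0] <= roc.auc <= roc.ci[1]
        assert 0 <= roc.auc <= 1

    def test_identical_scores_give_zero_delta_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=60)
        y = np.repeat([0, 1], 30)
        delta, p = compare_auc_paired(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_perfect_vs_useless_highly_significant(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        perfect = y + rng.uniform(0, 0.1, 200)
        useless = rng.normal(size=200)
        _, p = compare_auc_paired(perfect, useless, y)
        assert p < 0.001

    def test_p_agrees_with_paired_bootstrap(self):
        """Oracle: 10,000-replicate paired bootstrap of the AUC difference."""
        rng = np.random.default_rng(4)
        n = 120
        y = np.repeat([0, 1], n // 2)
        latent = rng.normal(size=n) + 0.9 * y
        a = latent + rng.normal(0, 0.8, n)
        b = rng.normal(size=n) + 0.4 * y
        delta, p = compare_auc_paired(a, b, y)
        boots = []
        idx = np.arange(n)
        for _ in range(10000):
            s = rng.choice(idx, size=n, replace=True)
            if len(np.unique(y[s])) < 2:
                continue
            boots.append(mann_whitney_auc(a[s], y[s]) - mann_whitney_auc(b[s], y[s]))
        boots = np.asarray(boots)
        z = delta / boots.std(ddof=1)
        p_boot = 2 * stats.norm.sf(abs(z))
        assert abs(p - p_boot) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_paired([1, 2], [1, 2, 3], [0, 1])


class TestYouden:
    def test_enumerated_options(self):
        cutoff, j = youden_from_sweep([3, 2, 1], [1.0, 0.8, 0.3], [0.2, 0.7, 0.9])
        assert cutoff == 2 and j == pytest.approx(0.5)

    def test_perfect_classifier_j_one(self):
        roc = roc_auc_delong([0, 0, 1, 1], [0, 0, 1, 1])
        assert roc.youden_j == pytest.approx(1.0)

    def test_ties_resolve_toward_specificity(self):
        cutoff, j = youden_from_sweep([1, 2], [0.9, 0.6], [0.3, 0.6])
        assert j == pytest.approx(0.2)
        assert cutoff == 2  # equal J, higher specificity wins

    def test_all_tied_scores_j_zero(self):
        roc = roc_auc_delong([1, 1, 1, 1], [0, 1, 0, 1])
        assert roc.youden_j == pytest.approx(0.0)


class TestClassifyThreshold:
    def test_exact_half_is_negative(self):
        c = classify_threshold([0.5], [1])
        assert c.fn == 1 and c.tp == 0

    def test_printed_rate_arithmetic(self):
        """23 FP and 16 FN among 120 subjects -> 19.2% and 13.3% at 1 dp."""
        y = np.array([1] * 50 + [0] * 70)
        p = np.concatenate([np.r_[np.ones(34), np.zeros(16)], np.r_[np.ones(23), np.zeros(47)]])
        c = classify_threshold(p, y)
        assert (c.fp, c.fn, c.n) == (23, 16, 120)
        assert c.rates_pct()["fp_rate"] == 19.2
        assert c.rates_pct()["fn_rate"] == 13.3

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            classify_threshold([1.2], [1])


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fully_discordant_table(self):
        from math import comb

        assert fisher_exact_2x2([[0, 10], [10, 0]]) == pytest.approx(2 / comb(20, 10))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_matches_hypergeometric_enumeration(self):
        """Probability-mass two-sided p recomputed by direct enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(enumerate_fisher(t), abs=1e-12)


def enumerate_fisher(t):
    t = np.asarray(t)
    N = t.sum()
    K = t[:, 0].sum()
    n = t[0].sum()
    lo, hi = max(0, n - (N - K)), min(K, n)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, N, K, n)
    obs = stats.hypergeom.pmf(t[0, 0], N, K, n)
    return pmf[pmf <= obs * (1 + 1e-10)].sum()


class TestTiered:
    def test_secondary_never_positive_is_identity(self):
        y = np.array([0, 1, 0, 1])
        r = tiered_strategy([1, 0, 0, 1], [0, 0, 0, 0], y)
        a, t = r["primary"], r["tiered"]
        assert (a.tp, a.fp, a.tn, a.fn) == (t.tp, t.fp, t.tn, t.fn)

    def test_secondary_always_positive_floods(self):
        y = np.array([0, 1, 0, 1])
        r = tiered_strategy([0, 0, 0, 0], [1, 1, 1, 1], y)
        assert r["tiered"].sensitivity == 1.0 and r["tiered"].specificity == 0.0

    def test_monotone_sensitivity_specificity(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            y = rng.integers(0, 2, 50)
            a = rng.integers(0, 2, 50)
            b = rng.integers(0, 2, 50)
            if y.min() == y.max():
                continue
            r = tiered_strategy(a, b, y)
            assert r["tiered"].sensitivity >= r["primary"].sensitivity
            assert r["tiered"].specificity <= r["primary"].specificity

    def test_engineered_false_positive_escalation(self):
        """Counts engineered so the second-look marker raises overall FP from
        5/120 (4.2%) to 23/120 (19.2%)."""
        y = np.array([1] * 50 + [0] * 70)
        primary = np.array([1] * 43 + [0] * 7 + [1] * 5 + [0] * 65)
        secondary = np.zeros(120, int)
        secondary[55:73] = 1  # 18 extra false positives among primary negatives
        r = tiered_strategy(primary, secondary, y)
        assert r["primary"].rates_pct()["fp_rate"] == 4.2
        assert r["tiered"].rates_pct()["fp_rate"] == 19.2


class TestWilcoxon:
    def test_identical_vectors(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_paired([1, 2, 3], [1, 2, 3]) == 1.0

    def test_five_concordant_pairs_exact(self):
        assert wilcoxon_paired([5, 6, 7, 8, 9], [1, 2, 3, 4, 5]) == pytest.approx(
            2 / 32
        )

    def test_exact_matches_sign_enumeration(self):
        """Oracle: enumerate all 2^n sign patterns at n = 10."""
        rng = np.random.default_rng(7)
        pre = rng.normal(size=10)
        post = pre + rng.normal(0.4, 1.0, 10)
        d = post - pre
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = []
        for mask in range(2**10):
            signs = np.array([(mask >> i) & 1 for i in range(10)])
            ws.append((ranks * signs).sum())
        ws = np.asarray(ws)
        p_lo = (ws <= w_obs + 1e-9).mean()
        p_hi = (ws >= w_obs - 1e-9).mean()
        expected = min(1.0, 2 * min(p_lo, p_hi))
        assert wilcoxon_paired(pre, post) == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_near_exact(self):
        rng = np.random.default_rng(8)
        pre = rng.normal(size=12)
        post = pre + rng.normal(0.5, 1.0, 12)
        exact = wilcoxon_paired(pre, post)
        approx = wilcoxon_paired(pre, post, exact_max_n=0)
        assert abs(exact - approx) < 0.05


class TestPower:
    def test_required_n_decreases_with_effect(self):
        ns = [
            power_auc_superiority(PowerSpec(auc_null=0.75, auc_alt=alt))["n_cases"]
            for alt in (0.80, 0.85, 0.90, 0.95)
        ]
        assert ns == sorted(ns, reverse=True)

    def test_alt_not_above_null_rejected(self):
        with pytest.raises(ValueError):
            power_auc_superiority(PowerSpec(auc_null=0.8, auc_alt=0.8)).items()

    def test_training_multiplier(self):
        out = power_auc_superiority(PowerSpec(auc_null=0.75, auc_alt=0.9))
        assert out["n_total_with_training"] == out["n_test_total"] * 4

    def test_analytic_n_matches_monte_carlo_power_search(self):
        """Oracle: 20,000-replicate binormal simulation of the same test."""
        spec = PowerSpec(auc_null=0.70, auc_alt=0.88)
        n_analytic = power_auc_superiority(spec)["n_cases"]
        rng = np.random.default_rng(9)
        delta = stats.norm.ppf(spec.auc_alt) * np.sqrt(2)
        z_a = stats.norm.ppf(1 - spec.alpha / 2)

        def mc_power(n, reps=20000):
            cases = rng.normal(delta, 1, size=(reps, n))
            controls = rng.normal(0, 1, size=(reps, n))
            wins = (cases[:, :, None] > controls[:, None, :]).mean(axis=(1, 2))
            crit = spec.auc_null + z_a * np.sqrt(
                hanley_mcneil_var(spec.auc_null, n, n)
            )
            return (wins > crit).mean()

        # the smallest n achieving 80% MC power is within 2 of the analytic n
        assert mc_power(n_analytic) >= 0.78
        assert mc_power(max(2, n_analytic - 3)) < 0.82
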