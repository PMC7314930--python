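"""Rates, Wilson-CC intervals, Youden, censored-score ROC/DeLong, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from methpanel.stats import (
    compare_positivity,
    delong_auc_ci,
    detection_rate,
    proportion_ci,
    roc_curve,
    round_half_up,
    wilson_cc_interval,
    youden,
)

# Reference intervals reported for the assay (counts -> printed percent CI).
PRINTED_INTERVALS = [
    (4, 6, (24.1, 94.0)), (49, 55, (77.1, 95.5)), (59, 65, (80.3, 96.2)),
    (6, 65, (3.8, 19.7)), (46, 55, (70.7, 91.8)), (43, 55, (64.6, 87.8)),
    (0, 65, (0.0, 7.0)), (6, 6, (51.7, 100.0)), (5, 6, (36.5, 99.1)),
    (2, 6, (6.0, 75.9)), (36, 39, (78.0, 98.0)), (55, 59, (82.7, 97.8)),
    (27, 65, (29.7, 54.4)), (15, 65, (13.9, 35.5)), (50, 55, (79.3, 96.6)),
    (17, 65, (16.4, 38.8)), (54, 55, (89.0, 99.9)), (35, 65, (41.1, 66.1)),
    (3, 6, (13.9, 86.1)), (8, 65, (5.8, 23.4)), (5, 65, (2.9, 17.8)),
    (12, 65, (10.3, 30.4)), (48, 55, (74.9, 94.3)), (16, 65, (15.1, 37.1)),
    (19, 65, (18.9, 42.0)),
]


class TestDetectionRate:
    def test_values(self):
        assert round_half_up(100 * detection_rate(49, 55)) == 89.1
        assert round_half_up(100 * detection_rate(52, 55)) == 94.5
        assert detection_rate(0, 65) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            detection_rate(0, 0)


class TestWilsonCC:
    @pytest.mark.parametrize("k, n, expected", PRINTED_INTERVALS)
    def test_reproduces_reported_intervals(self, k, n, expected):
        lo, hi = wilson_cc_interval(k, n)
        assert (round_half_up(100 * lo), round_half_up(100 * hi)) == expected

    def test_clamps(self):
        lo, _ = wilson_cc_interval(0, 10)
        _, hi = wilson_cc_interval(10, 10)
        assert lo == 0.0 and hi == 1.0

    @given(n=st.integers(1, 500), frac=st.floats(0, 1), conf=st.floats(0.5, 0.999))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_contains_point_estimate(self, n, frac, conf):
        k = round(frac * n)
        lo, hi = wilson_cc_interval(k, n, conf)
        assert lo <= k / n <= hi
        assert 0.0 <= lo <= hi <= 1.0

    @given(n=st.integers(4, 300), k=st.integers(1, 299))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_width_shrinks_with_doubled_counts(self, n, k):
        k = min(k, n - 1)
        lo1, hi1 = wilson_cc_interval(k, n)
        lo2, hi2 = wilson_cc_interval(2 * k, 2 * n)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_other_methods_differ(self):
        # plain Wilson and Clopper-Pearson do NOT reproduce the printed 4/6 CI
        assert proportion_ci(4, 6) == wilson_cc_interval(4, 6)
        for method in ("wilson", "clopper_pearson"):
            lo, hi = proportion_ci(4, 6, method=method)
            assert (round_half_up(100 * lo), round_half_up(100 * hi)) != (24.1, 94.0)


class TestYouden:
    def test_reported_values(self):
        assert round_half_up(100 * youden(49 / 55, 59 / 65)) == 79.9
        assert round_half_up(100 * youden(52 / 55, 1 - 19 / 65)) == 65.3
        assert youden(1, 1) == 1

    @given(rc=st.floats(0, 1), rx=st.floats(0, 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_two_phrasings_coincide(self, rc, rx):
        # sens + spec - 1 with spec = 1 - control rate equals case - control rate
        assert youden(rx, 1 - rc) == pytest.approx(rx - rc, abs=1e-12)


def brute_force_auc(scores, labels):
    """Exhaustive pairwise rank statistic: P(case < control) + half-ties."""
    cases = [s for s, l in zip(scores, labels) if l]
    controls = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c < d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestRoc:
    def test_perfect_separation(self):
        scores = [30.0] * 5 + [50.0] * 5
        labels = [True] * 5 + [False] * 5
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(1.0)

    def test_identical_distributions(self):
        scores = [30.0, 40.0, 50.0] * 2
        labels = [True] * 3 + [False] * 3
        assert roc_curve(scores, labels).auc == pytest.approx(0.5)

    def test_anchored_and_monotone(self, training_cohort):
        from methpanel.calling import censored_scores
        labels = training_cohort.frame["group"] == "CRC"
        keep = training_cohort.frame["group"].isin(["control", "CRC"])
        curve = roc_curve(censored_scores(training_cohort, "panel")[keep],
                          labels[keep])
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert (np.diff(curve.tpr) >= 0).all() and (np.diff(curve.fpr) >= 0).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_auc_equals_pairwise_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n_case = int(rng.integers(1, 31))
        n_ctrl = int(rng.integers(1, 31))
        # censored-like scores with heavy ties, including the mass at 50.0
        pool = np.r_[rng.uniform(30, 45, 40), np.full(20, 50.0)]
        scores = rng.choice(pool, n_case + n_ctrl)
        labels = np.r_[np.ones(n_case, bool), np.zeros(n_ctrl, bool)]
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        scores = np.round(rng.uniform(30, 50, 80), 1)
        labels = rng.random(80) < 0.4
        ours = roc_curve(scores, labels).auc
        theirs = sklearn.roc_auc_score(labels, -scores)  # lower score = case
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])


class TestDeLong:
    def test_clamped_at_perfect_separation(self):
        scores = [30.0] * 10 + [50.0] * 10
        labels = [True] * 10 + [False] * 10
        auc, (lo, hi) = delong_auc_ci(scores, labels)
        assert auc == 1.0 and hi == 1.0 and lo <= 1.0

    def test_symmetric_under_no_signal(self):
        scores = list(range(10)) * 2
        labels = [True] * 10 + [False] * 10
        auc, (lo, hi) = delong_auc_ci([float(s) for s in scores], labels)
        assert auc == pytest.approx(0.5)
        assert (0.5 - lo) == pytest.approx(hi - 0.5, abs=1e-9)

    def test_against_bootstrap_oracle(self):
        rng = np.random.default_rng(42)
        cases = rng.normal(36, 3, 40)
        controls = np.where(rng.random(50) < 0.6, 50.0, rng.normal(42, 3, 50))
        scores = np.r_[cases, controls]
        labels = np.r_[np.ones(40, bool), np.zeros(50, bool)]
        _, (lo, hi) = delong_auc_ci(scores, labels)
        boots = []
        for _ in range(2000):
            ic = rng.integers(0, 40, 40)
            in_ = rng.integers(40, 90, 50)
            idx = np.r_[ic, in_]
            boots.append(roc_curve(scores[idx], labels[idx]).auc)
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.03)
        assert hi == pytest.approx(bhi, abs=0.03)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            delong_auc_ci([1.0, 2.0, 3.0], [True, False, False])


class TestComparePositivity:
    def test_identical_arms(self):
        arm = [True] * 5 + [False] * 5
        assert compare_positivity(arm, arm) == pytest.approx(1.0, abs=1e-9)
        assert compare_positivity([True] * 4, [True] * 4) == 1.0

    def test_agrees_with_direct_welch_formula(self):
        a = np.r_[np.ones(46), np.zeros(7)]
        b = np.r_[np.ones(29), np.zeros(12)]
        p = compare_positivity(a, b)
        # independent two-sample t with Welch-Satterthwaite df, by hand
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        expected = 2 * sps.t.sf(abs(t), df)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_chi2_matches_reported_sex_comparison(self):
        # mSEPT9 positivity male 46/53 vs female 29/41 was reported as p=0.054;
        # the chi-square (no correction) variant reproduces that figure.
        a = [True] * 46 + [False] * 7
        b = [True] * 29 + [False] * 12
        assert round_half_up(compare_positivity(a, b, "chi2"), 3) == 0.054
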