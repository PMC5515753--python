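"""Evaluation statistics against independent oracles.

Each routine is checked two ways where possible: a hand-rolled brute-force
oracle (pairwise concordance for AUC, exhaustive threshold scan for the
Youden cutoff, integer-arithmetic hypergeometric enumeration for Fisher)
and an established library implementation (sklearn / scipy).
"""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from lhirisk import (
    auc_mann_whitney,
    best_cutoff,
    fisher_exact,
    pct,
    pearson_chi2,
    roc_curve,
    sens_spec,
    two_sample_t,
)
from lhirisk.stats import DegenerateInputError

# ---------------------------------------------------------------- oracles


def concordance_auc(scores, labels):
    """Brute-force Mann-Whitney AUC over all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def scan_best_cutoff(scores, labels):
    """Exhaustive Youden maximization over every candidate threshold."""
    candidates = [math.inf] + sorted(set(scores), reverse=True)
    best = None
    for t in candidates:
        se, sp = confusion_sens_spec(scores, labels, t)
        key = (se + sp - 1.0, se, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return best[1]


def confusion_sens_spec(scores, labels, cutoff):
    tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= cutoff)
    fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < cutoff)
    tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < cutoff)
    fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= cutoff)
    return tp / (tp + fn), tn / (tn + fp)


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p by exact integer enumeration (no scipy)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def mixed_labels(draw, n):
    labels = draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)
        )
    )
    return labels


scores_labels = st.integers(4, 30).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 8), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)
        ),
    )
)

# ---------------------------------------------------------------- ROC / AUC


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert best_cutoff(roc) == 3

    def test_no_discrimination_all_tied(self):
        roc = roc_curve([2, 2, 2, 2], [0, 1, 0, 1])
        assert roc.auc == 0.5
        # the single real threshold is the only informative operating point
        assert best_cutoff(roc) == 2

    def test_half_auc_one_concordant_one_discordant(self):
        assert roc_curve([1, 2, 3], [0, 1, 0]).auc == 0.5

    def test_endpoints(self):
        roc = roc_curve([1, 2, 3, 4], [0, 1, 0, 1])
        t, se, sp = roc.points[0]
        assert (t, se, sp) == (math.inf, 0.0, 1.0)
        t, se, sp = roc.points[-1]
        assert (se, sp) == (1.0, 0.0)

    def test_monotone_curve(self):
        roc = roc_curve([3, 1, 4, 1, 5, 9, 2, 6], [0, 0, 1, 0, 1, 1, 0, 1])
        sens = [se for _, se, _ in roc.points]
        spec = [sp for _, _, sp in roc.points]
        assert sens == sorted(sens)
        assert spec == sorted(spec, reverse=True)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_curve([1, 2, 3], [1, 1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(scores_labels)
    def test_trapezoid_equals_concordance_and_sklearn(self, data):
        scores, labels = data
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)
        assert roc.auc == pytest.approx(auc_mann_whitney(scores, labels), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(scores_labels)
    def test_label_reversal_maps_auc_to_complement(self, data):
        scores, labels = data
        flipped = [1 - y for y in labels]
        assert roc_curve(scores, labels).auc == pytest.approx(
            1.0 - roc_curve(scores, flipped).auc, abs=1e-12
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(scores_labels)
    def test_best_cutoff_matches_exhaustive_scan(self, data):
        scores, labels = data
        roc = roc_curve(scores, labels)
        assert best_cutoff(roc) == scan_best_cutoff(scores, labels)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(scores_labels)
    def test_roc_point_consistent_with_sens_spec(self, data):
        scores, labels = data
        roc = roc_curve(scores, labels)
        for t, se, sp in roc.points[1:]:
            se2, sp2 = sens_spec(scores, labels, t)
            assert (se, sp) == (se2, sp2)


class TestSensSpec:
    @pytest.mark.parametrize(
        "scores, labels, cutoff, expected",
        [
            ([0, 1, 2, 3], [0, 0, 1, 1], 2, (1.0, 1.0)),
            ([0, 1, 2, 3], [0, 1, 0, 1], 2, (0.5, 0.5)),
            ([0, 1, 2, 3], [0, 0, 1, 1], 99, (0.0, 1.0)),
        ],
    )
    def test_confusion_counts(self, scores, labels, cutoff, expected):
        assert sens_spec(scores, labels, cutoff) == expected


# ---------------------------------------------------------------- 2x2 tests


class TestPearsonChi2:
    def test_equal_proportions_give_zero(self):
        stat, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "table, printed_p",
        [
            ([[11, 22], [6, 38]], 0.04),   # stroke in progression by group
            ([[18, 15], [13, 31]], 0.03),  # early brain edema by group
            ([[18, 15], [11, 33]], 0.008), # hyperdense MCA sign by group
        ],
    )
    def test_reproduces_published_group_comparisons(self, table, printed_p):
        _, p = pearson_chi2(table)
        decimals = len(str(printed_p).split(".")[1])
        assert round(p, decimals) == printed_p

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_matches_scipy_and_symmetries(self, cells):
        a, b, c, d = cells
        stat, p = pearson_chi2([[a, b], [c, d]])
        s2, p2, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(s2, rel=1e-12)
        assert p == pytest.approx(p2, rel=1e-9, abs=1e-12)
        # transposition and simultaneous row/column swap invariance
        assert pearson_chi2([[a, c], [b, d]])[0] == pytest.approx(stat, rel=1e-12)
        assert pearson_chi2([[d, c], [b, a]])[0] == pytest.approx(stat, rel=1e-12)

    def test_yates_correction_flag(self):
        stat, _ = pearson_chi2([[11, 22], [6, 38]], correction=True)
        s2, _, _, _ = sps.chi2_contingency([[11, 22], [6, 38]], correction=True)
        assert stat == pytest.approx(s2, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi2([[0, 0], [5, 5]])


class TestFisherExact:
    def test_symmetric_modal_table(self):
        assert fisher_exact([[5, 5], [5, 5]]) == 1.0

    def test_tiny_table_by_enumeration(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(
            fisher_enumeration(2, 0, 0, 2), abs=1e-12
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 12)] * 4))
    def test_matches_enumeration_and_scipy(self, cells):
        a, b, c, d = cells
        p = fisher_exact([[a, b], [c, d]])
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-9)
        assert p == pytest.approx(
            sps.fisher_exact([[a, b], [c, d]])[1], abs=1e-9
        )


class TestTwoSampleT:
    def test_identical_samples(self):
        assert two_sample_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_large_shift_is_significant(self):
        stat, p = two_sample_t([1, 2, 3], [11, 12, 13])
        assert abs(stat) > 5 and p < 0.01

    def test_constant_unequal_samples_signal_infinity(self):
        stat, p = two_sample_t([5, 5], [3, 3])
        assert math.isinf(stat) and stat > 0 and p == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-50, 50), min_size=2, max_size=15),
        st.lists(st.integers(-50, 50), min_size=2, max_size=15),
        st.booleans(),
    )
    def test_matches_closed_form_and_scipy(self, xs, ys, welch):
        stat, p = two_sample_t(xs, ys, welch=welch)
        res = sps.ttest_ind(xs, ys, equal_var=not welch)
        if math.isinf(stat) or math.isnan(res.statistic):
            return  # scipy returns nan for zero-variance input
        assert stat == pytest.approx(res.statistic, rel=1e-10, abs=1e-12)
        assert p == pytest.approx(res.pvalue, rel=1e-9, abs=1e-12)

    def test_pooled_formula_direct(self):
        xs, ys = [1.0, 4.0, 6.0], [2.0, 2.5, 7.0, 9.0]
        n1, n2 = 3, 4
        m1, m2 = np.mean(xs), np.mean(ys)
        sp2 = ((n1 - 1) * np.var(xs, ddof=1) + (n2 - 1) * np.var(ys, ddof=1)) / 5
        expected = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert two_sample_t(xs, ys)[0] == pytest.approx(expected, rel=1e-12)


class TestPct:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(33, 77, 42.9), (44, 77, 57.1), (9, 77, 11.7), (0, 77, 0.0),
         (17, 77, 22.1), (8, 33, 24.2)],
    )
    def test_published_percentages(self, k, n, expected):
        assert pct(k, n) == expected

    def test_half_up_rounding(self):
        # 1/8 = 12.5% exactly: half-up gives 12.5 -> 13 at 0 decimals
        assert pct(1, 8, 0) == 13.0
        assert pct(1, 8, 1) == 12.5

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pct(1, 0)
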