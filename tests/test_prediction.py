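"""ROC construction, AUC, constrained cutoff search and rank tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerconcord.prediction import (
    ResponsePredictor,
    auc_with_p,
    constrained_cutoff,
    mann_whitney,
    response_rates,
    roc_curve,
)
from markerconcord.status import dichotomize_expression


def as_vl(pos, neg):
    values = list(pos) + list(neg)
    labels = [1] * len(pos) + [0] * len(neg)
    return values, labels


class TestRocCurve:
    def test_perfect_separation_has_perfect_point(self):
        curve = roc_curve(*as_vl([10, 12], [1, 2, 3]))
        both = (curve.sensitivity == 1.0) & (curve.specificity == 1.0)
        assert both.any()

    def test_all_identical_values_degenerate(self):
        curve = roc_curve(*as_vl([5.0], [5.0, 5.0]))
        assert len(curve.thresholds) == 2
        pts = set(zip(curve.sensitivity, curve.specificity))
        assert pts == {(1.0, 0.0), (0.0, 1.0)}

    def test_midpoints_verified_by_brute_force(self):
        pos, neg = [3.0, 1.0], [2.0, 0.0]
        curve = roc_curve(*as_vl(pos, neg))
        # sentinels + 3 midpoints of the 4 distinct values
        assert list(curve.thresholds) == [-1.0, 0.5, 1.5, 2.5, 4.0]
        for t, sens, spec in zip(curve.thresholds, curve.sensitivity, curve.specificity):
            assert sens == np.mean([v >= t for v in pos])
            assert spec == np.mean([v < t for v in neg])

    def test_sensitivity_non_increasing(self, rng):
        for _ in range(50):
            values = rng.normal(size=20)
            labels = rng.integers(0, 2, 20)
            if labels.sum() in (0, 20):
                continue
            curve = roc_curve(values, labels)
            assert (np.diff(curve.sensitivity) <= 1e-12).all()
            assert (np.diff(curve.specificity) >= -1e-12).all()

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="responder"):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestAuc:
    def test_perfect_separation(self):
        assert auc_with_p(*as_vl([10, 12], [1, 2, 3])).auc == 1.0

    def test_all_ties(self):
        res = auc_with_p(*as_vl([5.0, 5.0], [5.0, 5.0]))
        assert res.auc == 0.5
        assert res.p_vs_half == 1.0

    def test_exhaustive_pair_counting(self):
        # pairs (3,2),(3,0),(1,0) favorable; (1,2) not -> 3/4
        assert auc_with_p(*as_vl([3, 1], [2, 0])).auc == pytest.approx(0.75)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_invariance_under_monotone_transform(self, data):
        n_pos = data.draw(st.integers(1, 8))
        n_neg = data.draw(st.integers(1, 8))
        # grid-valued draws keep the transforms strictly monotone in float
        vals = [
            v / 100.0
            for v in data.draw(
                st.lists(
                    st.integers(min_value=-500, max_value=500),
                    min_size=n_pos + n_neg,
                    max_size=n_pos + n_neg,
                )
            )
        ]
        labels = [1] * n_pos + [0] * n_neg
        base = auc_with_p(vals, labels).auc
        for f in (np.exp, lambda v: np.asarray(v) ** 3, lambda v: 3 * np.asarray(v) + 7):
            assert auc_with_p(f(np.array(vals)), labels).auc == pytest.approx(base)


class TestConstrainedCutoff:
    def test_fix_sensitivity_perfect_split(self):
        res = constrained_cutoff(*as_vl([10, 12], [1, 2, 3]), "sensitivity", 1.0)
        assert res.cutoff == pytest.approx(6.5)  # midpoint of 3 and 10
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_tied_responder_and_nonresponder(self):
        res = constrained_cutoff(*as_vl([5.0], [5.0]), "sensitivity", 1.0)
        assert res.sensitivity == 100.0 and res.specificity == 0.0

    def test_tie_break_toward_larger_cutoff(self):
        # both sentinel and low midpoints give specificity 0; pick largest eligible
        values, labels = as_vl([4.0, 6.0], [1.0])
        res = constrained_cutoff(values, labels, "sensitivity", 1.0)
        assert res.cutoff == pytest.approx(2.5)
        assert res.specificity == 100.0

    def test_fix_specificity(self):
        values, labels = as_vl([3.0, 1.0], [2.0, 0.0])
        res = constrained_cutoff(values, labels, "specificity", 1.0)
        # need every non-responder below the threshold: t > 2 -> only {3} positive
        assert res.cutoff == pytest.approx(2.5)
        assert res.specificity == 100.0 and res.sensitivity == 50.0

    def test_unknown_axis(self):
        with pytest.raises(ValueError, match="axis"):
            constrained_cutoff([1, 2], [0, 1], "accuracy", 1.0)

    def test_reclassification_reproduces_reported_rates(self, rng):
        for _ in range(50):
            pos = rng.normal(1, 1, int(rng.integers(2, 10)))
            neg = rng.normal(0, 1, int(rng.integers(2, 15)))
            values, labels = as_vl(pos, neg)
            res = constrained_cutoff(values, labels, "sensitivity", 1.0)
            calls = [dichotomize_expression(v, res.cutoff) for v in values]
            sens = np.mean([c == "high" for c, y in zip(calls, labels) if y == 1])
            spec = np.mean([c == "low" for c, y in zip(calls, labels) if y == 0])
            assert 100 * sens == pytest.approx(res.sensitivity)
            assert 100 * spec == pytest.approx(res.specificity)


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)
        assert res.p_value >= 0.99

    def test_exact_enumeration_small(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_exact_vs_normal_approximation(self, rng):
        """The two p-value routes agree closely at n1=n2=8 without ties."""
        for _ in range(20):
            pool = rng.permutation(rng.normal(size=16))
            pos, neg = pool[:8], pool[8:]
            exact = mann_whitney(pos, neg)
            assert exact.method == "exact"
            # force the approximation by inflating n past the exact threshold
            from scipy import stats

            approx = stats.mannwhitneyu(
                pos, neg, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            assert exact.p_value == pytest.approx(float(approx.pvalue), abs=0.02)

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])


class TestResponseRates:
    def test_study_style_rates(self):
        statuses = {f"H{i}": "high" for i in range(24)}
        statuses.update({f"L{i}": "low" for i in range(59)})
        outcomes = {k: 0 for k in statuses}
        for i in range(9):
            outcomes[f"H{i}"] = 1
        table = response_rates(statuses, outcomes)
        assert table.rate_high == pytest.approx(37.5)
        assert table.rate_low == 0.0
        assert table.fisher_p < 0.001

    def test_empty_stratum_rate_missing(self):
        table = response_rates({"A": "high", "B": "high"}, {"A": 1, "B": 0})
        assert table.rate_low is None
        assert table.n_low == 0

    def test_qihc_style_rate(self):
        statuses = {f"H{i}": "high" for i in range(44)}
        outcomes = {k: (1 if i < 9 else 0) for i, k in enumerate(statuses)}
        table = response_rates(statuses, outcomes)
        assert table.rate_high == pytest.approx(100 * 9 / 44)
        assert round(table.rate_high, 1) == 20.5


def test_model_fit_summary_roundtrip(rng):
    values = np.concatenate([rng.normal(1.5, 1, 12), rng.normal(0, 1, 70)])
    labels = np.array([1] * 12 + [0] * 70)
    model = ResponsePredictor(values, labels, assay="rt_qpcr")
    res = model.fit()
    row = res.summary().iloc[0]
    assert row["n"] == 82 and row["n_pcr"] == 12
    assert row["sensitivity"] == 100.0
    assert 0.5 < row["auc"] <= 1.0
    # the high/low split at the returned cutoff matches the reported counts
    assert res.rates.n_high + res.rates.n_low == 82
    assert res.rates.n_high_pcr == 12  # all responders above the cutoff
    pts = res.roc_points()
    assert len(pts) == len(res.roc.thresholds)
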