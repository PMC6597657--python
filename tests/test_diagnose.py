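"""Threshold classification, exact intervals, optimal thresholds, and the
count-recovery enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.stats import binom

from octmorph import reference as R
from octmorph.diagnose import (DiagRule, apply_rule, clopper_pearson,
                               counts_from_rates, diagnostic_metrics,
                               optimal_threshold)
from octmorph.scan import ScanMeta
from octmorph.synth import sample_cohort


def _toy_cohort(case_vals, ctrl_vals, param="v"):
    rows = []
    for i, v in enumerate(case_vals):
        rows.append({"participant_id": f"c{i}", "group": "case", "eye": "OD",
                     "age_years": 5.0, "affected": True, param: v})
    for i, v in enumerate(ctrl_vals):
        rows.append({"participant_id": f"h{i}", "group": "control", "eye": "OD",
                     "age_years": 5.0, "affected": False, param: v})
    return pd.DataFrame(rows)


class TestApplyRule:
    def test_perfect_separation(self):
        cohort = _toy_cohort([3.0, 4.0], [1.0, 2.0])
        c = apply_rule(cohort, DiagRule("v", 2.5, "ge_is_case"))
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 0, 2)

    def test_threshold_above_all(self):
        cohort = _toy_cohort([3.0, 4.0], [1.0, 2.0])
        c = apply_rule(cohort, DiagRule("v", 99.0, "ge_is_case"))
        res = diagnostic_metrics(c.tp, c.fp, c.fn, c.tn)
        assert res.sensitivity.value == 0.0
        assert res.specificity.value == 100.0

    def test_ties_count_positive_for_ge(self):
        cohort = _toy_cohort([2.0], [2.0])
        c = apply_rule(cohort, DiagRule("v", 2.0, "ge_is_case"))
        assert c.tp == 1 and c.fp == 1

    def test_sampled_cohort_brackets_published_rates(self):
        """A cohort drawn from the published cup:disc-ratio distributions
        classified at 0.5 gives accuracy whose exact CI covers the
        published 81.5% / 80.0%."""
        cohort = sample_cohort(R.PCG, R.PCG_CONTROL, 20, 20, seed=21)
        c = apply_rule(cohort, DiagRule("cup_disc_ratio", 0.5, "ge_is_case"))
        res = diagnostic_metrics(c.tp, c.fp, c.fn, c.tn)
        assert res.sensitivity.lower <= 81.5 <= res.sensitivity.upper
        assert res.specificity.lower <= 80.0 <= res.specificity.upper

    def test_laterality_invariance(self):
        cohort = sample_cohort(R.PCG, R.PCG_CONTROL, 10, 10, seed=22)
        swapped = cohort.copy()
        swapped["eye"] = swapped["eye"].map({"OD": "OS", "OS": "OD"})
        rule = DiagRule("cup_depth_um", 600.0, "ge_is_case")
        a = apply_rule(cohort, rule, control_eyes="both")
        b = apply_rule(swapped, rule, control_eyes="both")
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)


class TestDiagnosticMetrics:
    def test_published_cup_depth_row(self):
        res = diagnostic_metrics(tp=22, fp=3, fn=5, tn=17)
        assert res.sensitivity.value == pytest.approx(81.5, abs=0.05)
        assert res.specificity.value == pytest.approx(85.0, abs=0.05)
        assert res.ppv.value == pytest.approx(88.0, abs=0.05)
        assert res.npv.value == pytest.approx(77.3, abs=0.05)
        assert res.specificity.lower == pytest.approx(62.1, abs=0.05)
        assert res.specificity.upper == pytest.approx(96.8, abs=0.05)

    def test_boundary_counts(self):
        res = diagnostic_metrics(tp=10, fp=0, fn=0, tn=5)
        assert res.sensitivity.value == 100.0
        assert res.sensitivity.upper == 100.0
        res0 = diagnostic_metrics(tp=0, fp=0, fn=10, tn=5)
        assert res0.sensitivity.lower == 0.0

    def test_undefined_metric_is_none(self):
        res = diagnostic_metrics(tp=0, fp=0, fn=3, tn=2)
        assert res.ppv is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(-1, 0, 0, 0)

    @given(st.integers(1, 30), st.data())
    def test_interval_covers_point(self, n, data):
        x = data.draw(st.integers(0, n))
        lo, hi = clopper_pearson(x, n)
        assert lo <= x / n <= hi

    def test_interval_narrows_with_n(self):
        widths = []
        for n in (10, 40, 160):
            lo, hi = clopper_pearson(int(0.8 * n), n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    @pytest.mark.parametrize("n", [5, 12, 27])
    def test_against_test_inversion_oracle(self, n):
        """Beta-quantile construction equals inverting the two one-sided
        exact binomial tests."""
        alpha = 0.05
        for x in range(n + 1):
            lo, hi = clopper_pearson(x, n, alpha)
            if x > 0:
                ref_lo = brentq(lambda p: binom.sf(x - 1, n, p) - alpha / 2,
                                1e-12, 1 - 1e-12)
                assert lo == pytest.approx(ref_lo, abs=5e-6)
            if x < n:
                ref_hi = brentq(lambda p: binom.cdf(x, n, p) - alpha / 2,
                                1e-12, 1 - 1e-12)
                assert hi == pytest.approx(ref_hi, abs=5e-6)


class TestOptimalThreshold:
    def test_perfect_separation_toy(self):
        cohort = _toy_cohort([3.0, 4.0], [1.0, 2.0])
        rule, j = optimal_threshold(cohort, "v", "ge_is_case")
        assert j == pytest.approx(1.0)
        assert 2.0 < rule.threshold <= 3.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        case = rng.normal(3, 1, 25)
        ctrl = rng.normal(1.5, 1, 20)
        cohort = _toy_cohort(case, ctrl)
        rule, j = optimal_threshold(cohort, "v", "ge_is_case")
        best = -np.inf
        for thr in np.concatenate([case, ctrl]):
            sens = np.mean(case >= thr)
            spec = np.mean(ctrl < thr)
            best = max(best, sens + spec - 1.0)
        assert j == pytest.approx(best, abs=1e-12)

    def test_identical_values_error(self):
        cohort = _toy_cohort([1.0, 1.0], [1.0])
        with pytest.raises(ValueError, match="identical"):
            optimal_threshold(cohort, "v")

    def test_large_cohort_brackets_published_cup_depth_threshold(self):
        cohort = sample_cohort(R.PCG, R.PCG_CONTROL, 2000, 2000,
                               unilateral_fraction=0.0, seed=23)
        rule, _ = optimal_threshold(cohort, "cup_depth_um", "ge_is_case",
                                    control_eyes="both")
        assert 550.0 <= rule.threshold <= 650.0


class TestCountsFromRates:
    def test_published_sensitivities_force_27(self):
        n, xs = counts_from_rates([81.5, 74.1, 88.9], max_n=40)
        assert n == 27
        assert xs == {81.5: 22, 74.1: 20, 88.9: 24}

    def test_published_specificities_force_20(self):
        n, xs = counts_from_rates([80.0, 85.0, 70.0, 75.0], max_n=40)
        assert n == 20

    def test_hundred_percent(self):
        n, xs = counts_from_rates([100.0], max_n=40)
        assert xs[100.0] == n

    def test_inconsistent_rates_error(self):
        with pytest.raises(ValueError, match="no denominator"):
            counts_from_rates([13.7], max_n=10)

    @given(st.integers(3, 30), st.data())
    def test_round_trip(self, n, data):
        x = data.draw(st.integers(0, n))
        rate = round(100.0 * x / n, 1)
        n_rec, xs = counts_from_rates([rate], max_n=n)
        assert round(100.0 * xs[rate] / n_rec, 1) == rate
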