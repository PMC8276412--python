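"""Diagnostic-accuracy statistics: exact intervals, DOR, table plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from fluormargin.diagnostics import (
    ContingencyTable,
    build_contingency,
    clopper_pearson,
    diagnostic_odds_ratio,
    predictive_values,
    reclassify_abnormal,
    round_half_away,
    sensitivity_specificity,
    summarize_study,
    summarize_table,
)
from fluormargin.types import BiopsyRecord, LoadError, ParameterError


def records_from_table(t: ContingencyTable, specimen_prefix="s"):
    """Expand a 2x2 table into individual biopsy records."""
    recs = []
    combos = [("red", "pos", t.TP), ("red", "neg", t.FP),
              ("green", "pos", t.FN), ("green", "neg", t.TN)]
    i = 0
    for call, histology, count in combos:
        for _ in range(count):
            rec = BiopsyRecord(f"{specimen_prefix}{i}", 1, 10, 10, 4.0,
                               t.stratum if t.stratum != "overall" else "outside",
                               histology, 0, dose_group=t.dose_group)
            rec.call = call
            rec.red_positive = call == "red"
            recs.append(rec)
            i += 1
    return recs


class TestClopperPearson:
    @pytest.mark.parametrize("x,n,lower,upper", [
        (8, 8, 0.631, 1.000),    # PPV 8/8 inside the border, low dose
        (1, 1, 0.025, 1.000),    # single negative biopsy inside the border
        (0, 10, 0.0, 0.3085),    # x=0 closed form 1 - 0.025**(1/10)
    ])
    def test_printed_bounds(self, x, n, lower, upper):
        ci = clopper_pearson(x, n)
        assert ci.lower == pytest.approx(lower, abs=5e-4)
        assert ci.upper == pytest.approx(upper, abs=5e-4)

    def test_upper_bound_matches_binomial_tail_equation(self):
        # Independent oracle: the CP upper bound u for x successes of n
        # solves P[Bin(n, u) <= x] = alpha/2.
        x, n = 3, 17
        ci = clopper_pearson(x, n)
        u = brentq(lambda p: binom.cdf(x, n, p) - 0.025, 1e-9, 1 - 1e-9)
        assert ci.upper == pytest.approx(u, abs=1e-9)
        lo = brentq(lambda p: binom.sf(x - 1, n, p) - 0.025, 1e-9, 1 - 1e-9)
        assert ci.lower == pytest.approx(lo, abs=1e-9)

    @pytest.mark.parametrize("n", [1, 5, 8, 20, 60])
    def test_degenerate_closed_forms(self, n):
        assert clopper_pearson(n, n).lower == pytest.approx(0.025 ** (1 / n), abs=1e-10)
        assert clopper_pearson(0, n).upper == pytest.approx(1 - 0.025 ** (1 / n), abs=1e-10)

    @pytest.mark.parametrize("x,n", [(0, 4), (2, 9), (5, 5), (13, 20), (21, 22)])
    def test_matches_statsmodels_beta_method(self, x, n):
        lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
        ci = clopper_pearson(x, n)
        assert ci.lower == pytest.approx(lo, abs=1e-12)
        assert ci.upper == pytest.approx(hi, abs=1e-12)

    def test_zero_denominator_flagged(self):
        ci = clopper_pearson(0, 0)
        assert ci.estimate is None and ci.flag and (ci.lower, ci.upper) == (0.0, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            clopper_pearson(5, 3)
        with pytest.raises(ParameterError):
            clopper_pearson(1, 2, level=1.2)


class TestContingency:
    def test_pooling_matches_published_low_dose_tables(self):
        inside = ContingencyTable(8, 0, 6, 1, "inside", "low")
        outside = ContingencyTable(5, 4, 1, 21, "outside", "low")
        recs = records_from_table(inside) + records_from_table(outside, "t")
        overall = build_contingency(recs, "overall", "low")
        assert (overall.TP, overall.FP, overall.FN, overall.TN) == (13, 4, 7, 22)
        pooled = inside + outside
        assert (pooled.TP, pooled.FP, pooled.FN, pooled.TN) == (13, 4, 7, 22)

    def test_empty_and_single_cell_records(self):
        assert build_contingency([]).n == 0
        t = build_contingency(records_from_table(ContingencyTable(1, 1, 1, 1)))
        assert (t.TP, t.FP, t.FN, t.TN) == (1, 1, 1, 1)

    def test_missing_call_raises(self):
        rec = BiopsyRecord("s", 1, 0, 0, 4.0, "outside", "pos", 0)
        with pytest.raises(LoadError, match="site 1"):
            build_contingency([rec])


class TestAccuracyMeasures:
    def test_predictive_values_outside_low_dose(self):
        t = ContingencyTable(5, 4, 1, 21, "outside", "low")
        ppv, npv = predictive_values(t)
        assert 100 * ppv.estimate == pytest.approx(55.6, abs=0.05)
        assert 100 * npv.estimate == pytest.approx(95.5, abs=0.05)

    def test_predictive_values_zero_denominator(self):
        ppv, _ = predictive_values(ContingencyTable(0, 0, 3, 4))
        assert ppv.estimate is None and ppv.flag

    def test_sensitivity_specificity(self):
        t = ContingencyTable(5, 4, 1, 21, "outside", "low")
        sens, spec = sensitivity_specificity(t)
        assert 100 * sens.estimate == pytest.approx(83.3, abs=0.05)
        assert 100 * spec.estimate == pytest.approx(84.0, abs=0.05)
        sens_hi, _ = sensitivity_specificity(ContingencyTable(10, 0, 5, 0))
        assert 100 * sens_hi.estimate == pytest.approx(66.7, abs=0.05)

    @pytest.mark.parametrize("cells,dor,ci,ci_decimals", [
        ((5, 4, 1, 21), 26.3, (2.38, 288.94), 2),
        ((5, 5, 2, 20), 10.0, (1.5, 67.6), 1),
        ((15, 5, 7, 20), 8.6, (2.3, 32.4), 1),
    ])
    def test_dor_printed_values(self, cells, dor, ci, ci_decimals):
        res = diagnostic_odds_ratio(ContingencyTable(*cells))
        assert res is not None
        assert round_half_away(res[0], 1) == pytest.approx(dor)
        assert round_half_away(res[1][0], ci_decimals) == pytest.approx(ci[0])
        assert round_half_away(res[1][1], ci_decimals) == pytest.approx(ci[1])

    def test_dor_zero_cell_not_applicable(self):
        assert diagnostic_odds_ratio(ContingencyTable(8, 0, 6, 1)) is None
        res = diagnostic_odds_ratio(ContingencyTable(8, 0, 6, 1), haldane=True)
        assert res is not None and res[0] > 0

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_dor_identity_with_sens_spec(self, cells):
        # DOR == sens*spec / ((1-sens)(1-spec)) whenever all cells > 0.
        t = ContingencyTable(*cells)
        sens, spec = sensitivity_specificity(t)
        dor = diagnostic_odds_ratio(t)[0]
        expected = (sens.estimate * spec.estimate) / ((1 - sens.estimate) * (1 - spec.estimate))
        assert dor == pytest.approx(expected, rel=1e-12)

    def test_reclassify_abnormal_ppv(self):
        low = reclassify_abnormal(ContingencyTable(5, 4, 1, 21), 3)
        assert 100 * low.TP / (low.TP + low.FP) == pytest.approx(88.9, abs=0.05)
        high = reclassify_abnormal(ContingencyTable(5, 5, 2, 20), 2)
        assert 100 * high.TP / (high.TP + high.FP) == pytest.approx(70.0, abs=0.05)
        same = reclassify_abnormal(ContingencyTable(5, 4, 1, 21), 0)
        assert (same.TP, same.FP) == (5, 4)
        with pytest.raises(ParameterError):
            reclassify_abnormal(ContingencyTable(5, 4, 1, 21), 5)


class TestSummaries:
    def test_summarize_study_layout_and_suppressions(self):
        recs = []
        recs += records_from_table(ContingencyTable(8, 0, 6, 1, "inside", "low"), "a")
        recs += records_from_table(ContingencyTable(5, 4, 1, 21, "outside", "low"), "b")
        recs += records_from_table(ContingencyTable(10, 0, 5, 0, "inside", "high"), "c")
        recs += records_from_table(ContingencyTable(5, 5, 2, 20, "outside", "high"), "d")
        ctrl = records_from_table(ContingencyTable(0, 0, 0, 5, "outside", "control"), "e")
        for r in ctrl:
            r.call, r.red_positive = "green", False
        summaries, log = summarize_study(recs + ctrl)
        assert len(summaries) == 6
        assert any(e["reason_code"] == "control_excluded" for e in log)
        by_key = {(s.dose_group, s.stratum): s for s in summaries}
        assert "npv" in by_key[("low", "inside")].flags
        assert by_key[("low", "inside")].dor is None  # zero FP cell
        assert by_key[("high", "inside")].specificity.estimate is None  # TN+FP = 0
        assert by_key[("low", "outside")].dor == pytest.approx(26.25)
        # Pooling: inside + outside equals the overall table cellwise.
        for dose in ("low", "high"):
            inside, outside = by_key[(dose, "inside")].table, by_key[(dose, "outside")].table
            overall = by_key[(dose, "overall")].table
            assert (inside + outside).TP == overall.TP
            assert (inside + outside).TN == overall.TN

    def test_single_stratum_input(self):
        recs = records_from_table(ContingencyTable(3, 1, 1, 5, "outside", "high"))
        summaries, _ = summarize_study(recs)
        assert {s.stratum for s in summaries} == {"outside", "overall"}


def test_round_half_away():
    assert round_half_away(2.5, 0) == 3.0
    assert round_half_away(-2.5, 0) == -3.0
    assert round_half_away(88.88888888888889, 0) == 89.0
    assert round_half_away(100 * 5 / 9, 1) == 55.6
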