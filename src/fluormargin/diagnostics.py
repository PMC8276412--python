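"""Stratified diagnostic accuracy of the red-fluorescence call.

Builds 2x2 tables from biopsy records (TP = red call and cancer-positive
histology, etc.), and computes PPV, NPV, sensitivity and specificity with
exact (Clopper-Pearson) 95% confidence intervals, plus the diagnostic odds
ratio DOR = (TP*TN)/(FP*FN) with a normal-approximation CI on the log scale.

Reporting rules mirror the trial's tables: a zero cell anywhere makes the
DOR not applicable (no continuity correction unless explicitly requested);
NPV is never reported inside the tumor border, where near-zero prevalence of
healthy tissue makes its denominator meaningless; the control group is
excluded from accuracy reporting because (a single anomaly aside) every
control biopsy is called red-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import stats

from .types import BiopsyRecord, LoadError, ParameterError

DEFAULT_LEVEL = 0.95


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (matches how the trial printed percents)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


@dataclass
class ContingencyTable:
    """TP/FP/FN/TN counts for one stratum of one dose group."""

    TP: int
    FP: int
    FN: int
    TN: int
    stratum: str = "overall"  # inside | outside | overall
    dose_group: str = "high"

    def validate(self) -> "ContingencyTable":
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ParameterError("contingency counts must be non-negative")
        return self

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        stratum = self.stratum if self.stratum == other.stratum else "overall"
        return ContingencyTable(self.TP + other.TP, self.FP + other.FP,
                                self.FN + other.FN, self.TN + other.TN,
                                stratum, self.dose_group)


@dataclass
class ProportionCI:
    """Binomial proportion with an exact Clopper-Pearson interval."""

    estimate: Optional[float]
    lower: float
    upper: float
    x: int
    n: int
    level: float = DEFAULT_LEVEL
    flag: Optional[str] = None  # reason when the estimate is not applicable

    @property
    def defined(self) -> bool:
        return self.estimate is not None

    def as_percent(self) -> dict:
        return {
            "estimate_pct": None if self.estimate is None else round_half_away(100 * self.estimate),
            "ci_pct": [round_half_away(100 * self.lower), round_half_away(100 * self.upper)],
            "x": self.x,
            "n": self.n,
            "flag": self.flag,
        }


def clopper_pearson(x: int, n: int, level: float = DEFAULT_LEVEL) -> ProportionCI:
    """Exact (Pearson-Clopper) binomial confidence interval.

    lower = BetaQuantile(alpha/2; x, n-x+1), 0 when x = 0;
    upper = BetaQuantile(1-alpha/2; x+1, n-x), 1 when x = n.
    n = 0 yields an undefined estimate with (0, 1) bounds and a flag.
    """
    if not 0 < level < 1:
        raise ParameterError("confidence level must lie in (0, 1)")
    if n < 0 or x < 0 or x > n:
        raise ParameterError("need 0 <= x <= n")
    if n == 0:
        return ProportionCI(None, 0.0, 1.0, 0, 0, level, flag="zero denominator")
    alpha = 1 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ProportionCI(x / n, lower, upper, x, n, level)


def build_contingency(records: Iterable[BiopsyRecord], stratum: str = "overall",
                      dose_group: Optional[str] = None) -> ContingencyTable:
    """Tally validated records into a 2x2 table.

    ``stratum`` selects inside/outside records ("overall" pools both).
    Records missing the fluorescence call or histology label raise a
    validation error naming the record.
    """
    tp = fp = fn = tn = 0
    for rec in records:
        if rec.red_positive is None or rec.call is None:
            raise LoadError(f"record {rec.specimen_id}/site {rec.site_id} has no fluorescence call")
        if rec.histology not in ("pos", "neg"):
            raise LoadError(f"record {rec.specimen_id}/site {rec.site_id} has no histology label")
        if stratum != "overall" and rec.stratum != stratum:
            continue
        if dose_group is not None and rec.dose_group != dose_group:
            continue
        cancer = rec.histology == "pos"
        if rec.red_positive:
            tp, fp = tp + cancer, fp + (not cancer)
        else:
            fn, tn = fn + cancer, tn + (not cancer)
    return ContingencyTable(tp, fp, fn, tn, stratum,
                            dose_group if dose_group else "high").validate()


def predictive_values(t: ContingencyTable,
                      level: float = DEFAULT_LEVEL) -> Tuple[ProportionCI, ProportionCI]:
    """PPV = TP/(TP+FP) and NPV = TN/(TN+FN), each with exact CI."""
    t.validate()
    return (clopper_pearson(t.TP, t.TP + t.FP, level),
            clopper_pearson(t.TN, t.TN + t.FN, level))


def sensitivity_specificity(t: ContingencyTable,
                            level: float = DEFAULT_LEVEL) -> Tuple[ProportionCI, ProportionCI]:
    """Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP), with exact CI."""
    t.validate()
    return (clopper_pearson(t.TP, t.TP + t.FN, level),
            clopper_pearson(t.TN, t.TN + t.FP, level))


def diagnostic_odds_ratio(t: ContingencyTable, level: float = DEFAULT_LEVEL,
                          haldane: bool = False):
    """DOR with a log-scale normal-approximation CI.

    Returns ``(dor, (lower, upper))`` or ``None`` when any cell is zero and
    the Haldane 0.5 correction was not requested.
    """
    t.validate()
    cells = [t.TP, t.FP, t.FN, t.TN]
    if min(cells) == 0:
        if not haldane:
            return None
        cells = [c + 0.5 for c in cells]
    tp, fp, fn, tn = cells
    dor = (tp * tn) / (fp * fn)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    lower = math.exp(math.log(dor) - z * se)
    upper = math.exp(math.log(dor) + z * se)
    return float(dor), (float(lower), float(upper))


def reclassify_abnormal(t: ContingencyTable, n_proliferative_fp: int) -> ContingencyTable:
    """Recount proliferative false positives as true "abnormal tissue" hits.

    Moves ``n_proliferative_fp`` counts from FP to TP, modelling the view
    that detecting benign proliferative change is a desirable outcome.
    """
    t.validate()
    if not 0 <= n_proliferative_fp <= t.FP:
        raise ParameterError("n_proliferative_fp must lie in [0, FP]")
    return ContingencyTable(t.TP + n_proliferative_fp, t.FP - n_proliferative_fp,
                            t.FN, t.TN, t.stratum, t.dose_group).validate()


@dataclass
class DiagnosticSummary:
    """All accuracy measures for one (dose group, stratum) cell."""

    dose_group: str
    stratum: str
    table: ContingencyTable
    ppv: ProportionCI
    npv: ProportionCI
    sensitivity: ProportionCI
    specificity: ProportionCI
    dor: Optional[float]
    dor_ci: Optional[Tuple[float, float]]
    flags: Dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "dose_group": self.dose_group,
            "stratum": self.stratum,
            "table": {"TP": self.table.TP, "FP": self.table.FP,
                      "FN": self.table.FN, "TN": self.table.TN},
            "ppv": self.ppv.as_percent(),
            "npv": None if "npv" in self.flags else self.npv.as_percent(),
            "sensitivity": self.sensitivity.as_percent(),
            "specificity": self.specificity.as_percent(),
            "dor": None if self.dor is None else round_half_away(self.dor),
            "dor_ci": None if self.dor_ci is None else [self.dor_ci[0], self.dor_ci[1]],
            "flags": self.flags,
        }


def summarize_table(t: ContingencyTable, level: float = DEFAULT_LEVEL) -> DiagnosticSummary:
    ppv, npv = predictive_values(t, level)
    sens, spec = sensitivity_specificity(t, level)
    dor = diagnostic_odds_ratio(t, level)
    flags = {}
    if t.stratum == "inside":
        flags["npv"] = ("not reported inside the tumor border: healthy-tissue "
                        "prevalence there is near zero, so the NPV denominator is degenerate")
    if dor is None:
        flags["dor"] = "not applicable: at least one contingency cell is zero"
        return DiagnosticSummary(t.dose_group, t.stratum, t, ppv, npv, sens, spec,
                                 None, None, flags)
    return DiagnosticSummary(t.dose_group, t.stratum, t, ppv, npv, sens, spec,
                             dor[0], dor[1], flags)


def summarize_study(records: List[BiopsyRecord],
                    level: float = DEFAULT_LEVEL) -> Tuple[List[DiagnosticSummary], List[dict]]:
    """Six summaries (low/high x inside/outside/overall) plus an exclusion log.

    Control-group records are excluded from accuracy reporting (with a logged
    reason), mirroring the trial.
    """
    log = []
    n_control = sum(1 for r in records if r.dose_group == "control")
    if n_control:
        log.append({
            "reason_code": "control_excluded",
            "detail": ("diagnostic accuracy not reported for the control group: "
                       "essentially all control biopsies are red-negative"),
            "n_records": n_control,
        })
    summaries = []
    for dose in ("low", "high"):
        dose_records = [r for r in records if r.dose_group == dose]
        if not dose_records:
            continue
        strata_present = {r.stratum for r in dose_records}
        for stratum in ("inside", "outside"):
            if stratum in strata_present:
                summaries.append(summarize_table(
                    build_contingency(dose_records, stratum, dose), level))
        summaries.append(summarize_table(
            build_contingency(dose_records, "overall", dose), level))
    return summaries, log
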