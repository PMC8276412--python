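"""The trial's printed biopsy counts, as analysis inputs.

These 2x2 counts are the published stratified contingency tables of the
imaging study (15 mg/kg "low" and 30 mg/kg "high" 5-ALA dose groups, biopsy
sites inside vs outside the clinically demarcated tumor border). They are
the inputs from which every accuracy measure in the published tables is
recomputed. Of the nine outside-border false positives across both dose
groups, five showed benign proliferative change on histology; the published
"abnormal tissue" PPVs (89% low, 70% high) imply a 3/2 low/high split.
"""

from __future__ import annotations

from .diagnostics import ContingencyTable

STUDY_COUNTS = {
    ("low", "inside"): ContingencyTable(TP=8, FP=0, FN=6, TN=1, stratum="inside", dose_group="low"),
    ("low", "outside"): ContingencyTable(TP=5, FP=4, FN=1, TN=21, stratum="outside", dose_group="low"),
    ("high", "inside"): ContingencyTable(TP=10, FP=0, FN=5, TN=0, stratum="inside", dose_group="high"),
    ("high", "outside"): ContingencyTable(TP=5, FP=5, FN=2, TN=20, stratum="outside", dose_group="high"),
}

#: Proliferative false positives among the outside-border FPs, per dose group
#: (the 3/2 split implied by the published 89%/70% abnormal-tissue PPVs).
PROLIFERATIVE_FP = {"low": 3, "high": 2}


def pooled_table(dose_group: str) -> ContingencyTable:
    """Inside + outside counts pooled cellwise (the overall table)."""
    t = STUDY_COUNTS[(dose_group, "inside")] + STUDY_COUNTS[(dose_group, "outside")]
    t.stratum = "overall"
    t.dose_group = dose_group
    return t
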