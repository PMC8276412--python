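#!/usr/bin/env python
"""Reproduce the trial's diagnostic-accuracy tables from their printed counts.

The published stratified 2x2 biopsy counts are the inputs; every measure
(PPV/NPV/sensitivity/specificity with exact Clopper-Pearson 95% CIs, DOR
with log-normal CI) is recomputed, including the pooled tables and the
abnormal-tissue reclassified PPVs. Two cells of the published tables are
inconsistent with their own counts (see docs/methods.md); the count-derived
values are reported.

Writes results/trial_tables.json.
"""

import json
from pathlib import Path

from fluormargin.diagnostics import summarize_table, reclassify_abnormal, round_half_away
from fluormargin.io import _to_jsonable
from fluormargin.studydata import PROLIFERATIVE_FP, STUDY_COUNTS, pooled_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    doc = {"stratified": [], "pooled": [], "abnormal_reclassified": []}
    for (dose, stratum), table in STUDY_COUNTS.items():
        doc["stratified"].append(summarize_table(table).as_dict())
    for dose in ("low", "high"):
        doc["pooled"].append(summarize_table(pooled_table(dose)).as_dict())
        t = reclassify_abnormal(STUDY_COUNTS[(dose, "outside")], PROLIFERATIVE_FP[dose])
        doc["abnormal_reclassified"].append({
            "dose_group": dose,
            "ppv_pct": round_half_away(100 * t.TP / (t.TP + t.FP), 1),
            "n": t.TP + t.FP,
        })
    path = OUT / "trial_tables.json"
    path.write_text(json.dumps(_to_jsonable(doc), indent=2, sort_keys=True) + "\n")

    for s in doc["stratified"] + doc["pooled"]:
        print(f"{s['dose_group']:>5} {s['stratum']:>8}: "
              f"PPV {s['ppv']['estimate_pct']}% {tuple(s['ppv']['ci_pct'])}, "
              f"sens {s['sensitivity']['estimate_pct']}%, DOR {s['dor']}")
    for a in doc["abnormal_reclassified"]:
        print(f"abnormal-tissue PPV ({a['dose_group']} dose, outside): {a['ppv_pct']}%")
    print(f"-> {path}")


if __name__ == "__main__":
    main()
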