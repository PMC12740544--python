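#!/usr/bin/env python
"""Accuracy and precision tables for every estimation method.

Joins the estimated TIAs with the reference TIAs, computes RD/RMSE/MAPE
(with propagated SDs), RD>10%/RD>20% counts and the eTIA-vs-rTIA
regression per method, and the per-method CV distribution, and writes the
tables as CSV and markdown.

Outputs: results/accuracy.csv, results/accuracy_precision.csv and the
matching .md files.
"""

from pathlib import Path

import numpy as np

from dosim.io import read_tia_table, write_report
from dosim.metrics import build_accuracy_report, cv_summary

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    ref = {t.subject_id: t for t in read_tia_table(OUT / "reference_tias_eval.csv")}
    ests = read_tia_table(OUT / "estimated_tias.csv")
    by_method: dict[str, list] = {}
    for e in ests:
        by_method.setdefault(e.method, []).append(e)

    reports, summaries = {}, {}
    for method, group in sorted(by_method.items()):
        paired = [(e, ref[e.subject_id]) for e in group if e.subject_id in ref]
        if not paired:
            continue
        reports[method] = build_accuracy_report(
            method,
            np.array([e.value for e, _ in paired]),
            np.array([e.sd for e, _ in paired]),
            np.array([r.value for _, r in paired]),
            np.array([r.sd for _, r in paired]),
        )
        summaries[method] = cv_summary(method, np.array([e.cv for e in group]))
    summaries["ATP_reference"] = cv_summary(
        "ATP_reference", np.array([t.cv for t in ref.values()])
    )
    write_report(reports, OUT / "accuracy.csv", cv_summaries=summaries)
    write_report(
        reports, OUT / "accuracy.md", format="markdown", cv_summaries=summaries
    )
    ordered = sorted(reports.values(), key=lambda r: r.rmse)
    print("methods by RMSE (best first):")
    for r in ordered[:8]:
        print(
            f"  {r.method:8s} RMSE {100 * r.rmse:5.1f}% ({100 * r.rmse_sd:.1f})  "
            f"MAPE {r.mape:5.1f}% ({r.mape_sd:.1f})  RD10 {r.rd10_count}  "
            f"RD20 {r.rd20_count}"
        )
    print("worst (no-imaging surrogates):")
    for r in ordered[-2:]:
        print(f"  {r.method:8s} RMSE {100 * r.rmse:5.1f}%  MAPE {r.mape:5.1f}%")


if __name__ == "__main__":
    main()
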