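#!/usr/bin/env python
"""Association and discrimination analysis of the scored cohort.

Computes the baseline and follow-up Kendall-tau tables (screening score
and physiologic measures against disability, pain and fear of movement),
ROC/AUC with 95 % CIs at the 6- and 12-month follow-ups, and the SBST
cutoff sweep with likelihood ratios.  Writes the report tables under
results/ and prints the headline cells.
"""

from pathlib import Path

from prognostrack.clinical import score_cohort
from prognostrack.io import read_cohort_csv
from prognostrack.pipeline import (
    baseline_comparison_table,
    correlation_tables,
    cutoff_table,
    roc_table,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUTCOMES = ("disability", "pain", "fear", "nochange")


def main() -> None:
    scored = score_cohort(read_cohort_csv(OUT / "cohort.csv"))
    base, fu = correlation_tables(scored)
    roc = roc_table(scored, OUTCOMES, ("t3", "t4"))
    cuts = cutoff_table(scored, OUTCOMES, ("t3", "t4"))
    comp = baseline_comparison_table(scored)
    base.to_csv(OUT / "baseline_correlations.csv", index=False)
    fu.to_csv(OUT / "followup_correlations.csv", index=False)
    roc.to_csv(OUT / "roc_results.csv", index=False)
    cuts.to_csv(OUT / "cutoff_performance.csv", index=False)
    comp.to_csv(OUT / "baseline_comparison.csv", index=False)

    sb = base[base.variable == "sbst_total"]
    print("baseline tau, SBST vs outcomes:")
    for _, r in sb.iterrows():
        print(f"  {r.outcome:<11} tau={r.tau:+.2f}{r.sig} (n={r.n}, {r.category})")
    print("SBST AUC at follow-ups:")
    sroc = roc[roc.predictor == "sbst_total"]
    for _, r in sroc.iterrows():
        print(
            f"  {r.outcome:<11} {r.timepoint}: AUC {r.auc:.2f} "
            f"[{r.ci_lo:.2f}, {r.ci_hi:.2f}]{r.sig} ({r.strength})"
        )
    at4 = cuts[(cuts.outcome == "disability") & (cuts.timepoint == "t4") & (cuts.cutoff == 4.0)]
    if len(at4):
        r = at4.iloc[0]
        print(
            f"SBST cutoff >=4 vs disability at t4: sens {100 * r.sensitivity:.1f} %, "
            f"spec {100 * r.specificity:.1f} %, LR+ {r.lr_pos:.2f}, LR- {r.lr_neg:.2f} "
            f"({r.interpretation})"
        )
    print(f"-> tables under {OUT}/")


if __name__ == "__main__":
    main()
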