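#!/usr/bin/env python
"""Score the cohort: SBST risk groups, lateral aggregates, outcome flags.

Reads results/cohort.csv (from 01_simulate_cohort.py), scores the 9-item
questionnaire, averages the lateral force tests, applies the dichotomy
thresholds (ODI >= 24 %, NRS >= 37, TSK >= 41, PGIC 1-2) at the 6- and
12-month follow-ups, and writes results/scored_cohort.csv.
"""

from pathlib import Path

from prognostrack.clinical import score_cohort
from prognostrack.io import read_cohort_csv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scored = score_cohort(read_cohort_csv(OUT / "cohort.csv"))
    scored.to_csv(OUT / "scored_cohort.csv", index=False)
    counts = scored["sbst_group"].value_counts()
    print(
        "risk groups low:medium:high = "
        f"{counts.get('low', 0)}:{counts.get('medium', 0)}:{counts.get('high', 0)}"
    )
    for t in ("t3", "t4"):
        n_dis = int(scored[f"disab_{t}"].sum())
        n_pain = int(scored[f"pain_{t}"].sum())
        n_fear = int(scored[f"fear_{t}"].sum())
        print(f"  {t}: disability present {n_dis}, pain {n_pain}, fear {n_fear}")
    print(f"-> {OUT / 'scored_cohort.csv'}")


if __name__ == "__main__":
    main()
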