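"""Clinical scoring: SBST risk stratification, outcome dichotomization,
and aggregation of trunk force-test results.

The STarT Back Screening Tool (SBST) is a 9-item prognostic questionnaire
for low back pain.  Items are scored 0/1; the total (0-9) stratifies risk
of persistent disabling pain, with the psychosocial subscale (items 5-9)
separating medium from high risk: total <= 3 -> low; total >= 4 with
subscale <= 3 -> medium; total >= 4 with subscale >= 4 -> high.

Follow-up outcomes are dichotomized with fixed literature thresholds:
disability present when ODI >= 24 %, pain present when NRS >= 37, fear of
movement present when TSK >= 41, and subjective status change present when
PGIC is 1 or 2 (much or very much improved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

N_SBST_ITEMS = 9
PSYCH_ITEMS = (5, 6, 7, 8, 9)  # 1-based item numbers of the psychosocial subscale

ODI_THRESHOLD = 24.0
NRS_THRESHOLD = 37.0
TSK_THRESHOLD = 41.0
PGIC_IMPROVED = (1, 2)

INSTRUMENT_RANGES = {
    "ODI": (0.0, 100.0),
    "NRS": (0.0, 100.0),
    "TSK": (17.0, 68.0),
    "PGIC": (1, 7),
}


@dataclass(frozen=True)
class SBSTResult:
    items: tuple[int, ...]
    total: int
    psych_subscale: int
    risk_group: str  # low | medium | high
    valid: bool = True


@dataclass(frozen=True)
class DichotomyRule:
    """Threshold rule turning an instrument score into present/absent."""

    outcome: str
    threshold: float
    direction: str  # 'ge' (score >= threshold) or 'in' (score in improved set)
    positive_meaning: str


RULES = {
    "ODI": DichotomyRule("ODI", ODI_THRESHOLD, "ge", "disability present"),
    "NRS": DichotomyRule("NRS", NRS_THRESHOLD, "ge", "pain present"),
    "TSK": DichotomyRule("TSK", TSK_THRESHOLD, "ge", "fear of movement present"),
    "PGIC": DichotomyRule("PGIC", 2, "in", "subjective status change present"),
}


def score_sbst(items) -> SBSTResult:
    """Score a 9-item SBST response vector.

    Each item must be 0 or 1 (the bothersomeness item is assumed already
    mapped to binary per the tool's standard rule).  A missing or invalid
    item makes the whole score invalid — no imputation.
    """
    items = tuple(items)
    if len(items) != N_SBST_ITEMS:
        raise ValueError(f"SBST requires exactly {N_SBST_ITEMS} items, got {len(items)}")
    clean: list[int] = []
    for k, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return SBSTResult(items, -1, -1, "invalid", valid=False)
        iv = int(v)
        if iv != v or iv not in (0, 1):
            raise ValueError(f"SBST item {k} must be 0 or 1, got {v!r}")
        clean.append(iv)
    total = sum(clean)
    psych = sum(clean[i - 1] for i in PSYCH_ITEMS)
    if total <= 3:
        group = "low"
    elif psych <= 3:
        group = "medium"
    else:
        group = "high"
    return SBSTResult(tuple(clean), total, psych, group)


def dichotomize(value: float, rule: DichotomyRule) -> bool:
    """Apply an outcome dichotomization rule; True means 'present'."""
    lo, hi = INSTRUMENT_RANGES[rule.outcome]
    if not (lo <= value <= hi):
        raise ValueError(
            f"{rule.outcome} value {value} outside instrument range [{lo}, {hi}]"
        )
    if rule.direction == "ge":
        return value >= rule.threshold
    if rule.direction == "in":
        return int(value) in PGIC_IMPROVED
    raise ValueError(f"unknown rule direction {rule.direction!r}")


def aggregate_lateral(right: float | None, left: float | None) -> float:
    """Average of the right- and left-side lateral task values.

    Both sides must be present; otherwise the aggregate is missing (NaN).
    """
    if right is None or left is None or math.isnan(right) or math.isnan(left):
        return math.nan
    return 0.5 * (right + left)


def score_cohort(df):
    """Score a cohort table in place of its raw columns.

    Adds sbst_total / sbst_psych / sbst_group, the lateral aggregates
    (mvc_lat, end_lat_s), and the dichotomous outcome flags at T3/T4:
    disab_* (ODI >= 24), pain_* (NRS >= 37), fear_* (TSK >= 41) and
    nochange_* (PGIC >= 3, i.e. absence of subjective status change — the
    positive class the discrimination analysis targets for PGIC).
    Missing outcome scores yield missing flags.
    """
    import numpy as np
    import pandas as pd

    df = df.copy()
    item_cols = [f"sbst_item_{i}" for i in range(1, N_SBST_ITEMS + 1)]
    totals, psychs, groups = [], [], []
    for _, row in df[item_cols].iterrows():
        res = score_sbst(row.tolist())
        totals.append(res.total if res.valid else np.nan)
        psychs.append(res.psych_subscale if res.valid else np.nan)
        groups.append(res.risk_group)
    df["sbst_total"] = totals
    df["sbst_psych"] = psychs
    df["sbst_group"] = groups
    df["mvc_lat"] = [
        aggregate_lateral(r, l) for r, l in zip(df["mvc_lat_r"], df["mvc_lat_l"])
    ]
    df["end_lat_s"] = [
        aggregate_lateral(r, l) for r, l in zip(df["end_lat_r_s"], df["end_lat_l_s"])
    ]

    def _flag(col: str, rule: DichotomyRule) -> pd.Series:
        def one(v):
            if pd.isna(v):
                return np.nan
            return float(dichotomize(v, rule))

        return df[col].map(one)

    for t in ("t3", "t4"):
        df[f"disab_{t}"] = _flag(f"odi_{t}", RULES["ODI"])
        df[f"pain_{t}"] = _flag(f"nrs_{t}", RULES["NRS"])
        df[f"fear_{t}"] = _flag(f"tsk_{t}", RULES["TSK"])
        # positive class = absence of subjective status change (PGIC >= 3)
        df[f"nochange_{t}"] = _flag(f"pgic_{t}", RULES["PGIC"]).map(
            lambda v: np.nan if pd.isna(v) else 1.0 - v
        )
    return df


def select_mvc(trial_forces) -> tuple[float, str]:
    """MVC from a sequence of 1-3 trial forces, with completion status.

    The protocol shows a target 10 % above the previous trial from trial 2
    on; the sequence ends when a trial fails to reach 1.1x the previous
    force ('threshold'), or after three trials ('three-trials').  The MVC
    is the maximum recorded force.
    """
    trials = [float(f) for f in trial_forces]
    if not trials:
        raise ValueError("select_mvc requires at least one trial")
    if len(trials) > 3:
        raise ValueError("at most three MVC trials are allowed")
    if any(f <= 0 for f in trials):
        raise ValueError("trial forces must be positive")
    # only the final transition may miss the threshold — an earlier miss
    # would have ended the sequence
    for prev, cur in zip(trials[:-2], trials[1:-1]):
        if cur < 1.1 * prev:
            raise ValueError(
                "inconsistent trial sequence: a non-final trial missed the "
                "10 % threshold but the sequence continued"
            )
    if len(trials) >= 2 and trials[-1] < 1.1 * trials[-2]:
        status = "threshold"
    elif len(trials) == 3:
        status = "three-trials"
    else:
        status = "incomplete"
    return max(trials), status
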