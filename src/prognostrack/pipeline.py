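"""End-to-end orchestration: simulate -> features -> score -> associate.

One :func:`run_pipeline` call generates (or loads) a cohort, optionally
replaces the EMG summary variables of a subset of participants with values
measured by the feature-extraction chain on synthetic grid recordings
whose ground truth is that participant's own cohort value, scores the
questionnaire and force tests, and produces the report bundle: baseline
and follow-up rank-correlation tables, ROC/AUC per outcome and timepoint,
cutoff sweeps for the screening tool, baseline group comparisons, and a
provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import score_cohort
from .emg_features import summarize_recording
from .geometry import GridGeometry
from .stats import (
    CorrelationResult,
    cutoff_sweep,
    kendall_tau,
    roc_auc,
    welch_t_test,
)
from .synthetic.cohort import CohortConfig, default_cohort_config, generate_cohort
from .synthetic.emg import EMGSimParams, generate_emg_recording

PHYSIO_VARS = [
    "end_prone_s",
    "end_lat_s",
    "mvc_prone",
    "mvc_lat",
    "motor_variability",
    "nmf_slope",
]
PREDICTORS = PHYSIO_VARS + ["sbst_total"]
OUTCOME_COLS = {"disability": "odi", "pain": "nrs", "fear": "tsk"}
DICHOTOMIES = {
    "disability": "disab",
    "pain": "pain",
    "fear": "fear",
    "nochange": "nochange",
}
FOLLOWUPS = ("t1", "t2", "t3", "t4")


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    seed: int = 0
    cohort: CohortConfig | None = None
    n_emg_participants: int = 4
    emg_duration_s: float = 20.0
    emg_fs: float = 2048.0
    out_dir: str | Path | None = None
    outcomes: tuple[str, ...] = ("disability", "pain", "fear", "nochange")
    roc_timepoints: tuple[str, ...] = ("t3", "t4")
    ci_method: str = "hanley-mcneil"
    make_plots: bool = False

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return default_cohort_config(seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a JSON or YAML file.

        The cohort block accepts ``kind`` ('default' or 'contrast') plus
        the keyword arguments of the corresponding config builder.
        """
        import yaml

        from .synthetic.cohort import contrast_cohort_config

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_spec = raw.pop("cohort", None)
        cohort = None
        if cohort_spec:
            kind = cohort_spec.pop("kind", "default")
            builder = {
                "default": default_cohort_config,
                "contrast": contrast_cohort_config,
            }[kind]
            cohort = builder(**cohort_spec)
        known = {f.name for f in dataclass_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        for key in ("outcomes", "roc_timepoints"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)


@dataclass
class ReportBundle:
    cohort: pd.DataFrame
    scored: pd.DataFrame
    baseline_correlations: pd.DataFrame
    followup_correlations: pd.DataFrame
    roc: pd.DataFrame
    cutoffs: pd.DataFrame
    baseline_comparison: pd.DataFrame
    provenance: dict


def _sig_flag(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _corr_row(df: pd.DataFrame, var: str, outcome_col: str) -> dict:
    try:
        res: CorrelationResult = kendall_tau(df[var], df[outcome_col])
        return {
            "tau": res.tau,
            "p": res.p_value,
            "n": res.n_pairs,
            "r_equiv": res.r_equiv,
            "category": res.category,
            "sig": _sig_flag(res.p_value),
        }
    except ValueError:
        return {"tau": np.nan, "p": np.nan, "n": 0, "r_equiv": np.nan, "category": "", "sig": ""}


def correlation_tables(scored: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline and follow-up Kendall-tau tables (variables x outcomes)."""
    base_rows = []
    for var in PREDICTORS:
        for outcome, col in OUTCOME_COLS.items():
            r = _corr_row(scored, var, f"{col}_t0")
            base_rows.append({"variable": var, "outcome": outcome, **r})
    fu_rows = []
    for var in PREDICTORS:
        for outcome, col in OUTCOME_COLS.items():
            for t in FOLLOWUPS:
                r = _corr_row(scored, var, f"{col}_{t}")
                fu_rows.append(
                    {"variable": var, "outcome": outcome, "timepoint": t, **r}
                )
    return pd.DataFrame(base_rows), pd.DataFrame(fu_rows)


def roc_table(
    scored: pd.DataFrame,
    outcomes: tuple[str, ...],
    timepoints: tuple[str, ...],
    ci_method: str = "hanley-mcneil",
) -> pd.DataFrame:
    """AUC with CI, p and strength for every predictor x outcome x timepoint."""
    rows = []
    for var in PREDICTORS:
        for outcome in outcomes:
            flag = DICHOTOMIES[outcome]
            for t in timepoints:
                col = f"{flag}_{t}"
                sub = scored[[var, col]].dropna()
                try:
                    res = roc_auc(sub[var], sub[col], positive_class=outcome, ci_method=ci_method)
                    rows.append(
                        {
                            "predictor": var,
                            "outcome": outcome,
                            "timepoint": t,
                            "auc": res.auc,
                            "ci_lo": res.ci95[0],
                            "ci_hi": res.ci95[1],
                            "p": res.p_value,
                            "strength": res.strength,
                            "n_pos": res.n_pos,
                            "n_neg": res.n_neg,
                            "n": res.n_pos + res.n_neg,
                            "sig": _sig_flag(res.p_value),
                        }
                    )
                except ValueError:
                    rows.append(
                        {
                            "predictor": var,
                            "outcome": outcome,
                            "timepoint": t,
                            "auc": np.nan,
                            "ci_lo": np.nan,
                            "ci_hi": np.nan,
                            "p": np.nan,
                            "strength": "",
                            "n_pos": 0,
                            "n_neg": 0,
                            "n": 0,
                            "sig": "",
                        }
                    )
    return pd.DataFrame(rows)


def cutoff_table(
    scored: pd.DataFrame, outcomes: tuple[str, ...], timepoints: tuple[str, ...]
) -> pd.DataFrame:
    """Sensitivity/specificity/LR sweep of the SBST total per outcome."""
    rows = []
    for outcome in outcomes:
        flag = DICHOTOMIES[outcome]
        for t in timepoints:
            col = f"{flag}_{t}"
            sub = scored[["sbst_total", col]].dropna()
            if sub[col].nunique() < 2:
                continue
            for perf in cutoff_sweep(sub["sbst_total"], sub[col]):
                rows.append(
                    {
                        "outcome": outcome,
                        "timepoint": t,
                        "cutoff": perf.cutoff,
                        "sensitivity": perf.sensitivity,
                        "specificity": perf.specificity,
                        "lr_pos": perf.lr_pos,
                        "lr_neg": perf.lr_neg,
                        "interpretation": perf.interpretation,
                        "n": len(sub),
                    }
                )
    return pd.DataFrame(rows)


def baseline_comparison_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Welch t-tests of baseline characteristics: M vs F, completers vs lost."""
    variables = [
        "age",
        "bmi",
        "odi_t0",
        "nrs_t0",
        "tsk_t0",
        "sbst_total",
        "end_prone_s",
        "end_lat_s",
        "mvc_prone",
        "mvc_lat",
    ]
    lost = scored[[f"dropout_{t}" for t in FOLLOWUPS]].any(axis=1)
    rows = []
    for var in variables:
        if var not in scored.columns:
            continue
        for label, mask in (
            ("male_vs_female", scored["sex"] == "M"),
            ("completer_vs_lost", ~lost),
        ):
            a = scored.loc[mask, var]
            b = scored.loc[~mask, var]
            try:
                t_stat, p = welch_t_test(a, b)
            except ValueError:
                t_stat, p = np.nan, np.nan
            rows.append(
                {
                    "variable": var,
                    "comparison": label,
                    "t": t_stat,
                    "p": p,
                    "n_a": int(a.notna().sum()),
                    "n_b": int(b.notna().sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EMG measurement stage


def measure_emg_features(
    cohort: pd.DataFrame,
    n_participants: int,
    duration_s: float,
    fs: float,
    seed: int,
) -> pd.DataFrame:
    """Replace copula EMG summaries with chain-measured values for a subset.

    For each selected participant, grid recordings are synthesized whose
    programmed CoG drift per window and MF decline equal that
    participant's cohort values of motor variability and NMFslope; the
    feature chain then measures them back.  This keeps the analysed
    columns on the measured scale while exercising the full chain inside
    the pipeline.
    """
    cohort = cohort.copy()
    grid = GridGeometry()
    k = min(n_participants, len(cohort))
    for idx in range(k):
        row = cohort.iloc[idx]
        drift_per_window = float(row["motor_variability"])
        nmf = float(row["nmf_slope"])
        mf_start = 100.0
        sides = {}
        for s, side in enumerate(("left", "right")):
            p_seed = int((seed + 7919 * (idx + 1) + s) % (2**31))
            margin = 2.5
            usable = grid.row_extent_cm - 2 * margin
            v_row = min(drift_per_window, usable / (duration_s / 0.5)) / 0.5
            endur = generate_emg_recording(
                EMGSimParams(
                    duration_s=duration_s,
                    fs=fs,
                    grid=grid,
                    true_mf_start=mf_start,
                    true_mf_slope=nmf * mf_start / 100.0,
                    true_cog_start=(margin, grid.col_extent_cm / 2.0),
                    true_cog_velocity=(v_row, 0.0),
                    side=side,
                    task="endurance",
                    seed=p_seed,
                )
            )
            mvc = generate_emg_recording(
                EMGSimParams(
                    duration_s=5.0,
                    fs=fs,
                    grid=grid,
                    true_mf_start=mf_start,
                    true_mf_slope=0.0,
                    true_cog_start=(grid.row_extent_cm / 2.0, grid.col_extent_cm / 2.0),
                    side=side,
                    task="mvc",
                    seed=p_seed + 1,
                )
            )
            sides[side] = (endur, mvc)
        summary = summarize_recording(
            sides["left"][0], sides["right"][0], sides["left"][1], sides["right"][1]
        )
        cohort.iloc[idx, cohort.columns.get_loc("motor_variability")] = (
            summary.motor_variability
        )
        cohort.iloc[idx, cohort.columns.get_loc("nmf_slope")] = summary.nmf_slope
    return cohort


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Simulate, measure, score and associate; deterministic per seed."""
    cohort_config = config.resolved_cohort()
    cohort = generate_cohort(cohort_config)
    if config.n_emg_participants > 0:
        cohort = measure_emg_features(
            cohort,
            config.n_emg_participants,
            config.emg_duration_s,
            config.emg_fs,
            config.seed,
        )
    scored = score_cohort(cohort)
    base, fu = correlation_tables(scored)
    roc = roc_table(scored, config.outcomes, config.roc_timepoints, config.ci_method)
    cuts = cutoff_table(scored, config.outcomes, config.roc_timepoints)
    baseline = baseline_comparison_table(scored)
    provenance = {
        "seed": config.seed,
        "package_version": __version__,
        "n_participants": cohort_config.n_participants,
        "n_emg_participants": int(min(config.n_emg_participants, len(cohort))),
        "dropout_rate_per_followup": cohort_config.dropout_rate_per_followup,
        "config_hash": _config_hash(config, cohort_config),
        "n_lost_any_followup": int(
            scored[[f"dropout_{t}" for t in FOLLOWUPS]].any(axis=1).sum()
        ),
    }
    bundle = ReportBundle(
        cohort=cohort,
        scored=scored,
        baseline_correlations=base,
        followup_correlations=fu,
        roc=roc,
        cutoffs=cuts,
        baseline_comparison=baseline,
        provenance=provenance,
    )
    if config.out_dir is not None:
        write_report(bundle, config.out_dir)
        if config.make_plots:
            from .plots import plot_cutoff_sweep, plot_roc_curves

            out = Path(config.out_dir)
            plot_roc_curves(scored, roc, out / "roc_curves.png")
            if len(cuts):
                plot_cutoff_sweep(cuts, out / "cutoff_sweep.png")
    return bundle


def _config_hash(config: RunConfig, cohort_config: CohortConfig) -> str:
    blob = json.dumps(
        {
            "seed": config.seed,
            "n_participants": cohort_config.n_participants,
            "variables": cohort_config.variables,
            "latent_assoc": np.asarray(cohort_config.latent_assoc).round(12).tolist(),
            "dropout": cohort_config.dropout_rate_per_followup,
            "n_emg_participants": config.n_emg_participants,
            "emg_duration_s": config.emg_duration_s,
            "outcomes": list(config.outcomes),
            "roc_timepoints": list(config.roc_timepoints),
            "ci_method": config.ci_method,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write the report bundle as CSVs plus a provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.scored.to_csv(out / "scored_cohort.csv", index=False)
    bundle.baseline_correlations.to_csv(out / "baseline_correlations.csv", index=False)
    bundle.followup_correlations.to_csv(out / "followup_correlations.csv", index=False)
    bundle.roc.to_csv(out / "roc_results.csv", index=False)
    bundle.cutoffs.to_csv(out / "cutoff_performance.csv", index=False)
    bundle.baseline_comparison.to_csv(out / "baseline_comparison.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=2, sort_keys=True))
    return out
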