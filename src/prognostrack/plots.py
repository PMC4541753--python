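"""Rendered figures for a report bundle.

Plots are conveniences; the CSV tables are the tested surface.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import roc_curve_points


def plot_roc_curves(
    scored: pd.DataFrame,
    roc: pd.DataFrame,
    out_path: str | Path,
    predictor: str = "sbst_total",
    outcomes: tuple[str, ...] = ("disability", "pain", "fear"),
) -> Path:
    """ROC curves for one predictor at the 6- and 12-month follow-ups."""
    from .pipeline import DICHOTOMIES

    fig, axes = plt.subplots(1, len(outcomes), figsize=(4 * len(outcomes), 4))
    styles = {"t3": "-", "t4": "--"}
    for ax, outcome in zip(axes, outcomes):
        for t, ls in styles.items():
            col = f"{DICHOTOMIES[outcome]}_{t}"
            sub = scored[[predictor, col]].dropna()
            if sub[col].nunique() < 2:
                continue
            pts = roc_curve_points(sub[predictor], sub[col])
            row = roc[
                (roc.predictor == predictor)
                & (roc.outcome == outcome)
                & (roc.timepoint == t)
            ]
            auc = row.auc.iloc[0] if len(row) else float("nan")
            order = pts[:, 2].argsort()
            ax.plot(pts[order, 2], pts[order, 1], ls, label=f"{t} (AUC {auc:.2f})")
        ax.plot([0, 1], [0, 1], color="0.8", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(outcome)
        ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_cutoff_sweep(cutoffs: pd.DataFrame, out_path: str | Path) -> Path:
    """Sensitivity and specificity against the screening-score cutoff."""
    combos = cutoffs[["outcome", "timepoint"]].drop_duplicates()
    n = len(combos)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(3.5 * max(n, 1), 3.5))
    if n <= 1:
        axes = [axes]
    for ax, (_, combo) in zip(axes, combos.iterrows()):
        sub = cutoffs[
            (cutoffs.outcome == combo.outcome) & (cutoffs.timepoint == combo.timepoint)
        ].sort_values("cutoff")
        ax.plot(sub.cutoff, sub.sensitivity, "o-", ms=3, label="sensitivity")
        ax.plot(sub.cutoff, sub.specificity, "s--", ms=3, label="specificity")
        ax.set_xlabel("cutoff (score >= c positive)")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(f"{combo.outcome} {combo.timepoint}", fontsize=9)
        ax.legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
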