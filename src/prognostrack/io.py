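"""Reading and writing the cohort CSV and the grid-EMG container.

Cohort tables travel as plain CSV with a JSON column dictionary sidecar.
EMG recordings travel as a delimited numeric matrix (channels x samples)
plus a JSON sidecar holding sampling and grid metadata and, for synthetic
recordings, the ground-truth block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg_features import EMGRecording
from .geometry import GridGeometry

REQUIRED_COHORT_COLUMNS = (
    ["participant_id", "sex"]
    + [f"sbst_item_{i}" for i in range(1, 10)]
    + [f"{v}_{t}" for v in ("odi", "nrs", "tsk") for t in ("t0", "t1", "t2", "t3", "t4")]
    + ["pgic_t3", "pgic_t4"]
    + ["mvc_prone", "mvc_lat_r", "mvc_lat_l", "end_prone_s", "end_lat_r_s", "end_lat_l_s"]
    + ["motor_variability", "nmf_slope"]
)

COLUMN_DICTIONARY = {
    "participant_id": "participant identifier",
    "sex": "M/F",
    "age": "years",
    "bmi": "kg/m^2",
    "sbst_item_i": "SBST item response, 0/1 (items 5-9 = psychosocial subscale)",
    "odi_t*": "Oswestry Disability Index, 0-100 %",
    "nrs_t*": "numerical pain rating, 0-100",
    "tsk_t*": "Tampa Scale for Kinesiophobia, 17-68",
    "pgic_t*": "patient global impression of change, 1-7 (1-2 = improved)",
    "mvc_*": "maximal voluntary contraction force, N",
    "end_*_s": "endurance time, s",
    "motor_variability": "mean CoG migration per 0.5-s window, cm",
    "nmf_slope": "normalized median-frequency slope, % s^-1",
    "dropout_t*": "True when the follow-up was missed",
}


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort table plus its JSON column-dictionary sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"columns": COLUMN_DICTIONARY}, indent=2))
    return path


def read_cohort_csv(path: str | Path, required=REQUIRED_COHORT_COLUMNS) -> pd.DataFrame:
    """Read and schema-check a cohort CSV.

    Missing required columns and non-numeric values in numeric columns are
    rejected with the offending column names and CSV line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing required column(s): {missing}")
    numeric = [c for c in required if c not in ("participant_id", "sex")]
    bad: list[str] = []
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        invalid = coerced.isna() & df[c].notna()
        if invalid.any():
            lines = (df.index[invalid] + 2).tolist()  # +2: header + 1-based
            bad.append(f"{c} (line {lines})")
        df[c] = coerced
    if bad:
        raise ValueError(f"cohort CSV {path} has non-numeric values: {bad}")
    return df


# ---------------------------------------------------------------------------
# EMG container


def write_emg_container(rec: EMGRecording, prefix: str | Path) -> tuple[Path, Path]:
    """Write an EMG recording as <prefix>.tsv + <prefix>.json sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    matrix_path = prefix.with_suffix(".tsv")
    np.savetxt(matrix_path, rec.signal, fmt="%.8e", delimiter="\t")
    sidecar = {
        "fs": rec.fs,
        "n_rows": rec.grid.n_rows,
        "n_cols": rec.grid.n_cols,
        "inter_electrode_distance_mm": rec.grid.inter_electrode_distance * 10.0,
        "side": rec.side,
        "task": rec.task,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        **{k: v for k, v in rec.meta.items() if k in ("seed", "ground_truth")},
    }
    sidecar_path = prefix.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return matrix_path, sidecar_path


def read_emg_container(prefix: str | Path) -> EMGRecording:
    """Read an EMG container, checking sidecar/matrix consistency."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    signal = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    grid = GridGeometry(
        n_rows=int(sidecar["n_rows"]),
        n_cols=int(sidecar["n_cols"]),
        inter_electrode_distance=float(sidecar["inter_electrode_distance_mm"]) / 10.0,
    )
    if signal.shape[0] != sidecar["n_channels"] or signal.shape[0] != grid.n_channels:
        raise ValueError(
            f"EMG container {prefix}: matrix has {signal.shape[0]} channels but "
            f"sidecar declares {sidecar['n_channels']} on a "
            f"{grid.n_rows}x{grid.n_cols} grid"
        )
    if signal.shape[1] != sidecar["n_samples"]:
        raise ValueError(
            f"EMG container {prefix}: matrix has {signal.shape[1]} samples but "
            f"sidecar declares {sidecar['n_samples']}"
        )
    meta = {k: sidecar[k] for k in ("seed", "ground_truth") if k in sidecar}
    return EMGRecording(
        signal=signal,
        fs=float(sidecar["fs"]),
        grid=grid,
        side=sidecar["side"],
        task=sidecar["task"],
        meta=meta,
    )
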