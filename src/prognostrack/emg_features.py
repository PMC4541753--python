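"""Surface-EMG processing chain for trunk-endurance fatigue analysis.

From a high-density grid recording of the lumbar erector spinae this module
extracts the two physiologic summary variables used in the prognostic
analysis:

* **motor variability** — the mean window-to-window migration (cm) of the
  centre of gravity (CoG) of the normalized RMS amplitude map, a measure of
  spatial redistribution of muscle activity during a sustained contraction;
* **NMFslope** — the normalized median-frequency slope (% s^-1): per channel,
  the least-squares slope of the median frequency (MF) over time divided by
  the regression intercept (initial MF), averaged over channels and sides.
  MF decline is the classical spectral manifestation of muscle fatigue.

Processing steps: band-pass 20-450 Hz (2nd-order Butterworth, zero-phase)
with notches at 60 Hz and harmonics; non-overlapping 0.5-s windows; per
window and channel an RMS value (normalized to the prone-MVC reference RMS)
and an MF value (frequency splitting the window periodogram into two equal
power areas).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .geometry import GridGeometry

logger = logging.getLogger(__name__)

BANDPASS_LOW_HZ = 20.0
BANDPASS_HIGH_HZ = 450.0
LINE_FREQ_HZ = 60.0
NOTCH_MAX_HZ = 450.0
NOTCH_Q = 30.0
WINDOW_S = 0.5
MIN_VALID_CHANNEL_FRACTION = 0.8


@dataclass
class EMGRecording:
    """One grid recording: channels x samples, in mV."""

    signal: np.ndarray
    fs: float
    grid: GridGeometry
    side: str = "right"
    task: str = "endurance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != self.grid.n_channels:
            raise ValueError(
                f"channel count {self.signal.shape[0]} does not match grid "
                f"({self.grid.n_rows}x{self.grid.n_cols}={self.grid.n_channels})"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.task not in ("mvc", "endurance"):
            raise ValueError("task must be 'mvc' or 'endurance'")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class RMSMapSeries:
    """Per-window, per-channel RMS values (windows x channels).

    ``values`` is in mV before normalization, in % of the MVC reference
    after.  ``times`` holds window start times in seconds.  Channels
    excluded by normalization are NaN columns listed in
    ``excluded_channels``.
    """

    values: np.ndarray
    times: np.ndarray
    window_length: float
    grid: GridGeometry
    units: str = "mV"
    excluded_channels: list[int] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class FatigueSummary:
    """Side-averaged physiologic summary of an endurance test.

    motor_variability : mean CoG migration per 0.5-s window, cm.
    nmf_slope : global NMFslope, % s^-1.
    per_side : per-side intermediates for audit (mean migration, mean
        NMFslope, per-channel MF slopes and intercepts).
    """

    motor_variability: float
    nmf_slope: float
    per_side: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Filtering


def preprocess(recording: EMGRecording) -> EMGRecording:
    """Band-pass 20-450 Hz and notch out 60 Hz and its harmonics.

    Filters are applied zero-phase (forward-backward), which doubles the
    effective order and leaves window alignment free of group delay.
    Requires fs > 900 Hz so the 450-Hz band edge stays below Nyquist.
    """
    if recording.fs <= 2 * BANDPASS_HIGH_HZ:
        raise ValueError(
            f"sampling rate {recording.fs} Hz too low: band-pass upper edge "
            f"{BANDPASS_HIGH_HZ} Hz must lie below Nyquist"
        )
    nyq = recording.fs / 2.0
    sos = sps.butter(
        2, [BANDPASS_LOW_HZ / nyq, BANDPASS_HIGH_HZ / nyq], btype="bandpass", output="sos"
    )
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    f0 = LINE_FREQ_HZ
    while f0 <= min(NOTCH_MAX_HZ, nyq * 0.99):
        b, a = sps.iirnotch(f0 / nyq, NOTCH_Q)
        filtered = sps.filtfilt(b, a, filtered, axis=1)
        f0 += LINE_FREQ_HZ
    return EMGRecording(
        signal=filtered,
        fs=recording.fs,
        grid=recording.grid,
        side=recording.side,
        task=recording.task,
        meta=dict(recording.meta, preprocessed=True),
    )


def single_differential(recording: EMGRecording) -> EMGRecording:
    """Software single-differential derivation along columns (cranio-caudal).

    Subtracts each channel from its caudal neighbour within the same
    column, reducing an R x C grid to (R-1) x C.  Use when the recorded
    channels are monopolar; the default assumption is hardware-bipolar
    input, for which this step is skipped.
    """
    g = recording.grid
    mat = recording.signal.reshape(g.n_rows, g.n_cols, -1)
    diff = mat[1:] - mat[:-1]
    new_grid = GridGeometry(g.n_rows - 1, g.n_cols, g.inter_electrode_distance)
    return EMGRecording(
        signal=diff.reshape(new_grid.n_channels, -1),
        fs=recording.fs,
        grid=new_grid,
        side=recording.side,
        task=recording.task,
        meta=dict(recording.meta, derivation="single-differential"),
    )


# ---------------------------------------------------------------------------
# Amplitude maps


def window_rms(recording: EMGRecording, window: float = WINDOW_S) -> RMSMapSeries:
    """Per-channel RMS over consecutive non-overlapping windows.

    Window k covers samples [k*window*fs, (k+1)*window*fs); a trailing
    partial window is discarded.
    """
    nper = int(round(window * recording.fs))
    if recording.n_samples < nper or nper < 1:
        raise ValueError("signal shorter than one window")
    n_win = recording.n_samples // nper
    x = recording.signal[:, : n_win * nper]
    x = x.reshape(recording.n_channels, n_win, nper)
    rms = np.sqrt(np.mean(x**2, axis=2)).T  # windows x channels
    times = np.arange(n_win) * window
    return RMSMapSeries(
        values=rms, times=times, window_length=window, grid=recording.grid, units="mV"
    )


def mvc_reference_rms(
    mvc_recording: EMGRecording, central_seconds: float = 3.0
) -> np.ndarray:
    """Per-channel reference RMS from the central segment of an MVC trial.

    The reference segment is the ``central_seconds`` window centred in the
    recording (the whole recording if shorter).
    """
    n = mvc_recording.n_samples
    seg = int(round(central_seconds * mvc_recording.fs))
    if seg >= n:
        sl = slice(0, n)
    else:
        start = (n - seg) // 2
        sl = slice(start, start + seg)
    return np.sqrt(np.mean(mvc_recording.signal[:, sl] ** 2, axis=1))


def normalize_rms(
    endurance_rms: RMSMapSeries, mvc_reference: np.ndarray, rel_tol: float = 1e-9
) -> RMSMapSeries:
    """Express RMS maps as % of the per-channel MVC reference RMS.

    Channels whose reference is zero or negligible (relative to the largest
    reference) are excluded: their columns become NaN and their indices are
    recorded in ``excluded_channels``.
    """
    ref = np.asarray(mvc_reference, dtype=float)
    if ref.shape != (endurance_rms.values.shape[1],):
        raise ValueError("reference length must equal channel count")
    floor = rel_tol * max(ref.max(initial=0.0), 1.0)
    bad = np.flatnonzero(~(ref > floor))
    values = 100.0 * endurance_rms.values / np.where(ref > floor, ref, np.nan)
    if bad.size:
        logger.warning(
            "normalize_rms: excluded %d channel(s) with ~zero MVC reference: %s",
            bad.size,
            bad.tolist(),
        )
    return RMSMapSeries(
        values=values,
        times=endurance_rms.times,
        window_length=endurance_rms.window_length,
        grid=endurance_rms.grid,
        units="%MVC",
        excluded_channels=sorted(set(endurance_rms.excluded_channels) | set(bad.tolist())),
    )


# ---------------------------------------------------------------------------
# Centre of gravity and migration


def center_of_gravity(rms_map: np.ndarray, grid: GridGeometry) -> tuple[float, float]:
    """Amplitude-weighted mean electrode position, in cm.

    ``rms_map`` is one window's map, flat (n_channels,) or (n_rows, n_cols).
    NaN channels are ignored when at least ``MIN_VALID_CHANNEL_FRACTION`` of
    channels are valid; otherwise, or for an all-zero map, the window is
    undefined and (nan, nan) is returned.
    """
    w = np.asarray(rms_map, dtype=float).ravel()
    if w.size != grid.n_channels:
        raise ValueError("map size does not match grid")
    valid = np.isfinite(w)
    if valid.mean() < MIN_VALID_CHANNEL_FRACTION:
        return (np.nan, np.nan)
    w = np.where(valid, w, 0.0)
    if np.any(w < 0):
        raise ValueError("RMS map must be nonnegative")
    total = w.sum()
    if total <= 0:
        return (np.nan, np.nan)
    coords = grid.channel_coordinates()
    cog = (w[:, None] * coords).sum(axis=0) / total
    return (float(cog[0]), float(cog[1]))


def cog_series(maps: RMSMapSeries) -> np.ndarray:
    """(n_windows, 2) CoG trajectory; undefined windows are NaN rows."""
    return np.array([center_of_gravity(row, maps.grid) for row in maps.values])


def motor_variability_side(cogs: np.ndarray) -> float:
    """Mean Euclidean CoG displacement between consecutive valid windows, cm.

    Steps are taken only between adjacent windows that are both defined.
    Requires at least two valid windows.
    """
    cogs = np.asarray(cogs, dtype=float)
    valid = np.all(np.isfinite(cogs), axis=1)
    if valid.sum() < 2:
        raise ValueError("motor variability needs at least two valid windows")
    pair = valid[:-1] & valid[1:]
    if not pair.any():
        raise ValueError("no consecutive pair of valid windows")
    steps = np.linalg.norm(np.diff(cogs, axis=0), axis=1)[pair]
    return float(steps.mean())


def motor_variability(cogs_left: np.ndarray, cogs_right: np.ndarray) -> float:
    """Global motor variability: mean of the two sides' mean migrations."""
    return 0.5 * (motor_variability_side(cogs_left) + motor_variability_side(cogs_right))


# ---------------------------------------------------------------------------
# Spectral fatigue index


def _mf_from_psd(freqs: np.ndarray, pxx: np.ndarray) -> np.ndarray:
    """Vectorized half-power crossing for (n_channels, n_bins) periodograms."""
    pxx = np.atleast_2d(pxx)
    total = pxx.sum(axis=1)
    cum = np.cumsum(pxx, axis=1)
    out = np.full(pxx.shape[0], np.nan)
    ok = total > 0
    half = 0.5 * total
    for i in np.flatnonzero(ok):
        k = int(np.searchsorted(cum[i], half[i]))
        if k == 0:
            out[i] = freqs[0] if freqs[0] > 0 else freqs[1] * half[i] / cum[i, 0]
            continue
        prev = cum[i, k - 1]
        frac = (half[i] - prev) / (cum[i, k] - prev) if cum[i, k] > prev else 0.0
        out[i] = freqs[k - 1] + frac * (freqs[k] - freqs[k - 1])
    return out


def median_frequency(window_signal: np.ndarray, fs: float) -> float:
    """Median frequency of one window: splits spectral power in two equal areas.

    Hann-tapered periodogram; the half-power crossing is located by linear
    interpolation of cumulative power within the crossing bin.  Returns NaN
    for a zero-variance window.
    """
    x = np.asarray(window_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("median_frequency expects a single-channel window")
    if np.allclose(x, x[0]):
        return np.nan
    freqs, pxx = sps.periodogram(x, fs=fs, window="hann", detrend="constant")
    return float(_mf_from_psd(freqs, pxx)[0])


def mf_series(recording: EMGRecording, window: float = WINDOW_S) -> tuple[np.ndarray, np.ndarray]:
    """Per-window, per-channel MF values.

    Returns (mf, times): mf is (n_windows, n_channels), times the window
    start times in seconds.
    """
    nper = int(round(window * recording.fs))
    if recording.n_samples < nper:
        raise ValueError("signal shorter than one window")
    n_win = recording.n_samples // nper
    out = np.empty((n_win, recording.n_channels))
    for k in range(n_win):
        seg = recording.signal[:, k * nper : (k + 1) * nper]
        freqs, pxx = sps.periodogram(
            seg, fs=recording.fs, window="hann", detrend="constant", axis=1
        )
        mf = _mf_from_psd(freqs, pxx)
        constant = np.ptp(seg, axis=1) == 0
        mf[constant] = np.nan
        out[k] = mf
    return out, np.arange(n_win) * window


def nmf_slope(mf: np.ndarray, times: np.ndarray) -> dict:
    """Per-channel MF regression and the side-level normalized slope.

    For each channel with >= 3 valid windows: MFslope = least-squares slope
    of MF against time (Hz s^-1), iMF = intercept at t = 0 (Hz), NMFslope =
    100 * MFslope / iMF (% s^-1).  Channels with iMF <= 0 are excluded and
    logged.  The side value is the mean of per-channel NMFslopes.
    """
    mf = np.asarray(mf, dtype=float)
    times = np.asarray(times, dtype=float)
    n_ch = mf.shape[1]
    slopes = np.full(n_ch, np.nan)
    intercepts = np.full(n_ch, np.nan)
    nmf = np.full(n_ch, np.nan)
    excluded: list[int] = []
    for c in range(n_ch):
        valid = np.isfinite(mf[:, c])
        if valid.sum() < 3:
            excluded.append(c)
            continue
        slope, intercept = np.polyfit(times[valid], mf[valid, c], 1)
        if intercept <= 0:
            excluded.append(c)
            logger.warning("nmf_slope: channel %d excluded (iMF <= 0)", c)
            continue
        slopes[c] = slope
        intercepts[c] = intercept
        nmf[c] = 100.0 * slope / intercept
    if np.all(np.isnan(nmf)):
        raise ValueError("no channel yielded a valid MF regression")
    return {
        "mf_slope_hz_per_s": slopes,
        "imf_hz": intercepts,
        "nmf_slope_pct_per_s": nmf,
        "side_nmf_slope": float(np.nanmean(nmf)),
        "excluded_channels": excluded,
    }


# ---------------------------------------------------------------------------
# Composition


def summarize_side(
    endurance: EMGRecording, mvc: EMGRecording, window: float = WINDOW_S
) -> dict:
    """Run the full chain for one side; returns per-side intermediates."""
    if endurance.fs != mvc.fs or endurance.grid != mvc.grid:
        raise ValueError("endurance and MVC recordings must share fs and grid")
    end_f = preprocess(endurance)
    mvc_f = preprocess(mvc)
    rms = window_rms(end_f, window)
    ref = mvc_reference_rms(mvc_f)
    norm = normalize_rms(rms, ref)
    cogs = cog_series(norm)
    migration = motor_variability_side(cogs)
    mf, times = mf_series(end_f, window)
    reg = nmf_slope(mf, times)
    return {
        "side": endurance.side,
        "mean_migration_cm": migration,
        "side_nmf_slope": reg["side_nmf_slope"],
        "cog_series": cogs,
        "mf_slope_hz_per_s": reg["mf_slope_hz_per_s"],
        "imf_hz": reg["imf_hz"],
        "nmf_slope_pct_per_s": reg["nmf_slope_pct_per_s"],
        "excluded_channels": sorted(
            set(norm.excluded_channels) | set(reg["excluded_channels"])
        ),
    }


def summarize_recording(
    endurance_left: EMGRecording,
    endurance_right: EMGRecording,
    mvc_left: EMGRecording,
    mvc_right: EMGRecording,
    window: float = WINDOW_S,
) -> FatigueSummary:
    """Full bilateral chain: preprocess, RMS maps, CoG migration, NMFslope.

    The global motor variability and NMFslope are the means of the left and
    right side values.
    """
    left = summarize_side(endurance_left, mvc_left, window)
    right = summarize_side(endurance_right, mvc_right, window)
    return FatigueSummary(
        motor_variability=0.5 * (left["mean_migration_cm"] + right["mean_migration_cm"]),
        nmf_slope=0.5 * (left["side_nmf_slope"] + right["side_nmf_slope"]),
        per_side={"left": left, "right": right},
    )
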