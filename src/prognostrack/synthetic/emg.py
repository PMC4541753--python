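"""Synthetic high-density grid EMG with programmed fatigue signatures.

Each 0.5-s block of each channel is band-limited noise (random phase, flat
magnitude over a band centred on the programmed median frequency), exactly
scaled to the channel's target RMS.  The target RMS across the grid is a
Gaussian spatial profile whose centre drifts along the programmed
centre-of-gravity trajectory; the spectral band centre declines along the
programmed median-frequency ramp.  A 60-Hz line component and broadband
noise (scaled to the local signal envelope) are added on top.

The point is not motor-unit realism: the generator gives the feature
estimators (median-frequency slope, CoG migration) a known ground truth
with the two properties they rely on — the spectrum's median tracks the
programmed MF and the RMS map's centre of gravity tracks the programmed
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..emg_features import EMGRecording, WINDOW_S
from ..geometry import GridGeometry


@dataclass
class EMGSimParams:
    """Ground-truth parameters for one synthetic grid recording.

    true_cog_velocity is in cm/s (0.2 cm/s = 0.1 cm per 0.5-s window).
    Both noise amplitudes are relative to the local (per-channel) signal
    envelope, so the signal-to-noise ratio is uniform across the grid.
    """

    duration_s: float = 30.0
    fs: float = 2048.0
    grid: GridGeometry = field(default_factory=GridGeometry)
    true_mf_start: float = 100.0
    true_mf_slope: float = -0.5
    true_cog_start: tuple[float, float] = (7.5, 2.5)
    true_cog_velocity: tuple[float, float] = (0.0, 0.0)
    spatial_sigma_cm: float = 1.5
    mf_band_halfwidth: float = 15.0
    amplitude_mv: float = 1.0
    line_noise_amplitude: float = 0.05
    broadband_noise_sd: float = 0.05
    active_channel: int | None = None
    side: str = "right"
    task: str = "endurance"
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        if not 0 < self.true_mf_start < self.fs / 2:
            raise ValueError("true_mf_start must lie in (0, fs/2)")
        mf_end = self.true_mf_start + self.true_mf_slope * self.duration_s
        for label, mf in (("start", self.true_mf_start), ("end", mf_end)):
            if mf - self.mf_band_halfwidth <= 0 or mf + self.mf_band_halfwidth >= self.fs / 2:
                raise ValueError(
                    f"MF band at trajectory {label} ({mf:.1f} +/- "
                    f"{self.mf_band_halfwidth:.1f} Hz) leaves (0, fs/2)"
                )
        if not self.grid.contains(*self.true_cog_start):
            raise ValueError(f"CoG start {self.true_cog_start} outside grid")
        end = (
            self.true_cog_start[0] + self.true_cog_velocity[0] * self.duration_s,
            self.true_cog_start[1] + self.true_cog_velocity[1] * self.duration_s,
        )
        if not self.grid.contains(*end):
            raise ValueError(
                f"programmed CoG trajectory leaves the grid (end point "
                f"({end[0]:.2f}, {end[1]:.2f}) cm outside "
                f"{self.grid.row_extent_cm:.2f} x {self.grid.col_extent_cm:.2f} cm)"
            )


def _band_noise_blocks(
    rng: np.random.Generator, n_channels: int, nper: int, fs: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """(n_channels, nper) independent unit-RMS flat-band noise blocks."""
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    k = int(mask.sum())
    spec = np.zeros((n_channels, freqs.size), dtype=complex)
    spec[:, mask] = rng.standard_normal((n_channels, k)) + 1j * rng.standard_normal(
        (n_channels, k)
    )
    x = np.fft.irfft(spec, n=nper, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return np.divide(x, rms, out=x, where=rms > 0)


def generate_emg_recording(params: EMGSimParams) -> EMGRecording:
    """Synthesize one grid recording from ground-truth fatigue parameters."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    nper = int(round(WINDOW_S * params.fs))
    n_blocks = int(params.duration_s / WINDOW_S)
    if n_blocks < 1:
        raise ValueError("duration must cover at least one 0.5-s block")
    n_samples = n_blocks * nper
    coords = grid.channel_coordinates()
    signal = np.zeros((grid.n_channels, n_samples))
    line_phase = rng.uniform(0, 2 * np.pi)
    for k in range(n_blocks):
        t0 = k * WINDOW_S
        mf = params.true_mf_start + params.true_mf_slope * t0
        cog = (
            params.true_cog_start[0] + params.true_cog_velocity[0] * t0,
            params.true_cog_start[1] + params.true_cog_velocity[1] * t0,
        )
        if params.active_channel is not None:
            amps = np.zeros(grid.n_channels)
            amps[params.active_channel] = params.amplitude_mv
        elif params.task == "mvc":
            # a maximal contraction activates the muscle volume broadly:
            # uniform grid amplitude, so MVC-normalization cancels channel
            # gain without reshaping endurance maps
            amps = np.full(grid.n_channels, params.amplitude_mv)
        else:
            d2 = ((coords - np.asarray(cog)) ** 2).sum(axis=1)
            amps = params.amplitude_mv * np.exp(-d2 / (2.0 * params.spatial_sigma_cm**2))
        sl = slice(k * nper, (k + 1) * nper)
        blocks = _band_noise_blocks(
            rng,
            grid.n_channels,
            nper,
            params.fs,
            mf - params.mf_band_halfwidth,
            mf + params.mf_band_halfwidth,
        )
        signal[:, sl] = amps[:, None] * blocks
        if params.broadband_noise_sd > 0:
            noise = rng.standard_normal((grid.n_channels, nper))
            signal[:, sl] += params.broadband_noise_sd * amps[:, None] * noise
        if params.line_noise_amplitude > 0:
            # line interference scaled to the local envelope, like the
            # broadband term, so every channel keeps a finite SNR
            t = (np.arange(nper) + k * nper) / params.fs
            line = np.sin(2 * np.pi * 60.0 * t + line_phase)
            signal[:, sl] += params.line_noise_amplitude * amps[:, None] * line[None, :]
    return EMGRecording(
        signal=signal,
        fs=params.fs,
        grid=grid,
        side=params.side,
        task=params.task,
        meta={
            "seed": params.seed,
            "ground_truth": {
                "true_mf_start": params.true_mf_start,
                "true_mf_slope": params.true_mf_slope,
                "true_cog_start": list(params.true_cog_start),
                "true_cog_velocity": list(params.true_cog_velocity),
                "duration_s": params.duration_s,
            },
        },
    )
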