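"""Unit and property tests for the EMG processing chain."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from prognostrack.emg_features import (
    EMGRecording,
    center_of_gravity,
    median_frequency,
    mf_series,
    motor_variability_side,
    mvc_reference_rms,
    nmf_slope,
    normalize_rms,
    preprocess,
    single_differential,
    window_rms,
)
from prognostrack.geometry import GridGeometry

FS = 1024.0


def make_recording(signal, fs=FS, grid=None, **kw):
    grid = grid or GridGeometry(n_rows=signal.shape[0], n_cols=1)
    return EMGRecording(signal=signal, fs=fs, grid=grid, **kw)


# ---------------------------------------------------------------------------
# preprocess


class TestPreprocess:
    def test_line_interference_removed(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)[None, :]
        out = preprocess(make_recording(x)).signal[0]
        core = slice(int(FS), int(3 * FS))  # avoid filter edge transients
        assert np.sqrt(np.mean(out[core] ** 2)) <= 0.1 * np.sqrt(np.mean(x[0, core] ** 2))

    def test_subband_stopband_attenuates_5_hz(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 5.0 * t)[None, :]
        out = preprocess(make_recording(x)).signal[0]
        core = slice(int(FS), int(3 * FS))
        # 2nd-order Butterworth applied twice: >= 12 dB down at 5 Hz
        assert np.sqrt(np.mean(out[core] ** 2)) < 0.25 * np.sqrt(np.mean(x[0, core] ** 2))

    def test_white_noise_matches_frequency_response_oracle(self, rng):
        """Measured power transfer tracks an independently composed |H|^2."""
        x = rng.standard_normal((1, int(30 * FS)))
        rec = make_recording(x)
        out = preprocess(rec).signal[0]
        f, pxx_in = sps.welch(x[0], fs=FS, nperseg=2048)
        _, pxx_out = sps.welch(out, fs=FS, nperseg=2048)
        # oracle: cascade response evaluated from freshly designed filters,
        # squared once more because filtering is forward-backward
        nyq = FS / 2
        sos = sps.butter(2, [20 / nyq, 450 / nyq], btype="bandpass", output="sos")
        _, h = sps.sosfreqz(sos, worN=f, fs=FS)
        gain = np.abs(h) ** 2
        for f0 in (60.0, 120.0, 180.0, 240.0, 300.0, 360.0, 420.0):
            b, a = sps.iirnotch(f0 / nyq, 30.0)
            _, hn = sps.freqz(b, a, worN=f, fs=FS)
            gain *= np.abs(hn) ** 2
        gain = gain**2
        for lo, hi in [(30, 50), (95, 115), (200, 220), (380, 400)]:
            band = (f >= lo) & (f <= hi)
            measured = np.mean(pxx_out[band]) / np.mean(pxx_in[band])
            expected = np.mean(gain[band])
            assert measured == pytest.approx(expected, rel=0.05)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            preprocess(make_recording(np.zeros((1, 1000)), fs=800.0))


# ---------------------------------------------------------------------------
# window RMS


class TestWindowRMS:
    def test_constant_signal(self):
        rec = make_recording(np.full((2, int(2 * FS)), -3.0))
        maps = window_rms(rec)
        assert maps.values.shape == (4, 2)
        assert np.allclose(maps.values, 3.0)

    def test_sinusoid_integer_periods(self):
        t = np.arange(int(2 * FS)) / FS
        a = 2.5
        rec = make_recording((a * np.sin(2 * np.pi * 40.0 * t))[None, :])
        maps = window_rms(rec)
        assert np.allclose(maps.values, a / np.sqrt(2), rtol=1e-6)

    def test_matches_direct_summation_oracle(self, rng):
        sig = rng.standard_normal((3, int(1.7 * FS)))
        rec = make_recording(sig)
        maps = window_rms(rec)
        nper = int(0.5 * FS)
        assert maps.n_windows == 3  # trailing partial window discarded
        for k in range(maps.n_windows):
            for c in range(3):
                seg = sig[c, k * nper : (k + 1) * nper]
                oracle = np.sqrt(sum(v * v for v in seg) / nper)
                assert maps.values[k, c] == pytest.approx(oracle, rel=1e-12)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError, match="window"):
            window_rms(make_recording(np.zeros((1, 10))))


class TestNormalizeRMS:
    def test_equal_maps_give_100_percent(self, rng):
        rec = make_recording(rng.standard_normal((3, int(FS))))
        maps = window_rms(rec)
        ref = maps.values[0].copy()
        norm = normalize_rms(maps, ref)
        assert np.allclose(norm.values[0], 100.0)
        assert norm.units == "%MVC"

    def test_doubling_reference_halves_values(self, rng):
        rec = make_recording(rng.standard_normal((3, int(FS))))
        maps = window_rms(rec)
        ref = np.abs(rng.standard_normal(3)) + 0.5
        a = normalize_rms(maps, ref)
        b = normalize_rms(maps, 2 * ref)
        assert np.allclose(b.values, a.values / 2)

    def test_zero_reference_channel_flagged(self, rng):
        rec = make_recording(rng.standard_normal((3, int(FS))))
        maps = window_rms(rec)
        ref = np.array([1.0, 0.0, 2.0])
        norm = normalize_rms(maps, ref)
        assert norm.excluded_channels == [1]
        assert np.all(np.isnan(norm.values[:, 1]))
        assert np.all(np.isfinite(norm.values[:, [0, 2]]))


# ---------------------------------------------------------------------------
# centre of gravity and migration


class TestCenterOfGravity:
    def test_uniform_map_gives_grid_center(self):
        grid = GridGeometry()  # 13 x 5, 1.25 cm
        cog = center_of_gravity(np.ones(65), grid)
        assert cog == pytest.approx((7.5, 2.5))

    def test_point_mass(self):
        grid = GridGeometry()
        w = np.zeros(65)
        w[(3 - 1) * 5 + (2 - 1)] = 4.2  # row 3, col 2
        assert center_of_gravity(w, grid) == pytest.approx((2.5, 1.25))

    def test_matches_double_loop_oracle(self, rng):
        grid = GridGeometry()
        w = rng.random(65)
        d = grid.inter_electrode_distance
        num_r = num_c = den = 0.0
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                v = w[i * grid.n_cols + j]
                num_r += v * i * d
                num_c += v * j * d
                den += v
        cog = center_of_gravity(w, grid)
        assert cog[0] == pytest.approx(num_r / den, abs=1e-12)
        assert cog[1] == pytest.approx(num_c / den, abs=1e-12)

    def test_all_zero_map_undefined(self):
        cog = center_of_gravity(np.zeros(65), GridGeometry())
        assert np.isnan(cog[0]) and np.isnan(cog[1])

    @given(st.integers(0, 2**32 - 1))
    def test_containment_property(self, seed):
        grid = GridGeometry()
        w = np.random.default_rng(seed).random(65)
        r, c = center_of_gravity(w, grid)
        assert 0 <= r <= grid.row_extent_cm
        assert 0 <= c <= grid.col_extent_cm


class TestMotorVariability:
    def test_static_cog_gives_zero(self):
        cogs = np.tile([3.0, 2.0], (10, 1))
        assert motor_variability_side(cogs) == 0.0

    def test_constant_step(self):
        cogs = np.column_stack([np.arange(10) * 0.1, np.zeros(10)])
        assert motor_variability_side(cogs) == pytest.approx(0.1)

    def test_matches_pairwise_distance_oracle(self, rng):
        cogs = rng.random((20, 2)) * 5
        oracle = np.mean(
            [np.hypot(*(cogs[i + 1] - cogs[i])) for i in range(len(cogs) - 1)]
        )
        assert motor_variability_side(cogs) == pytest.approx(oracle, rel=1e-12)

    def test_translation_invariance_and_nonnegativity(self, rng):
        cogs = rng.random((15, 2))
        shifted = cogs + np.array([2.0, -1.0])
        assert motor_variability_side(cogs) == pytest.approx(
            motor_variability_side(shifted)
        )
        assert motor_variability_side(cogs) >= 0

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="two valid windows"):
            motor_variability_side(np.array([[1.0, 1.0]]))


# ---------------------------------------------------------------------------
# median frequency and NMFslope


class TestMedianFrequency:
    def test_single_tone(self):
        t = np.arange(int(0.5 * FS)) / FS
        x = np.sin(2 * np.pi * 80.0 * t)
        assert median_frequency(x, FS) == pytest.approx(80.0, abs=2.0)

    def test_flat_band_midpoint(self, rng):
        # flat spectrum over 20-120 Hz has its half-power point at 70 Hz;
        # averaged over realizations to tame single-draw spectral wobble
        nper = int(0.5 * FS)
        freqs = np.fft.rfftfreq(nper, 1 / FS)
        mask = (freqs >= 20) & (freqs <= 120)
        mfs = []
        for _ in range(30):
            spec = mask * np.exp(1j * rng.uniform(0, 2 * np.pi, freqs.size))
            x = np.fft.irfft(spec, n=nper)
            mfs.append(median_frequency(x, FS))
        assert np.mean(mfs) == pytest.approx(70.0, abs=2.0)

    def test_matches_cumulative_power_oracle(self):
        t = np.arange(int(0.5 * FS)) / FS
        x = 1.0 * np.sin(2 * np.pi * 50.0 * t) + 0.8 * np.sin(2 * np.pi * 150.0 * t)
        freqs, pxx = sps.periodogram(x, fs=FS, window="hann", detrend="constant")
        cum = np.cumsum(pxx)
        oracle_bin = freqs[np.searchsorted(cum, 0.5 * cum[-1])]
        assert abs(median_frequency(x, FS) - oracle_bin) <= freqs[1] - freqs[0]

    def test_bisection_property(self, rng):
        x = rng.standard_normal(int(0.5 * FS))
        mf = median_frequency(x, FS)
        freqs, pxx = sps.periodogram(x, fs=FS, window="hann", detrend="constant")
        below = pxx[freqs < mf].sum() / pxx.sum()
        binmass = pxx.max() / pxx.sum()
        assert 0.5 - binmass <= below <= 0.5

    def test_zero_variance_window_missing(self):
        assert np.isnan(median_frequency(np.ones(512), FS))


class TestNMFSlope:
    def test_constant_series(self):
        mf = np.full((10, 2), 90.0)
        reg = nmf_slope(mf, np.arange(10) * 0.5)
        assert reg["side_nmf_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        times = np.arange(120) * 0.5
        mf = (100.0 - times / 3.0)[:, None]
        reg = nmf_slope(mf, times)
        assert reg["mf_slope_hz_per_s"][0] == pytest.approx(-1 / 3)
        assert reg["imf_hz"][0] == pytest.approx(100.0)
        assert reg["side_nmf_slope"] == pytest.approx(-1 / 3, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        times = np.arange(30) * 0.5
        mf = (80 - 0.2 * times + rng.standard_normal(30))[:, None]
        reg = nmf_slope(mf, times)
        x = np.column_stack([times, np.ones_like(times)])
        beta = np.linalg.solve(x.T @ x, x.T @ mf[:, 0])
        assert reg["mf_slope_hz_per_s"][0] == pytest.approx(beta[0], abs=1e-9)
        assert reg["imf_hz"][0] == pytest.approx(beta[1], abs=1e-9)

    def test_nonpositive_intercept_channel_excluded(self):
        times = np.arange(10) * 0.5
        mf = np.column_stack([np.full(10, 80.0), -5.0 + 0.1 * times])
        reg = nmf_slope(mf, times)
        assert reg["excluded_channels"] == [1]
        assert np.isnan(reg["nmf_slope_pct_per_s"][1])


# ---------------------------------------------------------------------------
# scale equivariance and derivations


class TestScaleEquivariance:
    def test_cog_mf_nmf_invariant_rms_scales(self, rng, small_grid):
        sig = rng.standard_normal((small_grid.n_channels, int(3 * FS)))
        rec1 = make_recording(sig, grid=small_grid)
        rec2 = make_recording(7.5 * sig, grid=small_grid)
        m1, m2 = window_rms(rec1), window_rms(rec2)
        assert np.allclose(m2.values, 7.5 * m1.values)
        assert center_of_gravity(m1.values[0], small_grid) == pytest.approx(
            center_of_gravity(m2.values[0], small_grid)
        )
        mf1, t1 = mf_series(rec1)
        mf2, _ = mf_series(rec2)
        assert np.allclose(mf1, mf2)
        assert nmf_slope(mf1, t1)["side_nmf_slope"] == pytest.approx(
            nmf_slope(mf2, t1)["side_nmf_slope"]
        )

    def test_single_differential_reduces_rows(self, rng):
        grid = GridGeometry(n_rows=4, n_cols=3)
        rec = make_recording(rng.standard_normal((12, 256)), grid=grid)
        sd = single_differential(rec)
        assert sd.grid.n_rows == 3 and sd.grid.n_cols == 3
        assert sd.signal.shape == (9, 256)

    def test_mvc_reference_uses_central_segment(self):
        # amplitude 1 in the middle 3 s, 10 at the edges: central RMS ~ 1
        fs = FS
        n = int(5 * fs)
        sig = np.full((1, n), 10.0)
        mid = slice(int(fs), int(4 * fs))
        sig[0, mid] = 1.0
        rec = make_recording(sig, fs=fs)
        ref = mvc_reference_rms(rec, central_seconds=3.0)
        assert ref[0] == pytest.approx(1.0)
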