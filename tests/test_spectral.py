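"""Spectral estimators: Welch, band power, sliding windows, TFR, CSD."""

import numpy as np
import pandas as pd
import pytest

from bistable_alpha import GenParams, gen_percept_table, gen_recording
from bistable_alpha.containers import Recording
from bistable_alpha.spectral import (
    alpha_timecourse,
    band_power,
    multitaper_csd,
    percept_alpha_power,
    sliding_band_power,
    tfr_around_press,
    tfr_window_length,
    welch_psd,
)

FS = 256.0


def tone(freq, amp, seconds, fs=FS, phase=0.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def cut(x, width=1.0, step=0.5, fs=FS):
    w, s = int(width * fs), int(step * fs)
    n = (len(x) - w) // s + 1
    return np.stack([x[i * s:i * s + w] for i in range(n)])


class TestWelch:
    def test_tone_peak_on_bin(self):
        psd = welch_psd(cut(tone(9, 2, 10)), FS)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(9.0)

    def test_tone_integrated_power_is_half_amp_squared(self):
        amp = 3.0
        psd = welch_psd(cut(tone(9, amp, 10)), FS)
        assert psd.power.sum() * psd.df == pytest.approx(amp ** 2 / 2, rel=0.02)

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(FS) * 60)
        psd = welch_psd(cut(x), FS)
        assert psd.power.sum() * psd.df == pytest.approx(x.var(), rel=0.01)

    def test_averaging_shrinks_bin_variance(self):
        rng = np.random.default_rng(1)
        few = welch_psd(rng.standard_normal((4, int(FS))), FS)
        many = welch_psd(rng.standard_normal((64, int(FS))), FS)
        assert many.power.std() < few.power.std() / 2

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.ones((1, 1)), FS)


class TestBandPower:
    def test_two_channel_average(self):
        x = np.stack([tone(9, 1, 4), tone(9, np.sqrt(3), 4)])  # powers p and 3p
        wins = np.stack([x[:, i * 128:i * 128 + 256] for i in range(7)])
        bp = band_power(welch_psd(wins, FS))
        assert bp.mean() == pytest.approx(2 * bp[0], rel=0.02)

    def test_doubling_amplitude_adds_log4(self):
        b1 = band_power(welch_psd(cut(tone(9, 1, 8)), FS)).item()
        b2 = band_power(welch_psd(cut(tone(9, 2, 8)), FS)).item()
        assert np.log(b2) - np.log(b1) == pytest.approx(np.log(4), abs=1e-6)

    def test_band_bounds_inclusive(self):
        from bistable_alpha.spectral import PSD
        power = np.zeros(31)
        power[7] = power[11] = 2.0                 # mass exactly on the edges
        psd = PSD(freqs=np.arange(31.0), power=power, n_windows=1)
        assert band_power(psd).item() == pytest.approx(4.0)

    def test_bad_band_rejected(self):
        psd = welch_psd(cut(tone(9, 1, 4)), FS)
        with pytest.raises(ValueError):
            band_power(psd, 11, 7)


class TestSlidingPower:
    def test_window_count_one_second_horizon(self):
        rec = Recording(tone(9, 1, 3)[None], FS, ["c1"])
        series = sliding_band_power(rec, 0.5, ["c1"], horizon=1.0)
        assert len(series) == 11
        assert series["centre"].iloc[0] == pytest.approx(0.25)

    def test_constant_tone_flat_series(self):
        rec = Recording(tone(9, 2, 4)[None], FS, ["c1"])
        series = sliding_band_power(rec, 0.0, ["c1"], horizon=2.0)
        assert series["log_power"].std() < 0.02

    def test_short_percept_empty(self):
        rec = Recording(tone(9, 1, 2)[None], FS, ["c1"])
        assert sliding_band_power(rec, 0.0, ["c1"], horizon=0.3).empty


class TestPerceptAlphaPower:
    def test_known_amplitude(self):
        rec = Recording(tone(9, 2, 12)[None], FS, ["c1"])
        row = pd.Series({"onset": 0.0, "duration": 12.0})
        la = percept_alpha_power(rec, row, ["c1"])
        assert la == pytest.approx(np.log(2.0), abs=0.02)   # log(A²/2)

    def test_too_short_gives_nan(self):
        rec = Recording(tone(9, 2, 3)[None], FS, ["c1"])
        row = pd.Series({"onset": 0.0, "duration": 2.4})
        assert np.isnan(percept_alpha_power(rec, row, ["c1"]))


class TestTFR:
    @pytest.mark.parametrize("freq,ms", [(4, 1250), (10, 500), (30, 167)])
    def test_five_cycle_window_lengths(self, freq, ms):
        assert round(tfr_window_length(freq) * 1000) == ms

    def test_stationary_noise_matches_welch_density(self):
        """TFR and Welch estimate the same density for a stationary signal."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal(int(FS) * 120)
        rec = Recording(x[None], FS, ["c1"])
        tfr = tfr_around_press(rec, np.arange(4.0, 116.0, 4.0), ["c1"])
        psd = welch_psd(cut(x), FS)
        sel_t = (tfr.freqs >= 7) & (tfr.freqs <= 11)
        sel_w = (psd.freqs >= 7) & (psd.freqs <= 11)
        assert tfr.power[sel_t].mean() == pytest.approx(
            psd.power[sel_w].mean(), rel=0.10)

    def test_edge_press_skipped(self):
        rec = Recording(tone(10, 1, 10)[None], FS, ["c1"])
        tfr = tfr_around_press(rec, [0.5, 5.0], ["c1"])
        assert tfr.n_used == 1 and tfr.n_skipped == 1

    def test_generator_dip_minimum_near_press(self, montage16):
        p = GenParams(n_subjects=1, n_days=1, n_sessions=1, session_length=120,
                      snr=np.inf, dip_depth=0.5, alpha_band_sd=0.0,
                      alpha_log_sd=0.0, sfreq=256, seed=4)
        tab = gen_percept_table(p)
        rec, _ = gen_recording(tab, montage16, p)
        presses = tab["onset"].to_numpy()[1:]
        presses = presses[(presses > 3) & (presses < rec.duration - 3)]
        tfr = tfr_around_press(rec, presses, montage16.posterior_set)
        sel = (tfr.freqs >= 7) & (tfr.freqs <= 11)
        course = tfr.power[sel].mean(axis=0)
        t_min = tfr.times[np.argmin(course)]
        assert -0.5 < t_min < 0.5
        dip = course[np.abs(tfr.times + 0.3) < 0.011][0]
        plateau = course[np.abs(tfr.times - 1.0) < 0.011][0]
        assert dip / plateau == pytest.approx(0.5, abs=0.2)


class TestMultitaperCSD:
    def test_identical_channels_rank_one_coherence_one(self):
        rng = np.random.default_rng(0)
        seg = rng.standard_normal((20, 1, 256)).repeat(2, axis=1)
        csd = multitaper_csd(seg, FS)
        csd.check()
        coh = abs(csd.matrix[0, 1]) / np.sqrt(
            csd.matrix[0, 0].real * csd.matrix[1, 1].real)
        assert coh == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.matrix_rank(csd.matrix, tol=1e-10) == 1

    def test_independent_channels_off_diagonal_vanishes(self):
        rng = np.random.default_rng(1)
        csd = multitaper_csd(rng.standard_normal((400, 2, 256)), FS)
        csd.check()
        rel = abs(csd.matrix[0, 1]) / np.sqrt(
            csd.matrix[0, 0].real * csd.matrix[1, 1].real)
        assert rel < 0.1

    def test_diagonal_matches_welch_band_power(self):
        rng = np.random.default_rng(2)
        segs = rng.standard_normal((100, 1, 256))
        csd = multitaper_csd(segs, FS)
        welch = band_power(welch_psd(segs[:, 0], FS)).item()
        assert csd.matrix[0, 0].real == pytest.approx(welch, rel=0.10)

    def test_taper_count_rule(self):
        rng = np.random.default_rng(3)
        csd = multitaper_csd(rng.standard_normal((5, 2, 256)), FS,
                             centre=9, smoothing=2)
        assert csd.n_tapers == 3                    # floor(2*1*2) - 1

    def test_smoothing_too_small_names_minimum(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="at least"):
            multitaper_csd(rng.standard_normal((5, 2, 256)), FS, smoothing=0.4)


class TestAlphaTimecourse:
    def _session(self, amp_fn, seconds=120, seed=0):
        """Single-channel recording with prescribed alpha amplitude over time."""
        rng = np.random.default_rng(seed)
        n = int(seconds * FS)
        t = np.arange(n) / FS
        x = amp_fn(t) * np.sqrt(2) * np.cos(2 * np.pi * 9 * t + rng.uniform(0, 2 * np.pi))
        rec = Recording(x[None], FS, ["c1"])
        onsets = np.arange(0.0, seconds - 15, 15.0)
        per = pd.DataFrame({
            "onset": onsets, "duration": 15.0, "included": True,
        })
        return rec, per

    def test_constant_alpha_gives_zero_course(self):
        rec, per = self._session(lambda t: 3.0 * np.ones_like(t))
        tc = alpha_timecourse((rec, per), ["c1"])
        assert np.abs(tc["mean"]).max() < 0.02

    def test_first_segment_baseline_is_exact_zero(self):
        rng = np.random.default_rng(5)
        rec, per = self._session(lambda t: 2 + np.sin(0.2 * t), seed=5)
        tc = alpha_timecourse((rec, per), ["c1"])
        # earliest aligned point of a 15 s percept: -(15 - 1 - 0.5) = -13.5 s
        first = tc.loc[tc["time_to_reversal"] == tc["time_to_reversal"].min()]
        assert abs(first["mean"].iloc[0]) < 1e-9

    def test_grid_alignment(self):
        rec, per = self._session(lambda t: np.ones_like(t))
        tc = alpha_timecourse((rec, per), ["c1"])
        steps = np.diff(np.sort(tc["time_to_reversal"]))
        np.testing.assert_allclose(steps, 0.5, atol=1e-9)
        assert tc["time_to_reversal"].max() == pytest.approx(-1.5)

    def test_ramping_amplitude_recovers_power_slope(self):
        # amplitude grows 2%/s -> log-power slope = 2 * log-amplitude slope
        rate = 0.02
        rec, per = self._session(lambda t: 2 * np.exp(rate * (t % 15)))
        tc = alpha_timecourse((rec, per), ["c1"])
        slope = np.polyfit(tc["time_to_reversal"], tc["mean"], 1)[0]
        assert slope == pytest.approx(2 * rate, rel=0.2)
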