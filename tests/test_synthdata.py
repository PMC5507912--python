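"""Generator behaviour: calibration, reproducibility, signal content."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from bistable_alpha import (
    GenParams,
    calibrate_gamma,
    events_from_percepts,
    gen_percept_table,
    gen_recording,
    gen_toy_leadfield,
)
from bistable_alpha.percepts import build_percepts, stable_windows
from bistable_alpha.spectral import band_power, welch_psd
from bistable_alpha.synthdata import truncated_gamma_stats



class TestGammaCalibration:
    def test_truncated_mean_hits_target(self):
        k, s = calibrate_gamma()
        mean, _, mass = truncated_gamma_stats(k, s)
        assert mean == pytest.approx(8.87, abs=1e-6)
        assert mass > 0.9          # the inclusion filter barely binds

    def test_sample_mean_matches_truncated_mean(self):
        """Monte-Carlo filtered mean vs the closed-form truncated integral."""
        p = GenParams(n_subjects=2, n_days=1, n_sessions=1, session_length=30000,
                      coupling_slope=0, re_sd_subject=0, re_sd_day=0,
                      re_sd_session=0, sd_alpha_shift=0, sd_direct_shift=0, seed=7)
        tab = gen_percept_table(p)
        inc = tab.loc[tab["included"], "duration"]
        assert len(inc) > 5000
        k, s = calibrate_gamma()
        target, _, _ = truncated_gamma_stats(k, s)
        sem = inc.std() / np.sqrt(len(inc))
        assert abs(inc.mean() - target) < 3 * sem

    def test_gamma_moments_untruncated(self):
        """Raw draws (no shifts, no coupling) have gamma mean k*theta."""
        p = GenParams(n_subjects=1, n_days=1, n_sessions=1, session_length=90000,
                      coupling_slope=0, re_sd_subject=0, re_sd_day=0,
                      re_sd_session=0, sd_alpha_shift=0, sd_direct_shift=0, seed=3)
        tab = gen_percept_table(p)
        k, s = calibrate_gamma()
        sem = tab["duration"].std() / np.sqrt(len(tab))
        assert abs(tab["duration"].mean() - k * s) < 3 * sem
        assert tab["duration"].skew() > 0


class TestPerceptTable:
    def test_same_seed_identical(self):
        p = GenParams(n_subjects=2, n_days=2, n_sessions=2, session_length=100, seed=5)
        a, b = gen_percept_table(p), gen_percept_table(p)
        pd.testing.assert_frame_equal(a, b)

    def test_onsets_strictly_increasing_and_contiguous(self):
        tab = gen_percept_table(GenParams(n_subjects=2, session_length=120, seed=1))
        for _, grp in tab.groupby(["subject", "day", "session"]):
            onsets = grp["onset"].to_numpy()
            assert np.all(np.diff(onsets) > 0)
            np.testing.assert_allclose(
                onsets[1:], onsets[:-1] + grp["duration"].to_numpy()[:-1])

    def test_null_coupling_decorrelates_alpha_and_duration(self):
        p = GenParams(coupling_slope=0, sd_alpha_shift=0, sd_direct_shift=0,
                      re_sd_subject=0, re_sd_day=0, re_sd_session=0,
                      n_subjects=2, n_days=1, n_sessions=1,
                      session_length=20000, seed=11)
        tab = gen_percept_table(p)
        r = np.corrcoef(tab["log_alpha_true"], np.log(tab["duration"]))[0, 1]
        assert abs(r) < 3 / np.sqrt(len(tab))

    def test_condition_contrast_in_latent_alpha(self):
        p = GenParams(n_subjects=6, n_sessions=3, session_length=600, seed=2)
        tab = gen_percept_table(p)
        sd = tab.loc[tab["condition"] == "SD", "log_alpha_true"]
        ns = tab.loc[tab["condition"] == "NS", "log_alpha_true"]
        contrast = sd.mean() - ns.mean()
        sem = np.sqrt(sd.var() / len(sd) + ns.var() / len(ns))
        assert abs(contrast - 0.202) < 3 * sem

    def test_return_transition_rate(self):
        tab = gen_percept_table(GenParams(n_subjects=4, session_length=1200, seed=9))
        frac = (tab["transition"] == "return").mean()
        assert 0.06 < frac < 0.12

    def test_events_round_trip_durations(self):
        tab = gen_percept_table(GenParams(n_subjects=2, session_length=150, seed=4))
        rebuilt = build_percepts(events_from_percepts(tab))
        np.testing.assert_allclose(
            np.sort(rebuilt["duration"].to_numpy()),
            np.sort(tab["duration"].to_numpy()))
        assert (rebuilt["transition"].fillna("none").to_numpy()
                == tab["transition"].fillna("none").to_numpy()).all()

    @pytest.mark.parametrize("field,value", [
        ("gamma_shape", -1.0), ("gamma_scale", 0.0), ("dip_depth", 1.5),
        ("session_length", -10.0), ("re_sd_subject", -0.1), ("snr", 0.0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            replace(GenParams(), **{field: value}).validate()


class TestRecording:
    def test_pure_tone_psd_peak_at_alpha(self, montage16, tone_params):
        tab = gen_percept_table(tone_params)
        rec, _ = gen_recording(tab, montage16, tone_params)
        row = tab.loc[tab["included"] & (tab["duration"] > 5)].iloc[0]
        starts = stable_windows(row["onset"], row["duration"])
        wins = np.stack([rec.extract(s, 1.0, montage16.posterior_set).mean(axis=0)
                         for s in starts])
        psd = welch_psd(wins, rec.sfreq)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(9.0)

    def test_posterior_average_band_power_matches_latent(self, montage16, tone_params):
        """Band power of the posterior-average signal realizes exp(x)."""
        tab = gen_percept_table(tone_params)
        rec, _ = gen_recording(tab, montage16, tone_params)
        sel = tab.loc[tab["included"] & (tab["duration"] > 5)].head(5)
        for _, row in sel.iterrows():
            starts = stable_windows(row["onset"], row["duration"])
            wins = np.stack([rec.extract(s, 1.0, montage16.posterior_set).mean(axis=0)
                             for s in starts])
            bp = band_power(welch_psd(wins, rec.sfreq)).item()
            assert bp == pytest.approx(np.exp(row["log_alpha_true"]), rel=0.10)

    def test_amplitude_doubling_quadruples_power(self, montage16, tone_params):
        tab = gen_percept_table(tone_params).head(3).copy()
        rec1, _ = gen_recording(tab, montage16, tone_params)
        tab2 = tab.copy()
        tab2["log_alpha_true"] += np.log(4)      # doubled amplitude
        rec2, _ = gen_recording(tab2, montage16, tone_params)
        v1 = rec1.data[0].var()
        v2 = rec2.data[0].var()
        assert v2 / v1 == pytest.approx(4.0, rel=0.05)

    def test_same_seed_identical_recording(self, montage16):
        p = GenParams(n_subjects=1, n_days=1, n_sessions=1, session_length=30,
                      sfreq=256, seed=8)
        tab = gen_percept_table(p)
        r1, _ = gen_recording(tab, montage16, p)
        r2, _ = gen_recording(tab, montage16, p)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_dip_halves_alpha_power_near_press(self, montage16):
        p = GenParams(n_subjects=1, n_days=1, n_sessions=1, session_length=120,
                      snr=np.inf, dip_depth=0.5, alpha_band_sd=0.0,
                      alpha_log_sd=0.0, sfreq=256, seed=4)
        tab = gen_percept_table(p)
        rec, _ = gen_recording(tab, montage16, p)
        post = montage16.posterior_set
        presses = tab["onset"].to_numpy()[1:]
        presses = presses[(presses > 3) & (presses < rec.duration - 3)]
        vin = [rec.extract(t - 0.45, 0.4, post).mean(axis=0).var() for t in presses]
        vout = [rec.extract(t + 0.7, 0.5, post).mean(axis=0).var() for t in presses]
        assert np.mean(vin) / np.mean(vout) == pytest.approx(0.5, abs=0.12)

    def test_overlapping_percepts_rejected(self, montage16, tone_params):
        tab = gen_percept_table(tone_params).head(3).copy()
        tab.loc[tab.index[1], "onset"] = tab.iloc[0]["onset"] + 0.1
        with pytest.raises(ValueError, match="overlap|sorted|consisten"):
            gen_recording(tab.sort_values("onset"), montage16, tone_params)

    def test_noise_snr_scaling(self, montage16):
        """Alpha-band noise power at a posterior channel tracks 1/snr."""
        base = GenParams(n_subjects=1, n_days=1, n_sessions=1, session_length=40,
                         sfreq=256, seed=6, dip_depth=0.0)
        tab = gen_percept_table(base)
        silent = tab.copy()
        silent["log_alpha_true"] = -np.inf     # no oscillation, noise only
        levels = {}
        for snr in (2.0, 8.0):
            p = replace(base, snr=snr)
            rec, _ = gen_recording(silent, montage16, p)
            ch = rec.ch_names.index(montage16.posterior_set[0])
            wins = np.stack([rec.data[ch, i * 256:(i + 1) * 256]
                             for i in range(int(rec.duration) - 1)])
            levels[snr] = band_power(welch_psd(wins, 256.0)).item()
        assert levels[2.0] / levels[8.0] == pytest.approx(4.0, rel=0.35)


class TestToyLeadfield:
    def test_identity_mode_maps_voxel_to_channel(self, montage16):
        lf = gen_toy_leadfield(16, montage16, mode="identity")
        np.testing.assert_array_equal(lf.gains, np.eye(16))

    def test_grid_nearest_neighbour_distance_is_spacing(self, montage16):
        lf = gen_toy_leadfield(27, montage16, spacing=10.0)
        d = np.linalg.norm(lf.grid[:, None] - lf.grid[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        np.testing.assert_allclose(d.min(axis=1), 10.0)

    def test_random_mode_full_rank(self, montage16):
        lf = gen_toy_leadfield(8, montage16, mode="random", seed=3)
        assert np.linalg.matrix_rank(lf.gains) == 8
        np.testing.assert_allclose(np.linalg.norm(lf.gains, axis=1), 1.0)

    def test_errors(self, montage16):
        with pytest.raises(ValueError):
            gen_toy_leadfield(1, montage16)
        with pytest.raises(ValueError):
            gen_toy_leadfield(8, montage16, mode="identity")
        with pytest.raises(ValueError):
            gen_toy_leadfield(8, montage16, mode="bogus")
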