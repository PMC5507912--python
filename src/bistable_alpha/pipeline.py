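"""Orchestration: preprocessing, configuration, and the end-to-end run.

``run_pipeline`` sequences the full analysis on simulated (or user) data:
simulate -> preprocess -> epochs -> per-percept alpha power -> duration
regression -> sliding-window prediction -> reversal-locked TFR ->
pre-reversal time course -> (optional) beamformer z-map -> KS condition
comparison -> mediation, and writes one JSON manifest holding every
statistic together with the seed, configuration, and output hashes, so a
manifest is reproducible from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from . import __version__
from .containers import Montage, Recording, write_table
from .inference import fit_lmem, ks_two_sample, mediate, sliding_prediction
from .percepts import build_percepts, duration_summary, return_fraction
from .spectral import alpha_timecourse, percept_csd, power_table, sliding_band_power, tfr_around_press
from .synthdata import GenParams, default_montage, events_from_percepts, gen_percept_table, gen_recording, gen_toy_leadfield


@dataclass
class Config:
    """Flat analysis configuration; defaults are the study parameters."""

    band_lo: float = 7.0
    band_hi: float = 11.0
    welch_width: float = 1.0
    welch_step: float = 0.5
    guard_pre: float = 1.0
    guard_post: float = 1.0
    slide_width: float = 0.5
    slide_step: float = 0.05
    slide_horizon: float = 1.0
    slide_min_n: int = 50
    tfr_fmin: float = 4.0
    tfr_fmax: float = 30.0
    tfr_cycles: int = 5
    csd_centre: float = 9.0
    csd_smoothing: float = 2.0
    bf_lambda: float = 0.05
    bf_threshold: float = 2.326
    grid_spacing: float = 10.0
    n_voxels: int = 27
    duration_min: float = 1.5
    duration_max: float = 60.0
    timecourse_horizon: float = 25.0
    baseline_rule: str = "first"
    highpass: float = 0.5
    line_freq: float = 50.0
    n_channels: int = 61
    sources: bool = False
    sim: GenParams = field(default_factory=GenParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        known = set(cls.__dataclass_fields__) - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = set(GenParams.__dataclass_fields__)
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
        cfg = cls(**raw, sim=GenParams(**sim_raw))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("band bounds must satisfy 0 < lo < hi")
        for name in ("welch_width", "welch_step", "slide_width", "slide_step",
                     "grid_spacing", "line_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_min >= self.duration_max:
            raise ValueError("duration_min must be below duration_max")
        if self.baseline_rule not in ("first", "preonset"):
            raise ValueError("baseline_rule must be 'first' or 'preonset'")
        self.sim.validate()


def preprocess(
    recording: Recording,
    highpass: float = 0.5,
    line_freq: float = 50.0,
    order: int = 4,
    bad_channels: tuple[str, ...] = (),
    bad_policy: str = "interpolate",
    montage: Montage | None = None,
) -> Recording:
    """Average reference, zero-phase Butterworth high-pass, 50 Hz notch.

    Filtering is forward-backward (zero phase, effective order doubled)
    so press-locked windows are not shifted by group delay.  Bad channels
    are either dropped (source analyses) or replaced by the average of
    their three nearest montage neighbours (scalp analyses).
    """
    if recording.sfreq <= 120:
        raise ValueError("sampling rate must exceed 120 Hz")
    data = recording.data.copy()
    names = list(recording.ch_names)
    bad_idx = [names.index(b) for b in bad_channels]
    good = [i for i in range(len(names)) if i not in bad_idx]
    if not good:
        raise ValueError("all channels marked bad")

    if bad_idx:
        if bad_policy == "drop":
            data = data[good]
            names = [names[i] for i in good]
        elif bad_policy == "interpolate":
            if montage is None:
                raise ValueError("interpolation requires a montage")
            pos = montage.positions
            for b in bad_idx:
                d = np.linalg.norm(pos[good] - pos[b], axis=1)
                nn = np.array(good)[np.argsort(d)[:3]]
                data[b] = data[nn].mean(axis=0)
        else:
            raise ValueError("bad_policy must be 'drop' or 'interpolate'")

    data = data - data.mean(axis=0, keepdims=True)          # average reference
    sos = signal.butter(order, highpass, btype="highpass",
                        fs=recording.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=-1)
    b, a = signal.iirnotch(line_freq, Q=30.0, fs=recording.sfreq)
    data = signal.filtfilt(b, a, data, axis=-1)
    return Recording(data=data, sfreq=recording.sfreq, ch_names=names,
                     meta=dict(recording.meta))


def _slide_table(recordings, percept_rows, posterior, cfg: Config) -> pd.DataFrame:
    """Per-percept log alpha on the common early-window grid (NaN when the
    percept is shorter than a window's end)."""
    n_win = int(np.floor((cfg.slide_horizon - cfg.slide_width)
                         / cfg.slide_step + 1e-9)) + 1
    centres = [round(cfg.slide_width / 2 + k * cfg.slide_step, 6)
               for k in range(n_win)]
    rows = []
    for rec, pers in zip(recordings, percept_rows):
        for _, row in pers.iterrows():
            horizon = min(cfg.slide_horizon, row["duration"])
            series = sliding_band_power(
                rec, row["onset"], posterior, cfg.slide_width,
                cfg.slide_step, horizon, (cfg.band_lo, cfg.band_hi))
            vals = dict.fromkeys(centres, np.nan)
            for _, w in series.iterrows():
                key = round(w["centre"], 6)
                if key in vals:
                    vals[key] = w["log_power"]
            rows.append(vals)
    return pd.DataFrame(rows, columns=centres)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Config, seed: int, outdir: str | Path,
                 simulate: bool = True) -> dict:
    """Execute every analysis stage on simulated data and write a manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    Recordings are generated, preprocessed, and analysed one session at a
    time to bound memory.  The beamformer stage runs only when
    ``config.sources`` is true; otherwise the manifest notes the skip.
    """
    if not simulate:
        raise NotImplementedError(
            "only the simulate path is orchestrated; use the library API for user data")
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = replace(config.sim, seed=seed)
    montage = default_montage(config.n_channels)

    table = gen_percept_table(params)
    events = events_from_percepts(table)
    percepts = build_percepts(events, config.duration_min, config.duration_max)
    # carry the latent alpha over for diagnostics
    percepts = percepts.merge(
        table[["percept_id", "log_alpha_true"]], on="percept_id", how="left")

    power_rows, slide_recs, slide_pers, tc_pairs = [], [], [], []
    tfr_res = None
    source_stage: dict = {"run": False, "note": "no leadfield configured; stage skipped"}
    posterior = montage.posterior_set
    session_keys = list(percepts.groupby(["subject", "day", "session"], sort=False).groups)

    zmaps = []
    for key in session_keys:
        sel = (percepts[["subject", "day", "session"]] == key).all(axis=1)
        sess_percepts = percepts.loc[sel]
        raw, _ = gen_recording(table.loc[
            (table[["subject", "day", "session"]] == key).all(axis=1)],
            montage, params)
        rec = preprocess(raw, config.highpass, config.line_freq)
        pw = power_table(rec, sess_percepts, posterior,
                         (config.band_lo, config.band_hi),
                         width=config.welch_width, step=config.welch_step,
                         guard_pre=config.guard_pre, guard_post=config.guard_post)
        power_rows.append(pw)
        slide_recs.append(rec)
        slide_pers.append(sess_percepts.loc[sess_percepts["included"]])
        tc_pairs.append((rec, sess_percepts))
        if tfr_res is None:
            presses = sess_percepts["onset"].to_numpy()[1:]
            if len(presses):
                tfr_res = tfr_around_press(
                    rec, presses, posterior, config.tfr_fmin, config.tfr_fmax,
                    n_cycles=config.tfr_cycles)
        if config.sources:
            from .beamformer import make_filters, source_power_table
            from .percepts import stable_windows
            from .spectral import multitaper_csd

            leadfield = gen_toy_leadfield(config.n_voxels, montage,
                                          config.grid_spacing, seed=seed)
            included = sess_percepts.loc[sess_percepts["included"]]
            epoch_csds = {
                row["percept_id"]: percept_csd(
                    rec, row, config.csd_centre, config.csd_smoothing,
                    config.welch_width, config.welch_step,
                    config.guard_pre, config.guard_post)
                for _, row in included.iterrows()
            }
            usable = {k: v for k, v in epoch_csds.items() if v is not None}
            all_segs = [
                rec.extract(st, config.welch_width)
                for _, row in included.iterrows()
                for st in stable_windows(row["onset"], row["duration"],
                                         config.welch_width, config.welch_step,
                                         config.guard_pre, config.guard_post)
            ]
            if usable and all_segs:
                session_csd = multitaper_csd(
                    np.stack(all_segs), rec.sfreq,
                    config.csd_centre, config.csd_smoothing)
                filters = make_filters(session_csd, leadfield, config.bf_lambda)
                st_tab = source_power_table(filters, usable)
                df = included.copy()
                df["log_duration"] = np.log(df["duration"])
                zmaps.append((st_tab, df))

    power = pd.concat(power_rows, ignore_index=True)
    power["log_duration"] = np.log(power["duration"])
    write_table(percepts.drop(columns=["log_alpha_true"]), outdir / "percepts.tsv")
    write_table(events, outdir / "events.tsv")
    write_table(power, outdir / "power.tsv")

    summary = duration_summary(percepts)
    returns = return_fraction(percepts)

    ns_power = power.loc[power["condition"] == "NS"]
    regress = fit_lmem(ns_power, "log_duration", ["log_alpha"])

    slide_pw = _slide_table(slide_recs, slide_pers, posterior, config)
    slide_meta = pd.concat(slide_pers, ignore_index=True)
    slide_meta["log_duration"] = np.log(slide_meta["duration"])
    slide = sliding_prediction(slide_pw, slide_meta, min_n=config.slide_min_n)
    write_table(slide, outdir / "slide.tsv")

    timecourse = alpha_timecourse(
        tc_pairs, posterior, config.timecourse_horizon,
        baseline=config.baseline_rule)
    write_table(timecourse, outdir / "timecourse.tsv")

    ns = percepts.loc[percepts["included"] & (percepts["condition"] == "NS"),
                      "duration"].to_numpy()
    sd = percepts.loc[percepts["included"] & (percepts["condition"] == "SD"),
                      "duration"].to_numpy()
    ks_res = {"D": np.nan, "p": np.nan}
    med_res = None
    if len(ns) and len(sd):
        d, p = ks_two_sample(ns, sd)
        ks_res = {"D": d, "p": p}
        med = mediate(power)
        med_res = {k: v for k, v in asdict(med).items()}

    if config.sources and zmaps:
        from .beamformer import voxel_zmap
        st = pd.concat([s for s, _ in zmaps])
        meta = pd.concat([m for _, m in zmaps], ignore_index=True)
        zmap = voxel_zmap(st, meta, threshold=config.bf_threshold)
        write_table(zmap, outdir / "zmap.tsv")
        source_stage = {
            "run": True,
            "n_voxels": int(len(zmap)),
            "n_masked": int(zmap["masked"].sum()),
            "max_z": float(np.nanmax(zmap["z"])),
        }

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {**{k: v for k, v in asdict(config).items() if k != "sim"},
                   "sim": asdict(config.sim)},
        "n_percepts": int(len(percepts)),
        "n_included": int(percepts["included"].sum()),
        "duration_mean": summary["mean"],
        "duration_median": summary["median"],
        "return_fraction": returns["frac_of_defined"],
        "alpha_regression": {
            "estimate": regress.estimate, "se": regress.se,
            "z": regress.wald_z, "p": regress.p, "n": regress.n_obs,
            "r2": regress.r2, "converged": regress.converged,
        },
        "sliding": slide.drop(columns=["skipped"]).to_dict("records"),
        "tfr": None if tfr_res is None else {
            "n_presses": tfr_res.n_used,
            "alpha_dip_time": float(tfr_res.times[int(np.argmin(
                tfr_res.power[(tfr_res.freqs >= 7) & (tfr_res.freqs <= 11)]
                .mean(axis=0)))]),
        },
        "ks": ks_res,
        "mediation": med_res,
        "sources": source_stage,
        "outputs": {p.name: _hash_file(p) for p in sorted(outdir.glob("*.tsv"))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    return manifest
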