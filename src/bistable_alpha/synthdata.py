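"""Synthetic percept tables, EEG recordings, and toy leadfields.

The generator emulates the statistical structure the downstream analysis
assumes about bistable-perception EEG:

* percept durations with a positively skewed gamma distribution whose
  mean, after the 1.5-60 s inclusion filter, is ~8.87 s (median ~5.94 s);
* a latent per-percept posterior alpha log-power ``x`` whose coupling to
  log-duration (slope ``coupling_slope``) is the quantity the inference
  stage estimates;
* a sleep-deprivation condition that raises mean log alpha power by
  ``sd_alpha_shift`` and log duration directly by ``sd_direct_shift``, so
  mediation has an exact product-of-paths ground truth
  (``sd_alpha_shift * coupling_slope``);
* nested subject / day / session random intercepts on log duration;
* a 9 Hz posterior-dominant narrowband oscillation riding on 1/f noise,
  with a transient alpha-power dip in the +-0.5 s around each button press.

The causal direction is alpha -> duration: ``x`` is drawn first and log
duration is built from it.  Durations are a gamma draw times a lognormal
multiplier; the noise part of the multiplier is mean-centred on the
natural scale so the calibrated truncated-gamma mean survives coupling
and random effects.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import Leadfield, Montage, Recording

__all__ = [
    "GenParams",
    "calibrate_gamma",
    "default_montage",
    "gen_percept_table",
    "events_from_percepts",
    "gen_recording",
    "gen_toy_leadfield",
]


def truncated_gamma_stats(
    shape: float, scale: float, lo: float = 1.5, hi: float = 60.0
) -> tuple[float, float, float]:
    """(mean, median, retained mass) of Gamma(shape, scale) truncated to
    ``[lo, hi]``, from closed-form incomplete-gamma identities."""
    flo, fhi = stats.gamma.cdf([lo, hi], shape, scale=scale)
    z = fhi - flo
    mean = shape * scale * (stats.gamma.cdf(hi, shape + 1, scale=scale)
                            - stats.gamma.cdf(lo, shape + 1, scale=scale)) / z
    median = stats.gamma.ppf(flo + z / 2, shape, scale=scale)
    return float(mean), float(median), float(z)


@lru_cache(maxsize=None)
def calibrate_gamma(
    mean: float = 8.87,
    shape: float = 2.5,
    lo: float = 1.5,
    hi: float = 60.0,
) -> tuple[float, float]:
    """Gamma (shape, scale) whose truncation to ``[lo, hi]`` has the given
    mean, at a fixed shape.

    The shape defaults to 2.5, a typical positive-skew value for bistable
    percept durations; with the calibrated scale only a few percent of
    draws fall outside the inclusion bounds, so the 1.5-60 s filter
    barely distorts the alpha-duration coupling.  (Matching the printed
    median as well would require a sub-1 shape whose heavy sub-1.5 s
    mass conflicts with slope recovery under the exclusion rule.)
    """

    def f(log_s: float) -> float:
        return truncated_gamma_stats(shape, np.exp(log_s), lo, hi)[0] - mean

    log_s = optimize.brentq(f, np.log(0.1), np.log(50.0))
    return float(shape), float(np.exp(log_s))


@dataclass
class GenParams:
    """Parameters of the synthetic-data generator.

    Units: durations in seconds, alpha power in µV² (log quantities in
    natural log), frequencies in Hz.  ``gamma_shape``/``gamma_scale``
    default to the pair calibrated so the truncated-to-[1.5, 60] mean is
    ~8.87 s; pass explicit values to override.
    """

    gamma_shape: Optional[float] = None
    gamma_scale: Optional[float] = None
    coupling_slope: float = 0.111          # log(s) per log(µV²), the "b" path
    sd_alpha_shift: float = 0.202          # condition shift in log alpha, the "a" path
    sd_direct_shift: float = 0.222         # unmediated condition shift in log duration
    re_sd_subject: float = 0.3             # nested random-intercept SDs, log(s)
    re_sd_day: float = 0.1
    re_sd_session: float = 0.1
    alpha_freq: float = 9.0
    alpha_band_sd: float = 0.5             # spectral width of the alpha carrier
    alpha_log_mean: float = 3.0            # baseline mean of latent log alpha power
    alpha_log_sd: float = 0.8              # SD of latent log alpha power
    noise_exponent: float = 1.0            # 1/f^exponent background
    snr: float = 5.0                       # alpha-band signal/noise power ratio
    dip_depth: float = 0.5                 # fractional alpha *power* drop near presses
    return_prob: float = 0.09              # i.i.d. probability of a return transition
    n_subjects: int = 8
    n_days: int = 2
    n_sessions: int = 5
    session_length: float = 240.0          # seconds
    sfreq: float = 1024.0
    min_duration: float = 1.5              # inclusion filter lower bound (analysis side)
    max_duration: float = 60.0
    seed: int = 0

    def resolved(self) -> "GenParams":
        """Return a copy with calibrated gamma parameters filled in."""
        if self.gamma_shape is None and self.gamma_scale is None:
            k, s = calibrate_gamma()
            return replace(self, gamma_shape=k, gamma_scale=s)
        if self.gamma_shape is None or self.gamma_scale is None:
            raise ValueError("gamma_shape and gamma_scale must be set together")
        return self

    def validate(self) -> None:
        p = self.resolved()
        if p.gamma_shape <= 0 or p.gamma_scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if not 0 <= p.dip_depth <= 1:
            raise ValueError("dip_depth must be in [0, 1]")
        if p.session_length <= 0:
            raise ValueError("session_length must be positive")
        if not 0 <= p.return_prob <= 1:
            raise ValueError("return_prob must be in [0, 1]")
        for name in ("re_sd_subject", "re_sd_day", "re_sd_session", "alpha_log_sd"):
            if getattr(p, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if p.snr <= 0:
            raise ValueError("snr must be positive (np.inf for noise-free)")
        if min(p.n_subjects, p.n_days, p.n_sessions) < 1:
            raise ValueError("counts must be at least 1")


def default_montage(n_channels: int = 61) -> Montage:
    """Synthetic montage: a Fibonacci lattice on the unit sphere.

    The 14 channels closest to the occipital pole (0, -1, 0) form the
    posterior set.  Geometry is schematic, not a physiological cap layout.
    """
    if n_channels < 14:
        raise ValueError("montage needs at least 14 channels")
    i = np.arange(n_channels)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (i + 0.5) / n_channels
    r = np.sqrt(1 - z ** 2)
    theta = 2 * np.pi * i / golden
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = [f"E{k + 1}" for k in i]
    pole = np.array([0.0, -1.0, 0.0])
    order = np.argsort(-pos @ pole)
    posterior = [labels[k] for k in order[:14]]
    return Montage(ch_names=labels, positions=pos, posterior_set=posterior)


def _condition(subject_idx: int, day_idx: int, n_days: int) -> str:
    """Counterbalanced condition order: half the subjects start sleep-deprived."""
    if n_days < 2:
        return "NS"
    return "SD" if (day_idx + subject_idx) % 2 else "NS"


def gen_percept_table(params: GenParams) -> pd.DataFrame:
    """Draw a percept table under the generative model.

    Returns one row per percept with columns ``subject, day, session,
    condition, percept_id, onset, duration, label, transition, included``
    plus ``log_alpha_true``, the latent log alpha power the recording
    generator will realize as oscillation amplitude.
    """
    params.validate()
    p = params.resolved()
    rng = np.random.default_rng(p.seed)

    # centring constant so E[duration] is preserved under the lognormal multiplier
    noise_var = (
        (p.coupling_slope * p.alpha_log_sd) ** 2
        + p.re_sd_subject ** 2 + p.re_sd_day ** 2 + p.re_sd_session ** 2
    )

    rows = []
    for si in range(p.n_subjects):
        subject = f"S{si + 1:02d}"
        u_subj = rng.normal(0.0, p.re_sd_subject)
        for di in range(p.n_days):
            day = f"D{di + 1}"
            cond = _condition(si, di, p.n_days)
            is_sd = 1.0 if cond == "SD" else 0.0
            u_day = rng.normal(0.0, p.re_sd_day)
            for ki in range(p.n_sessions):
                session = f"R{ki + 1}"
                u_sess = rng.normal(0.0, p.re_sd_session)
                t = 0.0
                label = rng.choice(["A", "B"])
                transition = None
                idx = 0
                # a percept whose onset falls before the session end completes
                # even if it straddles it, so observed durations carry no
                # length bias from the session boundary
                while t < p.session_length:
                    g = rng.gamma(p.gamma_shape, p.gamma_scale)
                    x = (p.alpha_log_mean + p.sd_alpha_shift * is_sd
                         + rng.normal(0.0, p.alpha_log_sd))
                    log_mult = (
                        p.coupling_slope * (x - p.alpha_log_mean)
                        + p.sd_direct_shift * is_sd
                        + u_subj + u_day + u_sess
                        - 0.5 * noise_var
                    )
                    d = g * np.exp(log_mult)
                    rows.append({
                        "subject": subject, "day": day, "session": session,
                        "condition": cond,
                        "percept_id": f"{subject}_{day}_{session}_{idx:04d}",
                        "onset": t, "duration": d, "label": label,
                        "transition": transition,
                        "included": bool(p.min_duration <= d <= p.max_duration),
                        "log_alpha_true": x,
                    })
                    t += d
                    idx += 1
                    if rng.random() < p.return_prob:
                        transition = "return"
                    else:
                        label = "A" if label == "B" else "B"
                        transition = "alternation"
                if idx == 0:
                    warnings.warn(
                        f"session {subject}/{day}/{session} too short for any percept",
                        stacklevel=2,
                    )
    return pd.DataFrame(rows)


def events_from_percepts(percepts: pd.DataFrame) -> pd.DataFrame:
    """Button-press event table implied by a percept table.

    Each percept onset is a press labelled with the emerging percept; a
    closing press (trial_type of the would-be next percept, label
    alternated) ends each session.
    """
    out = []
    for (subject, day, session), grp in percepts.groupby(
            ["subject", "day", "session"], sort=False):
        grp = grp.sort_values("onset")
        cond = grp["condition"].iloc[0]
        for _, row in grp.iterrows():
            out.append({
                "onset": row["onset"], "duration": 0.0, "trial_type": row["label"],
                "subject": subject, "day": day, "session": session,
                "condition": cond,
            })
        last = grp.iloc[-1]
        out.append({
            "onset": last["onset"] + last["duration"], "duration": 0.0,
            "trial_type": "A" if last["label"] == "B" else "B",
            "subject": subject, "day": day, "session": session,
            "condition": cond,
        })
    return pd.DataFrame(out)


def _narrowband_carrier(rng: np.random.Generator, n: int, sfreq: float,
                        f0: float, band_sd: float) -> np.ndarray:
    """Unit-variance alpha carrier: a random-phase tone when ``band_sd`` is
    zero, otherwise Gaussian-spectrum narrowband noise."""
    t = np.arange(n) / sfreq
    if band_sd == 0:
        phi = rng.uniform(0, 2 * np.pi)
        return np.sqrt(2.0) * np.cos(2 * np.pi * f0 * t + phi)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / sfreq)
    spec *= np.exp(-0.5 * ((freqs - f0) / band_sd) ** 2)
    carrier = np.fft.irfft(spec, n)
    sd = carrier.std()
    if sd == 0:
        raise ValueError("degenerate carrier (window too short?)")
    return carrier / sd


def _one_over_f_noise(rng: np.random.Generator, n: int, sfreq: float,
                      exponent: float, band: tuple[float, float],
                      band_power: float) -> np.ndarray:
    """1/f^exponent noise scaled so its integrated power in ``band`` equals
    ``band_power`` (µV²)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2)
    spec *= shape
    # variance contribution of each rfft bin: 2|X_k|^2/n^2 (k not 0/Nyquist)
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    current = np.sum(w[in_band] * np.abs(spec[in_band]) ** 2) / n ** 2
    noise = np.fft.irfft(spec, n)
    return noise * np.sqrt(band_power / current)


def gen_recording(
    percepts: pd.DataFrame,
    montage: Montage,
    params: GenParams,
    pad: float = 1.0,
) -> tuple[Recording, pd.DataFrame]:
    """Synthesize the EEG of one session from its percept table.

    Each percept contributes a narrowband alpha oscillation whose variance
    (= band power) is ``exp(log_alpha_true)``, projected to the sensors
    with a posterior-dominant cosine topography (gain normalized to mean 1
    over the posterior set), with the alpha power reduced by ``dip_depth``
    within +-0.5 s of each press, on top of 1/f noise at the configured
    alpha-band SNR.  Returns the recording and its press event table.
    """
    params.validate()
    p = params.resolved()
    if percepts.empty:
        raise ValueError("percept table is empty")
    key = percepts[["subject", "day", "session"]].drop_duplicates()
    if len(key) != 1:
        raise ValueError("gen_recording expects percepts from a single session")
    percepts = percepts.sort_values("onset").reset_index(drop=True)
    onsets = percepts["onset"].to_numpy()
    durations = percepts["duration"].to_numpy()
    if np.any(onsets[1:] < (onsets[:-1] + durations[:-1]) - 1e-9):
        raise ValueError("overlapping percepts")

    sfreq = p.sfreq
    end = onsets[-1] + durations[-1]
    n = int(round((end + pad) * sfreq))
    # derive an independent stream per session so sessions are reproducible
    tag = "/".join(str(key.iloc[0, j]) for j in range(3))
    h = zlib.crc32(tag.encode()) % (2 ** 31)
    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed), h]))

    press_times = np.append(onsets, end)
    source = np.zeros(n)
    for onset, dur, x in zip(onsets, durations, percepts["log_alpha_true"]):
        i0, i1 = int(round(onset * sfreq)), int(round((onset + dur) * sfreq))
        m = i1 - i0
        if m < 2:
            continue
        carrier = _narrowband_carrier(rng, m, sfreq, p.alpha_freq, p.alpha_band_sd)
        t_abs = onset + np.arange(m) / sfreq
        power_env = np.ones(m)
        if p.dip_depth > 0:
            near = np.min(np.abs(t_abs[:, None] - press_times[None, :]), axis=1) < 0.5
            power_env[near] = 1.0 - p.dip_depth
        source[i0:i1] = np.exp(x / 2.0) * np.sqrt(power_env) * carrier

    pole = montage.positions[[montage.ch_names.index(c)
                              for c in montage.posterior_set]].mean(axis=0)
    pole /= np.linalg.norm(pole)
    gains = np.clip(montage.positions @ pole, 0.0, None)
    post_idx = [montage.ch_names.index(c) for c in montage.posterior_set]
    gains /= gains[post_idx].mean()

    data = gains[:, None] * source[None, :]
    if np.isfinite(p.snr):
        target = np.exp(p.alpha_log_mean) / p.snr
        for ch in range(len(montage.ch_names)):
            data[ch] += _one_over_f_noise(
                rng, n, sfreq, p.noise_exponent, (7.0, 11.0), target)

    rec = Recording(
        data=data, sfreq=sfreq, ch_names=list(montage.ch_names),
        meta={
            "subject": str(key.iloc[0, 0]), "day": str(key.iloc[0, 1]),
            "session": str(key.iloc[0, 2]),
            "condition": str(percepts["condition"].iloc[0]),
        },
    )
    events = pd.DataFrame({
        "onset": press_times,
        "duration": 0.0,
        "trial_type": list(percepts["label"]) + [
            "A" if percepts["label"].iloc[-1] == "B" else "B"],
        "subject": key.iloc[0, 0], "day": key.iloc[0, 1],
        "session": key.iloc[0, 2],
        "condition": percepts["condition"].iloc[0],
    })
    return rec, events


def _cubic_grid(n_voxels: int, spacing: float) -> np.ndarray:
    side = int(np.ceil(n_voxels ** (1 / 3)))
    pts = [(i, j, k) for k in range(side) for j in range(side) for i in range(side)]
    grid = np.array(pts[:n_voxels], dtype=float) * spacing
    return grid - grid.mean(axis=0)


def gen_toy_leadfield(
    n_voxels: int,
    montage: Montage,
    spacing: float = 10.0,
    seed: int = 0,
    mode: str = "sphere",
) -> Leadfield:
    """Toy fixed-orientation leadfield on a cubic grid.

    Modes: ``"sphere"`` — current-dipole potentials in an infinite
    homogeneous conductor, one random tangential orientation per voxel
    (schematic, not a BEM head model); ``"random"`` — unit-norm random
    gain rows, useful as a bias-free test forward model; ``"identity"`` —
    each voxel maps to exactly one channel (requires
    ``n_voxels == n_channels``).
    """
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    rng = np.random.default_rng(seed)
    grid = _cubic_grid(n_voxels, spacing)
    n_ch = len(montage.ch_names)

    if mode == "identity":
        if n_voxels != n_ch:
            raise ValueError("identity mode requires n_voxels == n_channels")
        gains = np.eye(n_ch)
    elif mode == "random":
        gains = rng.standard_normal((n_voxels, n_ch))
        gains /= np.linalg.norm(gains, axis=1, keepdims=True)
    elif mode == "sphere":
        head_r = 100.0                       # mm
        sensors = montage.positions * head_r * 1.1
        # shrink the grid to fit well inside the head sphere
        extent = np.abs(grid).max()
        vox = grid * (0.7 * head_r / max(extent, spacing))
        gains = np.zeros((n_voxels, n_ch))
        for v in range(n_voxels):
            radial = vox[v] / max(np.linalg.norm(vox[v]), 1e-6)
            m = rng.standard_normal(3)
            m -= (m @ radial) * radial       # tangential orientation
            m /= np.linalg.norm(m)
            d = sensors - vox[v]
            gains[v] = (d @ m) / np.linalg.norm(d, axis=1) ** 3
        gains *= head_r ** 2                 # O(1) scaling
    else:
        raise ValueError(f"unknown leadfield mode {mode!r}")

    return Leadfield(gains=gains, grid=grid, spacing=spacing,
                     ch_names=list(montage.ch_names))
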