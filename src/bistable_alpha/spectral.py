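"""Sensor-level spectral estimation.

Welch PSDs on 1 s Hanning windows, 7-11 Hz band power per percept,
500 ms sliding-window power after percept onset, 5-cycle Hanning
time-frequency decomposition around reversals, DPSS multitaper
cross-spectral density at 9 +- 2 Hz, and the baseline-corrected
pre-reversal alpha time course.

Conventions: all log transforms are natural log; band integration
includes every FFT bin whose centre frequency lies in [lo, hi]
inclusive; spectra are one-sided densities in µV²/Hz so that the
integral over frequency equals the signal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import Recording
from .percepts import stable_windows

ALPHA_BAND = (7.0, 11.0)


@dataclass
class PSD:
    freqs: np.ndarray      # Hz, ascending
    power: np.ndarray      # (..., n_freqs) µV²/Hz
    n_windows: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class TFR:
    times: np.ndarray      # s relative to the press
    freqs: np.ndarray      # Hz
    power: np.ndarray      # (n_freqs, n_times) µV²/Hz, averaged over presses/channels
    n_used: int
    n_skipped: int


@dataclass
class CSDMatrix:
    matrix: np.ndarray     # complex Hermitian (n_ch, n_ch), integrated band power
    centre: float
    smoothing: float
    ch_names: list[str] | None = None
    n_segments: int = 0
    n_tapers: int = 0

    def check(self, atol: float = 1e-8) -> None:
        """Assert Hermitian symmetry and positive semi-definiteness."""
        m = self.matrix
        if not np.allclose(m, m.conj().T, atol=atol):
            raise AssertionError("CSD is not Hermitian")
        w = np.linalg.eigvalsh(m)
        if w.min() < -atol * max(w.max(), 1.0):
            raise AssertionError(f"CSD not PSD: min eigenvalue {w.min():.3g}")


def welch_psd(windows: np.ndarray, fs: float) -> PSD:
    """Average Hanning-tapered periodograms over pre-cut windows.

    ``windows`` has shape (n_windows, n_samples) or
    (n_windows, n_channels, n_samples).  Each window is mean-detrended
    and tapered; the density normalization corrects for taper power so
    the integrated density estimates the signal variance.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.shape[0] < 1:
        raise ValueError("need at least one window")
    if windows.shape[-1] < 2:
        raise ValueError("windows must have at least 2 samples")
    freqs, p = signal.periodogram(
        windows, fs=fs, window="hann", detrend="constant", axis=-1)
    return PSD(freqs=freqs, power=p.mean(axis=0), n_windows=windows.shape[0])


def band_power(psd: PSD, lo: float = ALPHA_BAND[0], hi: float = ALPHA_BAND[1]) -> np.ndarray:
    """Integrated power (µV²) over bins with centre frequency in [lo, hi]."""
    if lo >= hi:
        raise ValueError("band lo must be below hi")
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not sel.any():
        raise ValueError(f"no frequency bins in [{lo}, {hi}] Hz")
    return psd.power[..., sel].sum(axis=-1) * psd.df


def percept_alpha_power(
    recording: Recording,
    percept: pd.Series,
    posterior_set: list[str],
    band: tuple[float, float] = ALPHA_BAND,
    width: float = 1.0,
    step: float = 0.5,
    guard_pre: float = 1.0,
    guard_post: float = 1.0,
) -> float:
    """Natural-log alpha power of one percept's stable interval.

    Welch PSD over the 1 s / 50%-overlap windows from 1 s after the
    opening press to at least 1 s before the closing press, integrated
    over ``band`` and averaged over the posterior channels.  Returns NaN
    when no window fits (percept shorter than ~3 s with default guards).
    """
    starts = stable_windows(percept["onset"], percept["duration"],
                            width, step, guard_pre, guard_post)
    if len(starts) == 0:
        return np.nan
    wins = np.stack([recording.extract(s, width, posterior_set) for s in starts])
    psd = welch_psd(wins, recording.sfreq)
    return float(np.log(band_power(psd, *band).mean()))


def power_table(
    recording: Recording,
    percepts: pd.DataFrame,
    posterior_set: list[str],
    band: tuple[float, float] = ALPHA_BAND,
    **kwargs,
) -> pd.DataFrame:
    """Per-percept log alpha power for all included percepts of a session.

    Returns the percept rows with a ``log_alpha`` column; percepts with
    no usable window get NaN (reported by the caller, dropped by the
    regression stage).
    """
    out = percepts.loc[percepts["included"]].copy()
    out["log_alpha"] = [
        percept_alpha_power(recording, row, posterior_set, band, **kwargs)
        for _, row in out.iterrows()
    ]
    return out


def sliding_band_power(
    recording: Recording,
    onset: float,
    posterior_set: list[str],
    width: float = 0.5,
    step: float = 0.05,
    horizon: float = 1.0,
    band: tuple[float, float] = ALPHA_BAND,
) -> pd.DataFrame:
    """Log alpha power on short forward-sliding windows from ``onset``.

    Windows lie fully inside ``[onset, onset + horizon]``; timestamps are
    window centres (the first at onset + width/2).  Returns an empty
    frame when the horizon is shorter than one window.
    """
    if horizon < width:
        return pd.DataFrame(columns=["centre", "log_power"])
    n = int(np.floor((horizon - width) / step + 1e-9)) + 1
    rows = []
    for k in range(n):
        start = onset + k * step
        win = recording.extract(start, width, posterior_set)
        psd = welch_psd(win[None], recording.sfreq)
        rows.append({
            "centre": start + width / 2 - onset,
            "log_power": float(np.log(band_power(psd, *band).mean())),
        })
    return pd.DataFrame(rows)


def tfr_window_length(freq: float, n_cycles: int = 5) -> float:
    """Length in seconds of the fixed-cycle analysis window at ``freq``."""
    return n_cycles / freq


def tfr_around_press(
    recording: Recording,
    press_times: np.ndarray,
    ch_names: list[str] | None = None,
    fmin: float = 4.0,
    fmax: float = 30.0,
    fstep: float = 1.0,
    tmin: float = -1.0,
    tmax: float = 1.0,
    tstep: float = 0.05,
    n_cycles: int = 5,
) -> TFR:
    """Reversal-locked time-frequency power.

    At each frequency f the window is ``n_cycles / f`` seconds (1250 ms at
    4 Hz, ~167 ms at 30 Hz), Hanning-tapered, centred on each time point
    in [tmin, tmax] around the press.  Presses too close to the recording
    edge are skipped and counted.  Power is a one-sided density averaged
    over presses and channels.
    """
    fs = recording.sfreq
    freqs = np.arange(fmin, fmax + fstep / 2, fstep)
    times = np.round(np.arange(tmin, tmax + tstep / 2, tstep), 9)
    if ch_names is None:
        ch_names = recording.ch_names
    ch_idx = recording.channel_indices(ch_names)

    half_max = tfr_window_length(freqs.min(), n_cycles) / 2
    usable = [t for t in np.atleast_1d(press_times)
              if t + tmin - half_max >= 0
              and t + tmax + half_max <= recording.duration]
    n_skipped = len(np.atleast_1d(press_times)) - len(usable)
    if not usable:
        raise ValueError("no press has enough surrounding data for the TFR")

    kernels = []
    for f in freqs:
        m = int(np.floor(tfr_window_length(f, n_cycles) * fs + 0.5))
        taper = np.hanning(m)
        t_rel = (np.arange(m) - (m - 1) / 2) / fs
        k = taper * np.exp(-2j * np.pi * f * t_rel)
        kernels.append((m, k, taper @ taper))

    power = np.zeros((len(freqs), len(times)))
    for press in usable:
        for fi, (m, kern, u) in enumerate(kernels):
            for ti, t in enumerate(times):
                i0 = int(np.floor((press + t) * fs + 0.5)) - m // 2
                seg = recording.data[ch_idx, i0:i0 + m]
                seg = seg - seg.mean(axis=-1, keepdims=True)
                amp = seg @ kern.conj()
                power[fi, ti] += np.mean(np.abs(amp) ** 2) * 2 / (fs * u)
    power /= len(usable)
    return TFR(times=times, freqs=freqs, power=power,
               n_used=len(usable), n_skipped=n_skipped)


def multitaper_csd(
    segments: np.ndarray,
    fs: float,
    centre: float = 9.0,
    smoothing: float = 2.0,
    ch_names: list[str] | None = None,
) -> CSDMatrix:
    """DPSS multitaper cross-spectral density, integrated over the band.

    ``segments`` has shape (n_segments, n_channels, n_samples).  The
    number of Slepian tapers is floor(2*T*W) - 1 with T the segment
    length and W the half-bandwidth ``smoothing``; cross-spectra are
    averaged over tapers and segments and summed (x df) over the bins in
    [centre - smoothing, centre + smoothing], so the diagonal is the
    integrated band power in µV² per channel.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 3:
        raise ValueError("segments must be (n_segments, n_channels, n_samples)")
    n_seg, n_ch, n_samp = segments.shape
    if n_seg < 1:
        raise ValueError("need at least one segment")
    t_len = n_samp / fs
    n_tapers = int(np.floor(2 * t_len * smoothing)) - 1
    if n_tapers < 1:
        raise ValueError(
            f"smoothing {smoothing} Hz too small for {t_len:.3f} s segments; "
            f"need at least {1.0 / t_len:.3f} Hz")
    tapers = signal.windows.dpss(n_samp, t_len * smoothing, Kmax=n_tapers)

    freqs = np.fft.rfftfreq(n_samp, 1 / fs)
    sel = (freqs >= centre - smoothing) & (freqs <= centre + smoothing)
    df = freqs[1] - freqs[0]
    segments = segments - segments.mean(axis=-1, keepdims=True)

    csd = np.zeros((n_ch, n_ch), dtype=complex)
    for taper in tapers:
        u = taper @ taper
        spec = np.fft.rfft(segments * taper, axis=-1)[..., sel]  # (seg, ch, bins)
        cross = np.einsum("sif,sjf->ij", spec, spec.conj())
        csd += cross * 2 / (fs * u)
    csd *= df / (n_seg * n_tapers)
    out = CSDMatrix(matrix=csd, centre=centre, smoothing=smoothing,
                    ch_names=ch_names, n_segments=n_seg, n_tapers=n_tapers)
    return out


def percept_csd(
    recording: Recording,
    percept: pd.Series,
    centre: float = 9.0,
    smoothing: float = 2.0,
    width: float = 1.0,
    step: float = 0.5,
    guard_pre: float = 1.0,
    guard_post: float = 1.0,
) -> CSDMatrix | None:
    """Multitaper CSD over one percept's stable-interval windows, or None
    when no window fits."""
    starts = stable_windows(percept["onset"], percept["duration"],
                            width, step, guard_pre, guard_post)
    if len(starts) == 0:
        return None
    segs = np.stack([recording.extract(s, width) for s in starts])
    return multitaper_csd(segs, recording.sfreq, centre, smoothing,
                          ch_names=recording.ch_names)


def alpha_timecourse(
    pairs,
    posterior_set: list[str],
    horizon: float = 25.0,
    width: float = 1.0,
    step: float = 0.5,
    guard: float = 1.0,
    band: tuple[float, float] = ALPHA_BAND,
    baseline: str = "first",
) -> pd.DataFrame:
    """Baseline-corrected alpha power aligned on the next reversal.

    ``pairs`` is a ``(recording, percepts)`` tuple or a list of them (one
    per session).  Each included percept is segmented into 1 s, 50%
    overlapping windows anchored at the *end* of the percept (last window
    ends 1 s before the closing press), so window midpoints fall exactly
    on the -1.5, -2.0, ... s grid relative to the reversal.  Per-percept
    log alpha is baseline-corrected by the percept's first available
    segment (``baseline="first"``) or by the 1-2 s before percept onset
    (``baseline="preonset"``); values within ``horizon`` of the reversal
    are averaged across percepts.
    """
    if baseline not in ("first", "preonset"):
        raise ValueError("baseline must be 'first' or 'preonset'")
    if isinstance(pairs, tuple):
        pairs = [pairs]

    values: dict[float, list[float]] = {}
    for recording, percepts in pairs:
        for _, row in percepts.loc[percepts["included"]].iterrows():
            onset, dur = row["onset"], row["duration"]
            usable = dur - 2 * guard
            if usable < width:
                continue
            n = int(np.floor((usable - width) / step + 1e-9)) + 1
            offset = onset + dur
            # reverse-anchored starts, earliest first
            starts = offset - guard - width - step * np.arange(n)[::-1]
            logs = []
            for s in starts:
                win = recording.extract(s, width, posterior_set)
                psd = welch_psd(win[None], recording.sfreq)
                logs.append(float(np.log(band_power(psd, *band).mean())))
            if baseline == "first":
                base = logs[0]
            else:
                if onset - 2.0 < 0:
                    continue
                win = recording.extract(onset - 2.0, width, posterior_set)
                psd = welch_psd(win[None], recording.sfreq)
                base = float(np.log(band_power(psd, *band).mean()))
            for s, v in zip(starts, logs):
                t_rev = (s + width / 2) - offset
                if t_rev >= -horizon:
                    key = round(t_rev / step) * step
                    values.setdefault(key, []).append(v - base)

    rows = []
    for t in sorted(values):
        vals = np.array(values[t])
        rows.append({
            "time_to_reversal": t,
            "mean": vals.mean(),
            "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
            "n": len(vals),
        })
    return pd.DataFrame(rows)
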