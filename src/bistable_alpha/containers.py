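"""In-memory containers and file I/O.

The package works on three plain containers:

``Recording``
    A continuous multichannel EEG segment, channels x samples, in
    microvolts, with its sampling rate and channel labels.  Recordings are
    saved in a documented NPZ container (``data``, ``sfreq``, ``ch_names``,
    ``meta`` as a JSON string); EDF files can be read when :mod:`mne` is
    installed.

``Montage``
    Channel labels with unit-sphere positions and the designated set of 14
    posterior (parietal/occipital) channels used for scalp-level alpha
    power.

``Leadfield``
    A fixed-orientation forward gain matrix (voxels x channels) on a
    uniformly spaced volumetric grid, stored as a TSV matrix plus a JSON
    header.

Event and percept tables are ordinary :class:`pandas.DataFrame` objects
with documented columns, read and written as BIDS-style TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["onset", "duration", "trial_type", "subject", "day", "session", "condition"]
PERCEPT_COLUMNS = [
    "subject", "day", "session", "condition", "percept_id",
    "onset", "duration", "label", "transition", "included",
]


@dataclass
class Recording:
    """Continuous multichannel EEG, channels x samples, in microvolts."""

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for {self.data.shape[0]} rows"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel names must be unique")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sfreq

    def channel_indices(self, names: list[str]) -> np.ndarray:
        try:
            return np.array([self.ch_names.index(n) for n in names])
        except ValueError as err:
            raise KeyError(f"channel not in recording: {err}") from None

    def extract(self, start: float, width: float, ch_names: list[str] | None = None) -> np.ndarray:
        """Return the samples in ``[start, start + width)`` seconds.

        Sample indices are obtained by rounding half-up, so a 1 s window at
        1024 Hz is always exactly 1024 samples.
        """
        i0 = int(np.floor(start * self.sfreq + 0.5))
        n = int(np.floor(width * self.sfreq + 0.5))
        if i0 < 0 or i0 + n > self.n_samples:
            raise ValueError(
                f"window [{start}, {start + width}) s outside recording of {self.duration:.3f} s"
            )
        rows = slice(None) if ch_names is None else self.channel_indices(ch_names)
        return self.data[rows, i0:i0 + n]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            data=self.data,
            sfreq=np.array(self.sfreq),
            ch_names=np.array(self.ch_names),
            meta=np.array(json.dumps(self.meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Recording":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                data=f["data"],
                sfreq=float(f["sfreq"]),
                ch_names=[str(c) for c in f["ch_names"]],
                meta=json.loads(str(f["meta"])),
            )

    @classmethod
    def from_edf(cls, path: str | Path) -> "Recording":
        """Read an EDF file (requires :mod:`mne`); data returned in µV."""
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return cls(
            data=raw.get_data() * 1e6,
            sfreq=float(raw.info["sfreq"]),
            ch_names=list(raw.ch_names),
            meta={"source": str(path)},
        )


@dataclass
class Montage:
    """Channel geometry with the 14-channel posterior subset."""

    ch_names: list[str]
    positions: np.ndarray          # (n_channels, 3) on the unit sphere
    posterior_set: list[str]       # exactly 14 labels, subset of ch_names

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (len(self.ch_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.posterior_set) != 14:
            raise ValueError("posterior_set must contain exactly 14 labels")
        missing = set(self.posterior_set) - set(self.ch_names)
        if missing:
            raise ValueError(f"posterior labels not in montage: {sorted(missing)}")


@dataclass
class Leadfield:
    """Fixed-orientation forward model on a uniform volumetric grid."""

    gains: np.ndarray      # (n_voxels, n_channels)
    grid: np.ndarray       # (n_voxels, 3) voxel coordinates, mm
    spacing: float         # grid spacing, mm
    ch_names: list[str]

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.gains.ndim == 2:
            pass                                    # fixed orientation
        elif self.gains.ndim == 3 and self.gains.shape[2] == 3:
            pass                                    # free orientation
        else:
            raise ValueError(
                "gains must be (voxels x channels) or (voxels x channels x 3)")
        if self.grid.shape != (self.gains.shape[0], 3):
            raise ValueError("grid must be (n_voxels, 3)")
        if self.gains.shape[1] != len(self.ch_names):
            raise ValueError("gain columns must match ch_names")
        if self.gains.ndim == 2:
            if np.any(np.linalg.norm(self.gains, axis=1) == 0):
                raise ValueError("rank-deficient leadfield: zero gain vector at some voxel")
        else:
            ranks = [np.linalg.matrix_rank(self.gains[v]) for v in range(self.gains.shape[0])]
            if min(ranks) < 3:
                raise ValueError("rank-deficient leadfield: voxel gain matrix below full column rank")

    @property
    def n_voxels(self) -> int:
        return self.gains.shape[0]

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.tsv`` (gain matrix) and ``<prefix>.json`` (header)."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".tsv"), self.gains, delimiter="\t")
        header = {
            "spacing_mm": self.spacing,
            "ch_names": self.ch_names,
            "grid_mm": self.grid.tolist(),
        }
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "Leadfield":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        gains = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        return cls(
            gains=gains,
            grid=np.asarray(header["grid_mm"], dtype=float),
            spacing=float(header["spacing_mm"]),
            ch_names=list(header["ch_names"]),
        )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv; requires onset and trial_type columns."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    for col in ("onset", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"events table missing required column {col!r}")
    return df


def read_percepts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = set(PERCEPT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"percept table missing columns: {sorted(missing)}")
    return df
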