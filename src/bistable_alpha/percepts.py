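"""Percept epoching: from button-press events to the per-percept table.

A percept's duration is the interval between two subsequent button
presses; the last press of a session opens no percept.  Percepts shorter
than 1.5 s or longer than 60 s are flagged as excluded (the bounds
themselves are kept).  A reversal whose new label equals the previous
percept's label is a *return* transition, otherwise an *alternation*;
the first percept of a session has no defined transition.

All times are seconds from recording start; analysis windows are
half-open ``[start, start + width)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MIN = 1.5
DEFAULT_MAX = 60.0


def build_percepts(
    events: pd.DataFrame,
    min_duration: float = DEFAULT_MIN,
    max_duration: float = DEFAULT_MAX,
) -> pd.DataFrame:
    """Turn a press event table into the percept table.

    ``events`` needs columns ``onset`` and ``trial_type`` (two distinct
    labels); grouping columns ``subject``, ``day``, ``session``,
    ``condition`` are carried through when present.
    """
    events = events.copy()
    group_cols = [c for c in ("subject", "day", "session") if c in events.columns]
    if not group_cols:
        events["session"] = "R1"
        group_cols = ["session"]

    labels = set(events["trial_type"].astype(str))
    if len(labels) > 2:
        raise ValueError(f"expected at most two percept labels, got {sorted(labels)}")

    rows = []
    for key, grp in events.groupby(group_cols, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        onsets = grp["onset"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) < 0):
            raise ValueError(f"event onsets not sorted in session {key}")
        if len(grp) < 2:
            continue
        lab = grp["trial_type"].astype(str).to_numpy()
        cond = grp["condition"].iloc[0] if "condition" in grp.columns else "NS"
        prev_label = None
        for i in range(len(grp) - 1):
            dur = onsets[i + 1] - onsets[i]
            if dur <= 0:
                raise ValueError(f"non-positive percept duration at onset {onsets[i]}")
            if prev_label is None:
                transition = None
            else:
                transition = "return" if lab[i] == prev_label else "alternation"
            row = dict(zip(group_cols, key))
            row.setdefault("subject", "S01")
            row.setdefault("day", "D1")
            row.setdefault("session", "R1")
            row.update({
                "condition": cond,
                "percept_id": f"{row['subject']}_{row['day']}_{row['session']}_{i:04d}",
                "onset": onsets[i],
                "duration": dur,
                "label": lab[i],
                "transition": transition,
                # bounds kept; 1 ns slack absorbs float accumulation in onsets
                "included": bool(min_duration - 1e-9 <= dur <= max_duration + 1e-9),
            })
            rows.append(row)
            prev_label = lab[i]
    cols = ["subject", "day", "session", "condition", "percept_id",
            "onset", "duration", "label", "transition", "included"]
    return pd.DataFrame(rows, columns=cols)


def return_fraction(percepts: pd.DataFrame) -> dict:
    """Fraction of return transitions, with and without the session-initial
    percepts (which have no defined transition) in the denominator."""
    defined = percepts["transition"].notna()
    n_ret = int((percepts["transition"] == "return").sum())
    return {
        "n_return": n_ret,
        "frac_of_defined": n_ret / max(int(defined.sum()), 1),
        "frac_of_all": n_ret / max(len(percepts), 1),
    }


def duration_summary(percepts: pd.DataFrame, bin_width: float = 1.0) -> dict:
    """Mean/median of included durations and the participant-averaged
    probability histogram in 1 s bins.

    Each participant's histogram is normalized to unit mass before
    averaging, so rare long durations of a single prolific subject do not
    dominate the group histogram.
    """
    inc = percepts.loc[percepts["included"]]
    if inc.empty:
        return {"n": 0, "mean": np.nan, "median": np.nan,
                "bin_edges": np.array([]), "hist": np.array([])}
    durations = inc["duration"].to_numpy()
    hi = float(np.ceil(durations.max() / bin_width)) * bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    per_subj = []
    for _, grp in inc.groupby("subject"):
        h, _ = np.histogram(grp["duration"], bins=edges)
        per_subj.append(h / h.sum())
    return {
        "n": len(inc),
        "mean": float(durations.mean()),
        "median": float(np.median(durations)),
        "bin_edges": edges,
        "hist": np.mean(per_subj, axis=0),
    }


def stable_windows(
    onset: float,
    duration: float,
    width: float = 1.0,
    step: float = 0.5,
    guard_pre: float = 1.0,
    guard_post: float = 1.0,
) -> np.ndarray:
    """Start times of analysis windows inside one percept.

    Windows of ``width`` s advance by ``step`` s through the usable span
    ``[onset + guard_pre, onset + duration - guard_post]``; as many full
    windows as fit are placed, so with the defaults the last window ends
    between 1.5 and 1 s before the next press.  Returns an empty array
    when the usable span is shorter than one window.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    usable = duration - guard_pre - guard_post
    if usable < width:
        return np.array([])
    n = int(np.floor((usable - width) / step + 1e-9)) + 1
    return onset + guard_pre + step * np.arange(n)


def segment_percept(
    percept: pd.Series,
    recording,
    width: float = 1.0,
    step: float = 0.5,
    guard_pre: float = 1.0,
    guard_post: float = 1.0,
    ch_names: list[str] | None = None,
) -> np.ndarray:
    """Extract the stable-interval windows of a percept from a recording.

    Returns an array of shape (n_windows, n_channels, n_samples); empty
    first axis when no window fits.
    """
    starts = stable_windows(percept["onset"], percept["duration"],
                            width, step, guard_pre, guard_post)
    out = [recording.extract(s, width, ch_names) for s in starts]
    if not out:
        n_ch = len(ch_names) if ch_names else recording.n_channels
        return np.empty((0, n_ch, 0))
    return np.stack(out)
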