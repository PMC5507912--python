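"""Frequency-domain (DICS-style) beamformer source reconstruction.

A spatial filter per grid voxel is built from the session-level
cross-spectral density (CSD) and the leadfield, minimizing output power
subject to unit gain at the voxel:

    w_v = C'^{-1} l_v / (l_v^T C'^{-1} l_v),
    C'  = Re(C) + lambda * (trace Re(C) / n_channels) * I

with regularization fraction lambda (default 0.05).  The *common filter*
approach computes one filter set from all percepts of a session and
reapplies it to each percept's CSD, so per-percept source power
estimates share the same spatial weighting and are comparable:

    power_v = Re(w_v^T C_epoch conj(w_v)).

Only the real part of the CSD enters the filter (the standard power
variant); free-orientation leadfields are reduced to the
dominant-power orientation before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Leadfield
from .inference import NESTING, fit_lmem
from .spectral import CSDMatrix

Z_ONE_SIDED_01 = 2.326  # one-sided p = 0.01 under the normal reference


@dataclass
class SpatialFilterSet:
    weights: np.ndarray            # (n_voxels, n_channels), real
    leadfield: Leadfield
    regularization: float
    orientations: np.ndarray | None = None   # (n_voxels, 3) when reduced from free

    def check_unit_gain(self, atol: float = 1e-10) -> None:
        gains = np.einsum("vc,vc->v", self.weights, self._effective_gains())
        if not np.allclose(gains, 1.0, atol=atol):
            raise AssertionError("unit-gain constraint violated")

    def _effective_gains(self) -> np.ndarray:
        g = self.leadfield.gains
        if g.ndim == 3 and self.orientations is not None:
            return np.einsum("vco,vo->vc", g, self.orientations)
        return g


def _regularized(csd: CSDMatrix, lam: float) -> np.ndarray:
    c = np.real(csd.matrix)
    n = c.shape[0]
    return c + lam * (np.trace(c) / n) * np.eye(n)


def make_filters(csd: CSDMatrix, leadfield: Leadfield, lam: float = 0.05) -> SpatialFilterSet:
    """Unit-gain minimum-variance filters for every voxel.

    ``lam`` scales the diagonal loading by the mean sensor power
    (trace/n), which makes the weights invariant to a global rescaling of
    the CSD.  Free-orientation leadfields (voxels x channels x 3) are
    first reduced to the orientation maximizing source power.
    """
    csd.check()
    n_ch = csd.matrix.shape[0]
    if leadfield.gains.shape[1] != n_ch and not (
            leadfield.gains.ndim == 3 and leadfield.gains.shape[1] == n_ch):
        raise ValueError("channel count mismatch between CSD and leadfield")

    cr = _regularized(csd, lam)
    try:
        cinv = np.linalg.inv(cr)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"CSD singular even after {lam:.2%} regularization") from err

    gains = leadfield.gains
    orientations = None
    if gains.ndim == 3:
        # dominant orientation: eigenvector minimizing l^T C^-1 l
        orientations = np.zeros((gains.shape[0], 3))
        reduced = np.zeros((gains.shape[0], n_ch))
        for v in range(gains.shape[0]):
            lv = gains[v]                       # (n_ch, 3)
            m = lv.T @ cinv @ lv
            w_eig, vecs = np.linalg.eigh(m)
            u = vecs[:, 0]
            orientations[v] = u
            reduced[v] = lv @ u
        gains = reduced

    num = gains @ cinv                          # (n_vox, n_ch)
    denom = np.einsum("vc,vc->v", num, gains)
    if np.any(denom <= 0):
        raise np.linalg.LinAlgError("non-positive beamformer denominator")
    weights = num / denom[:, None]
    filt = SpatialFilterSet(weights=weights, leadfield=leadfield,
                            regularization=lam, orientations=orientations)
    filt.check_unit_gain()
    return filt


def source_power(filters: SpatialFilterSet, epoch_csd: CSDMatrix,
                 rel_tol: float = 1e-6) -> np.ndarray:
    """Per-voxel source power for one percept: Re(w^T C conj(w)).

    Values that are negative beyond ``rel_tol`` of the largest magnitude
    raise a conditioning error; tiny negative round-off is clipped to 0.
    """
    c = epoch_csd.matrix
    if c.shape[0] != filters.weights.shape[1]:
        raise ValueError("channel count mismatch between filters and CSD")
    p = np.real(np.einsum("vc,cd,vd->v", filters.weights, c,
                          filters.weights.conj()))
    floor = -rel_tol * max(np.abs(p).max(), 1e-300)
    if np.any(p < floor):
        raise np.linalg.LinAlgError(
            f"negative source power beyond tolerance (min {p.min():.3g}); "
            "epoch CSD is badly conditioned")
    return np.clip(p, 0.0, None)


def source_power_table(
    filters: SpatialFilterSet,
    epoch_csds: dict[str, CSDMatrix],
) -> pd.DataFrame:
    """Log source power per percept (rows) and voxel (columns ``v0...``)."""
    rows, index = [], []
    for pid, csd in epoch_csds.items():
        if csd is None:
            continue
        p = source_power(filters, csd)
        with np.errstate(divide="ignore"):
            rows.append(np.log(p))
        index.append(pid)
    cols = [f"v{j}" for j in range(filters.weights.shape[0])]
    return pd.DataFrame(rows, index=pd.Index(index, name="percept_id"),
                        columns=cols)


def voxel_zmap(
    source_table: pd.DataFrame,
    percepts: pd.DataFrame,
    response: str = "log_duration",
    nesting: tuple[str, ...] = NESTING,
    threshold: float = Z_ONE_SIDED_01,
) -> pd.DataFrame:
    """Per-voxel LMEM of log duration on log source alpha power.

    Each voxel column of ``source_table`` is used as the regressor in a
    nested-random-intercept LMEM over the included percepts; the result
    is one row per voxel with the Wald z and a one-sided mask at
    ``threshold`` (default 2.326, one-sided p = 0.01).  Non-convergent
    voxels are reported with NaN and counted via the ``converged``
    column.
    """
    meta = percepts.set_index("percept_id")
    common = source_table.index.intersection(meta.index)
    if len(common) == 0:
        raise ValueError("no percepts shared between source table and percept table")
    meta = meta.loc[common, [*nesting, response]].reset_index()

    rows = []
    for col in source_table.columns:
        df = meta.copy()
        df["vox_alpha"] = source_table.loc[common, col].to_numpy()
        df.loc[~np.isfinite(df["vox_alpha"]), "vox_alpha"] = np.nan
        try:
            f = fit_lmem(df, response, ["vox_alpha"], nesting)
            z, est, ok = f.wald_z, f.estimate, f.converged
        except (ValueError, np.linalg.LinAlgError):
            z, est, ok = np.nan, np.nan, False
        rows.append({"voxel": col, "estimate": est, "z": z,
                     "masked": bool(ok and z >= threshold), "converged": ok})
    return pd.DataFrame(rows)


def zmap_table(zmap: pd.DataFrame, leadfield: Leadfield) -> pd.DataFrame:
    """Attach grid coordinates: columns x, y, z_mm, zvalue, masked."""
    out = zmap.copy()
    out[["x", "y", "z_mm"]] = leadfield.grid
    return out[["x", "y", "z_mm", "z", "masked", "estimate", "converged"]].rename(
        columns={"z": "zvalue"})
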