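"""Nested mixed-effects inference, KS comparison, and Sobel mediation.

The workhorse is a linear mixed-effects model (LMEM) with nested random
intercepts for subject, day-within-subject, and session-within-day, with
percepts as the residual level — the four nested levels of the study
design.  Models are fit by maximum likelihood (not REML) via
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; fixed effects
are tested with the Wald z statistic (estimate / SE against the standard
normal).

The sleep-deprivation mediation is the LMEM implementation of the Sobel
test: path *a* from ``log_alpha ~ condition``, paths *b* (alpha) and *c*
(condition, unmediated) from the joint model ``log_duration ~ log_alpha +
condition``, and the mediated effect ``ab = a*b`` with standard error
``sqrt(a² se_b² + b² se_a²)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NESTING = ("subject", "day", "session")


@dataclass
class LMEMFit:
    """Fixed-effect summary for one effect of interest, plus the full table."""

    effect: str
    estimate: float
    se: float
    wald_z: float
    p: float
    n_obs: int
    n_dropped: int
    converged: bool
    var_components: dict = field(default_factory=dict)
    r2: float = np.nan
    effects: dict = field(default_factory=dict)   # name -> (estimate, se, z, p)


@dataclass
class MediationResult:
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    ab: float
    se_ab: float
    sobel_z: float
    p: float
    converged: bool
    n_obs: int


@dataclass
class SobelResult:
    ab: float
    se_ab: float
    z: float
    p: float


def z_critical(p: float, one_sided: bool = False) -> float:
    """Standard-normal critical value at significance level ``p``."""
    return float(stats.norm.isf(p if one_sided else p / 2))


def _wald(estimate: float, se: float) -> tuple[float, float]:
    z = estimate / se
    return z, float(2 * stats.norm.sf(abs(z)))


def fit_lmem(
    data: pd.DataFrame,
    response: str,
    predictors: list[str] | str,
    nesting: tuple[str, ...] = NESTING,
    effect: str | None = None,
) -> LMEMFit:
    """Fit ``response ~ predictors`` with nested random intercepts.

    Rows with missing response or predictors are dropped pairwise and
    counted.  Day and session labels need only be unique within their
    parent level; nesting codes are rebuilt internally.  Levels that are
    degenerate (one unit per parent, so their variance is inseparable
    from the level above) are dropped from the random-effects structure.
    The Wald z and two-sided p are reported for ``effect`` (default: the
    first predictor).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if isinstance(predictors, str):
        predictors = [predictors]
    effect = effect or predictors[0]
    cols = [response, *predictors, *nesting]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    df = data[cols].copy()
    n_total = len(df)
    df = df.dropna(subset=[response, *predictors])
    n_dropped = n_total - len(df)
    if df.empty:
        raise ValueError("no complete observations")

    subject, *inner = nesting
    if df[subject].nunique() < 2:
        raise ValueError("need at least 2 top-level groups")

    # unique-within-subject codes for the inner levels
    code_cols = []
    parent = df[subject].astype(str)
    for lvl in inner:
        code = parent + "//" + df[lvl].astype(str)
        col = f"_code_{lvl}"
        df[col] = code
        code_cols.append((lvl, col))
        parent = code
    # drop degenerate levels (as many units as parents -> no separable variance)
    vc = {}
    parents = df[subject].astype(str)
    for lvl, col in code_cols:
        if df[col].nunique() > parents.nunique():
            vc[lvl] = f"0 + C({col})"
        parents = df[col]

    formula = f"{response} ~ " + " + ".join(predictors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = sm.MixedLM.from_formula(
            formula, groups=subject, re_formula="1",
            vc_formula=vc or None, data=df)
        fit, converged = None, False
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=300)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if fit is None:
                fit = cand
            if cand.converged:
                fit, converged = cand, True
                break
        if fit is None:
            return LMEMFit(effect=effect, estimate=np.nan, se=np.nan,
                           wald_z=np.nan, p=np.nan, n_obs=len(df),
                           n_dropped=n_dropped, converged=False)

    effects = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fe_params, bse_fe = fit.fe_params, fit.bse_fe
    for name in fe_params.index:
        est, se = float(fe_params[name]), float(bse_fe[name])
        z, p = _wald(est, se)
        effects[name] = {"estimate": est, "se": se, "z": z, "p": p}
    if effect not in effects:
        raise ValueError(f"effect {effect!r} not among fitted terms {list(effects)}")

    var_components = {"subject": float(fit.cov_re.iloc[0, 0])}
    for j, name in enumerate(getattr(model.exog_vc, "names", [])):
        var_components[name] = float(fit.vcomp[j])
    var_components["residual"] = float(fit.scale)

    r2 = np.nan
    try:
        fitted = np.asarray(fit.fittedvalues) + _ranef_contribution(model, fit, df, subject)
        obs = df[response].to_numpy(dtype=float)
        if np.std(fitted) > 0:
            r2 = float(np.corrcoef(fitted, obs)[0, 1] ** 2)
    except Exception:
        pass

    e = effects[effect]
    if not np.isfinite(e["se"]) or e["se"] <= 0:
        converged = False
    return LMEMFit(effect=effect, estimate=e["estimate"], se=e["se"],
                   wald_z=e["z"], p=e["p"], n_obs=len(df),
                   n_dropped=n_dropped, converged=converged,
                   var_components=var_components, r2=r2, effects=effects)


def _ranef_contribution(model, fit, df: pd.DataFrame, subject: str) -> np.ndarray:
    """Per-row predicted random-effect contribution (intercept + VC BLUPs)."""
    contrib = np.zeros(len(df))
    re = fit.random_effects
    row_group = df[subject].astype(str).to_numpy()
    n_vc = len(getattr(model.exog_vc, "names", []))
    for gi, group in enumerate(model.group_labels):
        mask = row_group == str(group)
        coefs = re[group].to_numpy(dtype=float)
        blocks = [np.ones((int(mask.sum()), 1))]
        for j in range(n_vc):
            blocks.append(np.asarray(model.exog_vc.mats[j][gi]))
        design = np.hstack(blocks)
        contrib[mask] = design @ coefs
    return contrib


def sliding_prediction(
    window_powers: pd.DataFrame,
    percepts: pd.DataFrame,
    response: str = "log_duration",
    nesting: tuple[str, ...] = NESTING,
    min_n: int = 50,
) -> pd.DataFrame:
    """Per-window LMEM of log duration on early sliding-window alpha power.

    ``window_powers`` is indexed like ``percepts`` and has one column per
    window offset (float seconds, the window centre), holding log alpha
    power or NaN for percepts too short to contain that window.  Windows
    with fewer than ``min_n`` complete percepts are skipped with a note.
    """
    offsets = [c for c in window_powers.columns if isinstance(c, (int, float))]
    meta = percepts[[*nesting, response]].reset_index(drop=True)
    rows = []
    for off in offsets:
        df = meta.copy()
        df["win_alpha"] = window_powers[off].to_numpy()
        n_ok = int(df["win_alpha"].notna().sum())
        if n_ok < min_n:
            rows.append({"centre": float(off), "estimate": np.nan, "se": np.nan,
                         "z": np.nan, "p": np.nan, "n": n_ok, "skipped": True})
            continue
        f = fit_lmem(df, response, ["win_alpha"], nesting)
        rows.append({"centre": float(off), "estimate": f.estimate, "se": f.se,
                     "z": f.wald_z, "p": f.p, "n": f.n_obs, "skipped": False})
    return pd.DataFrame(rows)


def ks_two_sample(durations_a: np.ndarray, durations_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and p (exact for small samples)."""
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if min(len(a), len(b)) < 5:
        warnings.warn("fewer than 5 observations per side; exact p used",
                      stacklevel=2)
        res = stats.ks_2samp(a, b, method="exact")
    else:
        res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def sobel(a: float, se_a: float, b: float, se_b: float) -> SobelResult:
    """Sobel test of the mediated effect ab.

    z = a*b / sqrt(a² se_b² + b² se_a²), two-sided normal p.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    ab = a * b
    se_ab = float(np.sqrt(a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2))
    if ab == 0:
        return SobelResult(ab=0.0, se_ab=se_ab, z=0.0, p=1.0)
    z = ab / se_ab
    return SobelResult(ab=ab, se_ab=se_ab, z=z, p=float(2 * stats.norm.sf(abs(z))))


def mediate(
    data: pd.DataFrame,
    alpha_col: str = "log_alpha",
    response: str = "log_duration",
    condition_col: str = "condition",
    nesting: tuple[str, ...] = NESTING,
) -> MediationResult:
    """LMEM Sobel mediation of the sleep-deprivation effect via alpha power.

    ``condition`` is coded 0 for normal sleep (NS), 1 for sleep
    deprivation (SD).  Path *a* is the condition effect on log alpha;
    the joint model of log duration on alpha and condition yields *b*
    (alpha, condition-adjusted) and *c* (the unmediated condition
    effect).  The Sobel z is withheld (NaN) when either fit fails.
    """
    df = data.copy()
    levels = set(df[condition_col].astype(str))
    if not {"NS", "SD"} <= levels and not {0, 1} <= set(np.unique(df[condition_col])):
        raise ValueError("both conditions (NS and SD) must be present")
    df["_is_sd"] = (df[condition_col].astype(str) == "SD").astype(float) \
        if "SD" in levels else df[condition_col].astype(float)
    if df["_is_sd"].nunique() < 2:
        raise ValueError("both conditions must be present")

    fit_a = fit_lmem(df, alpha_col, ["_is_sd"], nesting)
    fit_joint = fit_lmem(df, response, [alpha_col, "_is_sd"], nesting,
                         effect=alpha_col)
    converged = fit_a.converged and fit_joint.converged
    b = fit_joint.effects.get(alpha_col, {})
    c = fit_joint.effects.get("_is_sd", {})
    if not converged or not b or not c:
        return MediationResult(
            a=fit_a.estimate, se_a=fit_a.se,
            b=b.get("estimate", np.nan), se_b=b.get("se", np.nan),
            c=c.get("estimate", np.nan), se_c=c.get("se", np.nan),
            ab=np.nan, se_ab=np.nan, sobel_z=np.nan, p=np.nan,
            converged=False, n_obs=fit_joint.n_obs)
    s = sobel(fit_a.estimate, fit_a.se, b["estimate"], b["se"])
    return MediationResult(
        a=fit_a.estimate, se_a=fit_a.se,
        b=b["estimate"], se_b=b["se"],
        c=c["estimate"], se_c=c["se"],
        ab=s.ab, se_ab=s.se_ab, sobel_z=s.z, p=s.p,
        converged=True, n_obs=fit_joint.n_obs)
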