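"""Shared fixtures and the model-free generative oracle used across tests."""

import numpy as np
import pandas as pd
import pytest

from bistable_alpha import GenParams, default_montage


@pytest.fixture(scope="session")
def montage16():
    return default_montage(16)


@pytest.fixture(scope="session")
def tone_params():
    """Noise-free single-session generator with a pure 9 Hz carrier."""
    return GenParams(
        n_subjects=1, n_days=1, n_sessions=1, session_length=80,
        snr=np.inf, dip_depth=0.0, alpha_band_sd=0.0, sfreq=256.0, seed=42,
    )


def generative_oracle(params: GenParams, n: int = 2_000_000, seed: int = 12345) -> dict:
    """Inclusion-conditional path values of the generative model.

    Vectorized direct draw from the generative equations (independent of
    the table generator's tiling loop and of the mixed-model machinery),
    followed by plain moment/OLS estimands on the 1.5-60 s filtered
    sample: a = condition contrast in latent log alpha, (b, c) = partial
    regression of log duration on (log alpha, condition).
    """
    p = params.resolved()
    rng = np.random.default_rng(seed)
    is_sd = rng.random(n) < 0.5
    x = (p.alpha_log_mean + p.sd_alpha_shift * is_sd
         + rng.normal(0, p.alpha_log_sd, n))
    re_var = p.re_sd_subject ** 2 + p.re_sd_day ** 2 + p.re_sd_session ** 2
    u = rng.normal(0, np.sqrt(re_var), n)
    noise_var = (p.coupling_slope * p.alpha_log_sd) ** 2 + re_var
    g = rng.gamma(p.gamma_shape, p.gamma_scale, n)
    d = g * np.exp(p.coupling_slope * (x - p.alpha_log_mean)
                   + p.sd_direct_shift * is_sd + u - 0.5 * noise_var)
    keep = (d >= p.min_duration) & (d <= p.max_duration)
    xs, ys, cs = x[keep], np.log(d[keep]), is_sd[keep].astype(float)
    a = xs[cs == 1].mean() - xs[cs == 0].mean()
    design = np.column_stack([np.ones(len(xs)), xs, cs])
    beta = np.linalg.lstsq(design, ys, rcond=None)[0]
    return {"a": a, "b": beta[1], "c": beta[2], "ab": a * beta[1],
            "included_fraction": keep.mean()}


def percepts_with_response(table: pd.DataFrame) -> pd.DataFrame:
    """Included percepts with log duration and the latent alpha as regressor."""
    inc = table.loc[table["included"]].copy()
    inc["log_duration"] = np.log(inc["duration"])
    return inc.rename(columns={"log_alpha_true": "log_alpha"})
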