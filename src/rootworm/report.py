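"""Posterior summaries, multiplicative effect statements, and the
posterior-predictive cumulative-emergence band.

Because the hierarchy lives on the log scale, a regression coefficient c
acts multiplicatively on the natural-scale parameter: a one-unit covariate
increase changes it by 100*(exp(c)-1) percent.  Summaries use the
empirical mean, standard deviation, and equal-tailed 95% interval of the
retained draws (the convention of classic BUGS summary tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws, ModelData
from .model import _log_mu  # shared intensity kernel

__all__ = [
    "EffectStatement",
    "summarize",
    "percent_change",
    "percent_effect",
    "posterior_predictive_cumulative",
    "effect_table",
]


def summarize(draws: PosteriorDraws, min_draws: int = 100) -> pd.DataFrame:
    """Posterior mean, sd and equal-tailed 95% interval per scalar parameter."""
    scalars = draws.scalars()
    total = draws.n_chains * draws.n_draws
    if total == 0:
        raise ValueError("no retained draws to summarize")
    if total < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, got {total}")
    rows = []
    for name, values in scalars.items():
        flat = values.ravel()
        lo, hi = np.quantile(flat, [0.025, 0.975])
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(lo),
                "q97.5": float(hi),
            }
        )
    return pd.DataFrame(rows)


def percent_change(coef):
    """Percent change per unit covariate: 100*(exp(coef)-1); monotone, exactly
    invertible via log(1 + pct/100)."""
    return 100.0 * np.expm1(np.asarray(coef, dtype=float))


@dataclass(frozen=True)
class EffectStatement:
    """A coefficient translated to percent change per covariate unit."""

    covariate: str
    percent_mean: float
    percent_lo: float
    percent_hi: float


def percent_effect(coef_draws, covariate: str = "") -> EffectStatement:
    """Multiplicative effect of one log-linear coefficient from its draws."""
    flat = np.asarray(coef_draws, dtype=float).ravel()
    lo, hi = np.quantile(flat, [0.025, 0.975])
    return EffectStatement(
        covariate=covariate,
        percent_mean=float(percent_change(flat.mean())),
        percent_lo=float(percent_change(lo)),
        percent_hi=float(percent_change(hi)),
    )


def effect_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Percent-change translation of every regression coefficient (intercepts excluded)."""
    rows = []
    scalars = draws.scalars()
    for name, values in scalars.items():
        if name.startswith("tau") or name.endswith("intercept"):
            continue
        eff = percent_effect(values, name)
        rows.append(
            {
                "parameter": name,
                "coef_mean": float(values.mean()),
                "percent_mean": eff.percent_mean,
                "percent_lo": eff.percent_lo,
                "percent_hi": eff.percent_hi,
            }
        )
    return pd.DataFrame(rows)


def posterior_predictive_cumulative(
    draws: PosteriorDraws,
    data: ModelData,
    rng=None,
    max_draws: int = 500,
    mode: str = "replicate",
    retention_filter: bool = True,
) -> pd.DataFrame:
    """Posterior-predictive band for the average cumulative weekly count.

    For a subsample of retained draws a full replicate study is simulated:
    in mode "replicate" (default) new trap-year log-parameters are drawn
    from the fitted hierarchy at each trap-year's covariates, weekly counts
    from Poisson(mu), and (when ``retention_filter`` is set, mirroring how
    monitoring data are assembled) trap-years with no positive count are
    dropped before accumulating and averaging; the
    band is the pointwise equal-tailed 95% interval over replicates and
    reflects the population heterogeneity of the traps, not only count
    noise.  Mode "conditional" keeps each draw's own latent parameters and
    shows only Poisson variation around the fitted trap-years.  The
    observed average cumulative curve fills MISSING cells with their
    posterior-mean imputed values so it is defined at every week.

    Returns a DataFrame with columns week, observed, mean, lo, hi.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_weeks = data.y.shape[1]
    if draws.latents.shape[2] != data.n_trap_years:
        raise ValueError("draws and data disagree on the number of trap-years")
    if mode not in ("replicate", "conditional"):
        raise ValueError(f"unknown mode {mode!r}")

    total = draws.n_chains * draws.n_draws
    latents = draws.latents.reshape(total, data.n_trap_years, 3)
    coef_a = draws.coef_alpha.reshape(total, -1)
    coef_b = draws.coef_beta.reshape(total, -1)
    coef_g = draws.coef_gamma.reshape(total, -1)
    tau = draws.tau.reshape(total, 3)
    take = rng.choice(total, size=min(max_draws, total), replace=False)
    curves = np.empty((len(take), n_weeks))
    n_ty = data.n_trap_years
    for j, t in enumerate(take):
        if mode == "replicate":
            lat = np.column_stack(
                [
                    rng.normal(data.X_alpha @ coef_a[t], tau[t, 0] ** -0.5),
                    rng.normal(np.full(n_ty, coef_b[t, 0]), tau[t, 1] ** -0.5),
                    rng.normal(data.X_gamma @ coef_g[t], tau[t, 2] ** -0.5),
                ]
            )
        else:
            lat = latents[t]
        mu = np.exp(np.minimum(_log_mu(lat, data.z), 27.0))
        sim = rng.poisson(mu)
        if mode == "replicate" and retention_filter:
            keep = sim.sum(axis=1) > 0
        else:
            keep = np.ones(n_ty, bool)
        if not keep.any():
            keep = np.ones(n_ty, bool)
        curves[j] = sim[keep].cumsum(axis=1).mean(axis=0)
    lo, hi = np.quantile(curves, [0.025, 0.975], axis=0)

    y_filled = data.y.copy()
    if data.n_missing:
        imput = draws.y_missing.reshape(total, -1).mean(axis=0)
        y_filled[~data.obs] = imput
    observed = y_filled.cumsum(axis=1).mean(axis=0)
    return pd.DataFrame(
        {
            "week": np.arange(1, n_weeks + 1),
            "observed": observed,
            "mean": curves.mean(axis=0),
            "lo": lo,
            "hi": hi,
        }
    )
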