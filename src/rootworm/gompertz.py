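"""Gompertz growth curve, its inflection point, and the derived emergence intensity.

The cumulative number of western corn rootworm (WCR) beetles expected in a
trap by phenological time ``z`` (cumulative growing degree days, possibly
rescaled) is modelled by the Gompertz sigmoid

    f(z) = alpha * exp(-beta * exp(-gamma * z))

with ``alpha`` the upper asymptote (saturation level of the population),
``beta`` a relative starting value (lower beta -> earlier first emergence)
and ``gamma`` a growth-rate coefficient (lower gamma -> more protracted
emergence).  Weekly trap counts are Poisson with mean equal to the
derivative of f, so the log-intensity is

    log f'(z) = log(alpha) + log(beta) + log(gamma) - gamma*z - beta*exp(-gamma*z)

which is unimodal in z with its maximum (peak emergence) at the inflection
point z* = log(beta)/gamma, where the intensity equals alpha*gamma/e.

All functions are pure and broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GompertzParams",
    "gompertz_cdf",
    "inflection_z",
    "log_intensity",
    "weekly_mean_from_curve",
]


@dataclass(frozen=True)
class GompertzParams:
    """Parameter triple of the Gompertz curve; all strictly positive.

    Fields may be scalars or equal-shape arrays (one triple per trap-year).
    """

    alpha: np.ndarray | float
    beta: np.ndarray | float
    gamma: np.ndarray | float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            value = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(value)) or np.any(value <= 0):
                raise ValueError(f"{name} must be finite and strictly positive")


def _unpack(params: GompertzParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        np.asarray(params.alpha, dtype=float),
        np.asarray(params.beta, dtype=float),
        np.asarray(params.gamma, dtype=float),
    )


def gompertz_cdf(z, params: GompertzParams):
    """Expected cumulative count f(z) = alpha*exp(-beta*exp(-gamma*z)).

    Strictly increasing in z with range (0, alpha); requires z >= 0.
    """
    alpha, beta, gamma = _unpack(params)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z (cumulative degree days) must be non-negative")
    return alpha * np.exp(-beta * np.exp(-gamma * z))


def inflection_z(params: GompertzParams):
    """Phenological time of peak emergence, z* = log(beta)/gamma.

    Negative values are legitimate and mean the inflection precedes the
    degree-day start date (beta < 1).
    """
    _, beta, gamma = _unpack(params)
    return np.log(beta) / gamma


def log_intensity(z, params: GompertzParams):
    """Log of the Gompertz derivative: the log expected weekly count.

    log f'(z) = log(alpha) + log(beta) + log(gamma) - gamma*z - beta*exp(-gamma*z)
    """
    alpha, beta, gamma = _unpack(params)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z (cumulative degree days) must be non-negative")
    return (
        np.log(alpha)
        + np.log(beta)
        + np.log(gamma)
        - gamma * z
        - beta * np.exp(-gamma * z)
    )


def weekly_mean_from_curve(params: GompertzParams, z_vector, mode: str = "derivative"):
    """Expected count per weekly reading, bridging the continuous curve to
    the 19 discrete trap readings.

    mode "derivative": mu_t = f'(z_t), the pointwise intensity at each
    reading (the observation model used for fitting).  mode "increment":
    mu_t = f(z_t) - f(z_{t-1}), the exact accumulation between readings
    (with f(z_0^-) taken as f at the first reading, so the first increment
    is 0).  The two agree to O(dz) on a fine grid.
    """
    z = np.asarray(z_vector, dtype=float)
    if np.any(np.diff(z) < 0):
        raise ValueError("z_vector must be non-decreasing")
    if mode == "derivative":
        return np.exp(log_intensity(z, params))
    if mode == "increment":
        cdf = gompertz_cdf(z, params)
        out = np.diff(cdf, prepend=cdf[..., :1])
        return np.maximum(out, 0.0)
    raise ValueError(f"unknown mode {mode!r}; expected 'derivative' or 'increment'")
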