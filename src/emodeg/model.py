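"""Pure model mathematics: link functions and transition/observation densities.

Per inter-visit interval (t_{i-1}, t_i] of length dt the model is

    dM ~ Normal(mu, sigma^2 * dt),   mu = c_mu * tanh(w.delta + w_z.z + w_d*D_prev + w_0) * dt
    dD ~ Gamma(shape = c_ga * logistic(M_prev) * dt, rate = beta)
    Y  ~ Normal(h_0 + h_d*D + h_m*M, sigma_eps^2)

with compound-Poisson emotional impacts: counts Poisson(k*dt), magnitudes
Exponential(lambda). All functions here are stateless (no sampling, no I/O).
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .params import DegenerateModelError, ModelParameters

__all__ = [
    "sigmoid",
    "drift_mu",
    "gamma_shape",
    "logpdf_emotion_increment",
    "logpdf_degradation_increment",
    "logpdf_observation",
    "logpmf_impact_count",
    "logpdf_impact_total",
]


def sigmoid(x):
    """Standard logistic function 1 / (1 + exp(-x))."""
    return special.expit(x)


def _check_dt(dt) -> None:
    if np.any(np.asarray(dt) <= 0):
        raise ValueError(f"dt must be strictly positive, got {dt!r}")


def drift_mu(params: ModelParameters, delta_neg, delta_pos, z, d_prev, dt):
    """Mean change of the emotional state over an interval of length dt.

    The tanh link bounds the per-unit-time drift in (-c_mu, c_mu); the
    positive-impact coefficient multiplies the positive cumulative impact
    and likewise for the negative side.
    """
    _check_dt(dt)
    z = np.atleast_1d(np.asarray(z, dtype=float)) if z is not None else np.zeros(0)
    if z.shape[-1] != params.p_covariates:
        raise ValueError(
            f"covariate length {z.shape[-1]} != coefficient length {params.p_covariates}")
    arg = (params.w_delta_pos * np.asarray(delta_pos)
           + params.w_delta_neg * np.asarray(delta_neg)
           + (z @ params.w_z if params.p_covariates else 0.0)
           + params.w_d * np.asarray(d_prev)
           + params.w_0)
    return params.c_mu * np.tanh(arg) * dt


def gamma_shape(params: ModelParameters, m_prev, dt):
    """Shape of the degradation increment: c_ga * logistic(M_prev) * dt.

    Strictly positive and increasing in the previous emotional state, so a
    raised emotional state accelerates degradation.
    """
    _check_dt(dt)
    if params.c_ga == 0:
        raise DegenerateModelError(
            "c_ga = 0: degradation increments are identically zero and their "
            "density is undefined")
    return params.c_ga * sigmoid(np.asarray(m_prev, dtype=float)) * dt


def logpdf_emotion_increment(params: ModelParameters, dm, delta_neg, delta_pos,
                             z, d_prev, dt):
    """Log density of the emotional-state increment dM over an interval."""
    if params.sigma <= 0:
        raise DegenerateModelError("sigma = 0: emotion increment density undefined")
    mu = drift_mu(params, delta_neg, delta_pos, z, d_prev, dt)
    return stats.norm.logpdf(dm, loc=mu, scale=params.sigma * np.sqrt(dt))


def logpdf_degradation_increment(params: ModelParameters, dd, m_prev, dt):
    """Log density of the degradation increment dD; -inf for dd < 0."""
    alpha = gamma_shape(params, m_prev, dt)
    dd = np.asarray(dd, dtype=float)
    out = stats.gamma.logpdf(dd, a=alpha, scale=1.0 / params.beta)
    # scipy returns -inf outside the support already; make 0-d arrays scalar
    return out if out.ndim else float(out)


def logpdf_observation(params: ModelParameters, y, d, m):
    """Log density of the observed score given the latent state."""
    if params.sigma_eps <= 0:
        raise DegenerateModelError("sigma_eps = 0: observation density undefined")
    mean = params.h_0 + params.h_d * np.asarray(d) + params.h_m * np.asarray(m)
    return stats.norm.logpdf(y, loc=mean, scale=params.sigma_eps)


def logpmf_impact_count(k: float, n, dt) -> float:
    """Log probability of n impact events in an interval of length dt.

    The counting process is a homogeneous Poisson process with rate k, so
    the interval count is Poisson with mean k*dt.
    """
    _check_dt(dt)
    if k <= 0:
        raise ValueError(f"rate k must be strictly positive, got {k}")
    n_arr = np.asarray(n)
    if np.any(n_arr < 0) or not np.issubdtype(n_arr.dtype, np.integer) and np.any(n_arr != np.floor(n_arr)):
        raise ValueError(f"count n must be a non-negative integer, got {n!r}")
    out = stats.poisson.logpmf(n_arr, mu=k * dt)
    return out if out.ndim else float(out)


def logpdf_impact_total(lam: float, total, n) -> float:
    """Log density of the cumulative impact given the event count.

    A sum of n iid Exponential(lam) marks is Gamma(n, rate=lam); n = 0
    forces total = 0 (log-probability 0 there, -inf elsewhere).
    """
    if lam <= 0:
        raise ValueError(f"rate lambda must be strictly positive, got {lam}")
    n = int(n)
    if n == 0:
        return 0.0 if total == 0 else -np.inf
    return float(stats.gamma.logpdf(total, a=n, scale=1.0 / lam))
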