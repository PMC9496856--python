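"""Sequential one-step-ahead forecasting of the cognitive score.

The prediction task is P{Y(t_{i+1}) | Y(t_0), ..., Y(t_i)}: as each new
visit arrives the model state is updated and the next score is predicted
with a 5-95% interval. Parameter uncertainty is carried by a set of
posterior (or prior) parameter draws; within each draw a particle cloud
tracks the latent (D, M) state. Arrival of an observation updates both the
particle clouds (filtering) and the parameter weights (sequential Bayesian
reweighting by each draw's accumulated marginal likelihood) — the same
prior-to-posterior updating that a full refit performs, done by importance
weighting of the initial draws. A full particle-marginal refit per step is
available via ``update='refit'``.

Forecast propagation draws the unknown future emotional impacts from their
compound-Poisson prior; recorded past impacts are conditioned on during
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy import special

from .inference import McmcConfig, PosteriorFit, PriorSpec, fit_mcmc
from .params import ModelParameters, Trajectory
from .simulate import Dataset

__all__ = [
    "Forecast",
    "EvaluationReport",
    "predict_next",
    "sequential_predict",
    "sequential_predict_dataset",
    "evaluate",
    "pair_forecasts_with_truths",
]


@dataclass
class Forecast:
    """Predictive mean and 5%/95% quantiles of the next score."""

    subject_id: str
    target_time: float
    predictive_mean: float
    q05: float
    q95: float
    predictive_draws: Optional[np.ndarray] = None


@dataclass
class EvaluationReport:
    """Pooled and per-subject squared-error summary of one-step forecasts."""

    mse: float
    n_predictions: int
    coverage_05_95: float
    per_subject_mse: Dict[str, float] = field(default_factory=dict)
    mean_subject_mse: float = float("nan")


def _as_param_draws(fit_or_prior: Union[PosteriorFit, PriorSpec],
                    n_theta: int, rng: np.random.Generator,
                    ) -> List[ModelParameters]:
    if isinstance(fit_or_prior, PosteriorFit):
        return fit_or_prior.thin_params(n_theta)
    if isinstance(fit_or_prior, PriorSpec):
        spec = fit_or_prior
        draws = []
        for _ in range(n_theta):
            free = {n: spec.priors[n].sample(rng) for n in spec.free_names}
            draws.append(spec.build_params(free))
        return draws if draws else [spec.build_params({})]
    raise TypeError("expected a PosteriorFit or a PriorSpec")


class _SequentialFilter:
    """Per-subject filter over parameter draws x latent particles."""

    def __init__(self, params_list: List[ModelParameters], n_particles: int,
                 rng: np.random.Generator):
        self.params = params_list
        self.rng = rng
        self.T = len(params_list)
        self.N = n_particles
        self.D = np.zeros((self.T, self.N))
        self.M = np.zeros((self.T, self.N))
        self.log_ml = np.zeros(self.T)  # cumulative marginal log lik per draw
        # vectorizable parameter columns
        def col(name):
            return np.array([getattr(p, name) for p in params_list])[:, None]
        self.c_mu, self.sigma = col("c_mu"), col("sigma")
        self.c_ga, self.beta = col("c_ga"), col("beta")
        self.h_0, self.h_d, self.h_m = col("h_0"), col("h_d"), col("h_m")
        self.sigma_eps = col("sigma_eps")
        self.w_dp, self.w_dn = col("w_delta_pos"), col("w_delta_neg")
        self.w_d, self.w_0 = col("w_d"), col("w_0")
        self.k_pos, self.k_neg = col("k_pos"), col("k_neg")
        self.lam_pos, self.lam_neg = col("lambda_pos"), col("lambda_neg")
        self.w_z = np.array([p.w_z for p in params_list])  # (T, p)

    def _obs_logpdf(self, y, D, M):
        # sigma_eps = 0 (degenerate noise-off mode) scores exact matches 0
        # and mismatches -inf
        mean = self.h_0 + self.h_d * D + self.h_m * M
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.where(self.sigma_eps > 0, self.sigma_eps, np.nan)
            resid = (y - mean) / se
            out = -0.5 * resid * resid - np.log(se * np.sqrt(2 * np.pi))
        return np.where(np.isnan(out),
                        np.where(np.isclose(y, mean), 0.0, -np.inf), out)

    def _propagate(self, D, M, dt, z_prev, delta_neg=None, delta_pos=None):
        """One-interval move of every (draw, particle); impacts sampled from
        their compound-Poisson prior when not supplied."""
        rng = self.rng
        shp = D.shape
        if delta_neg is None:
            dn = rng.standard_gamma(rng.poisson(self.k_neg * dt, shp))
            dn = np.divide(dn, self.lam_neg)
            dp = rng.standard_gamma(rng.poisson(self.k_pos * dt, shp))
            dp = np.divide(dp, self.lam_pos)
        else:
            dn, dp = delta_neg, delta_pos
        arg = self.w_dp * dp + self.w_dn * dn + self.w_d * D + self.w_0
        if self.w_z.shape[1]:
            arg = arg + (self.w_z @ np.asarray(z_prev, dtype=float))[:, None]
        M_new = (M + self.c_mu * np.tanh(arg) * dt
                 + self.sigma * np.sqrt(dt) * rng.standard_normal(shp))
        shape = self.c_ga * special.expit(M) * dt
        D_new = np.where(shape > 0,
                         D + rng.standard_gamma(np.maximum(shape, 1e-300)) / self.beta,
                         D)
        return D_new, M_new

    def assimilate_first(self, y0: float) -> None:
        self.log_ml += self._obs_logpdf(y0, self.D, self.M)[:, 0]

    def assimilate(self, y: float, dt: float, z_prev,
                   delta_neg=None, delta_pos=None) -> None:
        """Advance one observed interval and condition on the new score."""
        if delta_neg is not None:
            delta_neg = np.broadcast_to(delta_neg, (self.T, 1))
            delta_pos = np.broadcast_to(delta_pos, (self.T, 1))
        D_new, M_new = self._propagate(self.D, self.M, dt, z_prev,
                                       delta_neg, delta_pos)
        lw = self._obs_logpdf(y, D_new, M_new)
        step = special.logsumexp(lw, axis=1) - np.log(self.N)
        self.log_ml += np.where(np.isfinite(step), step, -np.inf)
        # resample particles within each draw
        w = np.exp(lw - special.logsumexp(lw, axis=1, keepdims=True))
        for t in range(self.T):
            if not np.all(np.isfinite(w[t])):
                w[t] = 1.0 / self.N
            cum = np.cumsum(w[t])
            cum[-1] = 1.0
            pos = (self.rng.random() + np.arange(self.N)) / self.N
            idx = np.searchsorted(cum, pos)
            self.D[t] = D_new[t, idx]
            self.M[t] = M_new[t, idx]

    def theta_weights(self) -> np.ndarray:
        top = np.max(self.log_ml)
        if not np.isfinite(top):
            return np.full(self.T, 1.0 / self.T)
        w = np.exp(self.log_ml - top)
        return w / np.sum(w)

    def forecast(self, subject_id: str, target_time: float, t_last: float,
                 z_prev, n_draws: int) -> Forecast:
        """Posterior-predictive draws of the next score, integrating over
        parameter weights, particle clouds and future impacts."""
        dt = target_time - t_last
        if dt <= 0:
            raise ValueError("target time must exceed the last history time")
        D_new, M_new = self._propagate(self.D, self.M, dt, z_prev)
        mean = self.h_0 + self.h_d * D_new + self.h_m * M_new
        y_all = mean + self.sigma_eps * self.rng.standard_normal(mean.shape)
        # sample draw indices by parameter weight, particles uniformly
        w = self.theta_weights()
        cum = np.cumsum(w)
        cum[-1] = 1.0
        t_idx = np.searchsorted(cum, (self.rng.random() + np.arange(n_draws)) / n_draws)
        p_idx = self.rng.integers(0, self.N, size=n_draws)
        draws = y_all[t_idx, p_idx]
        return Forecast(
            subject_id=subject_id,
            target_time=float(target_time),
            predictive_mean=float(np.mean(draws)),
            q05=float(np.quantile(draws, 0.05)),
            q95=float(np.quantile(draws, 0.95)),
            predictive_draws=draws,
        )


def _interval_impacts(traj: Trajectory, i: int):
    if traj.impacts is None:
        return None, None
    imp = traj.impacts[i - 1]
    return imp.delta_neg, imp.delta_pos


def _z_prev(traj: Trajectory, i: int):
    return traj.z[i] if traj.z is not None else np.zeros(0)


def sequential_predict(trajectory: Trajectory,
                       fit_or_prior: Union[PosteriorFit, PriorSpec],
                       config: Optional[McmcConfig] = None,
                       i_min: int = 1,
                       n_theta: int = 200,
                       n_particles: int = 256,
                       n_forecast_draws: int = 400,
                       seed: int = 0,
                       update: str = "reweight") -> List[Forecast]:
    """One-step-ahead forecasts along a subject's record.

    For each i = i_min .. n-1 the filter conditions on observations up to
    t_i only (leakage-free) and predicts Y(t_{i+1}). ``update='reweight'``
    (default) performs the sequential parameter update by importance
    reweighting of the initial draws; ``update='refit'`` re-runs the MCMC on
    the accumulated history before every forecast.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 observations to forecast")
    if not 0 <= i_min <= len(trajectory) - 2:
        raise ValueError(f"i_min must be in [0, {len(trajectory) - 2}]")
    if update not in ("reweight", "refit"):
        raise ValueError(f"unknown update scheme {update!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if update == "refit":
        if not isinstance(fit_or_prior, (PosteriorFit, PriorSpec)):
            raise TypeError("expected a PosteriorFit or a PriorSpec")
        priors = (fit_or_prior if isinstance(fit_or_prior, PriorSpec)
                  else fit_or_prior.priors)
        if config is None:
            raise ValueError("update='refit' requires an McmcConfig")
        forecasts = []
        for i in range(max(i_min, 1), len(trajectory) - 1):
            history = trajectory.prefix(i + 1)
            step_fit = fit_mcmc(Dataset([history]), priors,
                                McmcConfig(**{**config.__dict__,
                                              "seed": config.seed + i}))
            forecasts.extend(sequential_predict(
                history_plus_target(trajectory, i), step_fit, i_min=i,
                n_theta=n_theta, n_particles=n_particles,
                n_forecast_draws=n_forecast_draws, seed=seed + i))
        return forecasts

    params_list = _as_param_draws(fit_or_prior, n_theta, rng)
    filt = _SequentialFilter(params_list, n_particles, rng)
    filt.assimilate_first(trajectory.y[0])
    forecasts: List[Forecast] = []
    for i in range(len(trajectory) - 1):
        if i >= i_min:
            forecasts.append(filt.forecast(
                trajectory.subject_id, trajectory.times[i + 1],
                trajectory.times[i], _z_prev(trajectory, i), n_forecast_draws))
        dn, dp = _interval_impacts(trajectory, i + 1)
        filt.assimilate(trajectory.y[i + 1],
                        trajectory.times[i + 1] - trajectory.times[i],
                        _z_prev(trajectory, i), dn, dp)
    return forecasts


def history_plus_target(trajectory: Trajectory, i: int) -> Trajectory:
    """Prefix of a trajectory through observation i+1 (one forecast target)."""
    return trajectory.prefix(i + 2)


def predict_next(history: Trajectory,
                 fit_or_prior: Union[PosteriorFit, PriorSpec],
                 config: Optional[McmcConfig] = None,
                 target_time: Optional[float] = None,
                 n_theta: int = 200, n_particles: int = 256,
                 n_forecast_draws: int = 400, seed: int = 0) -> Forecast:
    """Posterior-predictive forecast of the observation after a history.

    The filter conditions on every observation in ``history``; the target
    defaults to one median inter-visit interval past the last visit.
    """
    if len(history) < 1:
        raise ValueError("history must contain at least one observation")
    t_last = float(history.times[-1])
    if target_time is None:
        gaps = np.diff(history.times)
        target_time = t_last + (float(np.median(gaps)) if gaps.size else 1.0)
    if target_time <= t_last:
        raise ValueError("target time must exceed the last history time")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    params_list = _as_param_draws(fit_or_prior, n_theta, rng)
    filt = _SequentialFilter(params_list, n_particles, rng)
    filt.assimilate_first(history.y[0])
    for i in range(1, len(history)):
        dn, dp = _interval_impacts(history, i)
        filt.assimilate(history.y[i], history.times[i] - history.times[i - 1],
                        _z_prev(history, i - 1), dn, dp)
    return filt.forecast(history.subject_id, target_time, t_last,
                         _z_prev(history, len(history) - 1), n_forecast_draws)


def sequential_predict_dataset(dataset: Dataset,
                               fit_or_prior: Union[PosteriorFit, PriorSpec],
                               i_min: int = 1, seed: int = 0,
                               **kwargs) -> List[Forecast]:
    """Run sequential_predict on every trajectory (independent sub-seeds)."""
    out: List[Forecast] = []
    for j, traj in enumerate(dataset.trajectories):
        out.extend(sequential_predict(traj, fit_or_prior, i_min=i_min,
                                      seed=seed + 7919 * j, **kwargs))
    return out


def pair_forecasts_with_truths(forecasts: Sequence[Forecast],
                               dataset: Dataset) -> np.ndarray:
    """Look up the realized score for each forecast by (subject, target time)."""
    lookup = {}
    for traj in dataset.trajectories:
        for t, y in zip(traj.times, traj.y):
            lookup[(traj.subject_id, float(t))] = float(y)
    truths = []
    for f in forecasts:
        key = (f.subject_id, float(f.target_time))
        if key not in lookup:
            raise ValueError(f"no observation for subject {key[0]} at time {key[1]}")
        truths.append(lookup[key])
    return np.asarray(truths)


def evaluate(forecasts: Sequence[Forecast], truths) -> EvaluationReport:
    """Mean squared error of predictive means and empirical 5-95% coverage."""
    truths = np.asarray(truths, dtype=float)
    if len(forecasts) != truths.shape[0]:
        raise ValueError(
            f"{len(forecasts)} forecasts but {truths.shape[0]} truths")
    if len(forecasts) == 0:
        raise ValueError("nothing to evaluate")
    means = np.array([f.predictive_mean for f in forecasts])
    lo = np.array([f.q05 for f in forecasts])
    hi = np.array([f.q95 for f in forecasts])
    sq = (means - truths) ** 2
    inside = (truths >= lo) & (truths <= hi)
    per_subject: Dict[str, list] = {}
    for f, e in zip(forecasts, sq):
        per_subject.setdefault(f.subject_id, []).append(e)
    per_subject_mse = {s: float(np.mean(v)) for s, v in per_subject.items()}
    return EvaluationReport(
        mse=float(np.mean(sq)),
        n_predictions=int(sq.shape[0]),
        coverage_05_95=float(np.mean(inside)),
        per_subject_mse=per_subject_mse,
        mean_subject_mse=float(np.mean(list(per_subject_mse.values()))),
    )
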