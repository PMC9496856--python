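"""Scikit-learn-style estimator wrapping the MCMC fit and the sequential
one-step-ahead forecaster.

``ProgressionMCMC`` accepts longitudinal data either as a :class:`Dataset`
or as a long-format :class:`pandas.DataFrame` (columns ``subject_id, time,
y`` plus optional covariate/impact columns), fits the posterior by
particle-marginal MCMC, and predicts each subject's next score
sequentially. It composes with sklearn model selection through
``get_params``/``set_params`` and exposes fitted state through
trailing-underscore attributes.
"""

from __future__ import annotations

from typing import List, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import inference
from .forecast import (EvaluationReport, Forecast, evaluate,
                       pair_forecasts_with_truths, sequential_predict_dataset)
from .inference import McmcConfig, PosteriorFit, PriorSpec, synthetic_priors
from .simulate import Dataset

__all__ = ["ProgressionMCMC"]


class ProgressionMCMC(BaseEstimator):
    """Bayesian degradation/emotion progression model.

    Parameters
    ----------
    priors
        A :class:`PriorSpec`; defaults to the synthetic eight-free-parameter
        profile.
    n_chains, n_warmup, n_samples, n_particles, latent_treatment, seed
        Sampler settings (see :class:`McmcConfig`).
    i_min, n_theta, forecast_particles, n_forecast_draws
        Forecasting settings: first history length to forecast from, number
        of retained parameter draws, latent particles per draw, and
        predictive draws per forecast.
    """

    def __init__(self, priors: Optional[PriorSpec] = None, n_chains: int = 3,
                 n_warmup: int = 1000, n_samples: int = 1000,
                 n_particles: int = 512,
                 latent_treatment: str = "impacts_observed", seed: int = 0,
                 i_min: int = 1, n_theta: int = 200,
                 forecast_particles: int = 256, n_forecast_draws: int = 400):
        self.priors = priors
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.n_particles = n_particles
        self.latent_treatment = latent_treatment
        self.seed = seed
        self.i_min = i_min
        self.n_theta = n_theta
        self.forecast_particles = forecast_particles
        self.n_forecast_draws = n_forecast_draws

    # -- data plumbing ------------------------------------------------------

    @staticmethod
    def _as_dataset(X: Union[Dataset, pd.DataFrame]) -> Dataset:
        if isinstance(X, Dataset):
            return X
        if isinstance(X, pd.DataFrame):
            from .io import dataset_from_frame
            return dataset_from_frame(X)
        raise TypeError(
            f"X must be a Dataset or a long-format DataFrame, got {type(X)}")

    def _mcmc_config(self) -> McmcConfig:
        return McmcConfig(n_chains=self.n_chains, n_warmup=self.n_warmup,
                          n_samples=self.n_samples, seed=self.seed,
                          latent_treatment=self.latent_treatment,
                          n_particles=self.n_particles)

    def _prior_spec(self) -> PriorSpec:
        return self.priors if self.priors is not None else synthetic_priors()

    # -- estimator API ------------------------------------------------------

    def fit(self, X: Union[Dataset, pd.DataFrame], y=None) -> "ProgressionMCMC":
        """Sample the posterior from longitudinal data.

        Sets ``posterior_`` (the full :class:`PosteriorFit`), ``draws_``
        (chains x samples x parameters), ``param_names_``, ``rhat_`` and
        ``summary_``.
        """
        dataset = self._as_dataset(X)
        if len(dataset.trajectories) == 0:
            raise ValueError("X contains no trajectories")
        self.posterior_ = inference.fit_mcmc(
            dataset, self._prior_spec(), self._mcmc_config())
        self.draws_ = self.posterior_.draws
        self.param_names_ = list(self.posterior_.param_names)
        self.rhat_ = dict(self.posterior_.rhat)
        self.summary_ = self.posterior_.summary
        self.n_features_in_ = dataset.p_covariates
        return self

    def _fit_or_prior(self):
        return getattr(self, "posterior_", None) or self._prior_spec()

    def forecast(self, X: Union[Dataset, pd.DataFrame]) -> List[Forecast]:
        """Sequential one-step-ahead forecasts for every subject in X."""
        dataset = self._as_dataset(X)
        return sequential_predict_dataset(
            dataset, self._fit_or_prior(), i_min=self.i_min,
            seed=self.seed + 1, n_theta=self.n_theta,
            n_particles=self.forecast_particles,
            n_forecast_draws=self.n_forecast_draws)

    def predict(self, X: Union[Dataset, pd.DataFrame]) -> np.ndarray:
        """Predictive means of the sequential forecasts, ordered by subject
        (as sorted by the Dataset) then target time."""
        return np.array([f.predictive_mean for f in self.forecast(X)])

    def score(self, X: Union[Dataset, pd.DataFrame], y=None) -> float:
        """Negative pooled one-step-ahead MSE (larger is better)."""
        return -self.report(X).mse

    def report(self, X: Union[Dataset, pd.DataFrame]) -> EvaluationReport:
        """Full one-step-ahead evaluation (MSE and interval coverage)."""
        dataset = self._as_dataset(X)
        forecasts = self.forecast(dataset)
        truths = pair_forecasts_with_truths(forecasts, dataset)
        return evaluate(forecasts, truths)
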