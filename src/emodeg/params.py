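"""Domain types for the coupled degradation/emotion progression model.

The model tracks two latent processes per subject: a monotone physiological
degradation level ``D(t) >= 0`` (gamma-process increments) and a real-valued
emotional state ``M(t)`` (Wiener process with a bounded tanh drift driven by
compound-Poisson emotional impacts, covariates and the degradation level).
A cognitive score ``Y(t)`` is observed through a linear-Gaussian link.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "LatentState",
    "ImpactSeries",
    "Trajectory",
    "DegenerateModelError",
]


class DegenerateModelError(ValueError):
    """Raised when a density is requested in the degenerate c_ga = 0 mode."""


@dataclass
class ModelParameters:
    """Generative coefficients of the full progression model.

    Parameters
    ----------
    k_pos, k_neg
        Poisson event rates (events per unit time) of the positive- and
        negative-impact processes.
    lambda_pos, lambda_neg
        Exponential rate parameters of the impact magnitudes (marks).
    w_delta_pos, w_delta_neg
        Drift coefficients on the cumulative positive/negative impact over
        an inter-visit interval.
    w_z
        Covariate coefficients (length-p vector; may be empty).
    w_d
        Drift coefficient on the previous degradation level.
    w_0
        Drift intercept.
    c_mu
        Drift amplitude bound: the per-unit-time mean change of the
        emotional state lies in (-c_mu, c_mu).
    sigma
        Wiener diffusion (standard deviation per sqrt(unit time)).
    c_ga
        Gamma shape amplitude per unit time; c_ga = 0 is a degenerate
        test mode in which the degradation increment is identically zero.
    beta
        Gamma rate parameter of degradation increments.
    h_0, h_d, h_m
        Observation intercept and loadings of degradation and emotion on
        the cognitive score.
    sigma_eps
        Observation noise standard deviation (score units).
    """

    k_pos: float
    k_neg: float
    lambda_pos: float
    lambda_neg: float
    w_delta_pos: float
    w_delta_neg: float
    w_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    w_d: float = 0.0
    w_0: float = 0.0
    c_mu: float = 1.0
    sigma: float = 1.0
    c_ga: float = 1.0
    beta: float = 1.0
    h_0: float = 0.0
    h_d: float = 0.0
    h_m: float = 0.0
    sigma_eps: float = 1.0

    def __post_init__(self) -> None:
        self.w_z = np.atleast_1d(np.asarray(self.w_z, dtype=float))
        for name in ("lambda_pos", "lambda_neg", "c_mu", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        # k, sigma, sigma_eps and c_ga admit 0 as a degenerate (noise-off)
        # test mode; density evaluation rejects the zero cases.
        for name in ("k_pos", "k_neg", "sigma", "sigma_eps", "c_ga"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    @property
    def p_covariates(self) -> int:
        return self.w_z.shape[0]

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class LatentState:
    """Latent state at one time point: degradation level d >= 0, emotion m."""

    d: float
    m: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"degradation level must be >= 0, got {self.d}")


@dataclass(frozen=True)
class ImpactSeries:
    """Cumulative emotional impacts over one inter-visit interval.

    ``delta_neg``/``delta_pos`` are sums of exponential marks, hence
    non-negative and zero exactly when the corresponding count is zero.
    Counts may be ``None`` when a data file records only the totals.
    """

    interval_index: int
    n_neg: Optional[int]
    n_pos: Optional[int]
    delta_neg: float
    delta_pos: float

    def __post_init__(self) -> None:
        if self.delta_neg < 0 or self.delta_pos < 0:
            raise ValueError("cumulative impacts must be non-negative")
        for n, delta, label in ((self.n_neg, self.delta_neg, "neg"),
                                (self.n_pos, self.delta_pos, "pos")):
            if n is None:
                continue
            if n < 0 or int(n) != n:
                raise ValueError(f"n_{label} must be a non-negative integer")
            if n == 0 and delta != 0:
                raise ValueError(f"delta_{label} must be 0 when n_{label} = 0")


@dataclass
class Trajectory:
    """One subject's longitudinal record on a strictly increasing time grid.

    ``times`` and ``y`` have length n+1; ``impacts`` (if recorded) has one
    entry per interval (t_{i-1}, t_i], i.e. length n; ``latent`` (if known,
    e.g. from simulation) aligns with ``times``.
    """

    subject_id: str
    times: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray] = None
    latent: Optional[Sequence[LatentState]] = None
    impacts: Optional[Sequence[ImpactSeries]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.y.shape:
            raise ValueError("times and y must be 1-D and aligned")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"times must be strictly increasing for subject {self.subject_id}")
        if self.z is not None:
            self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
            if self.z.shape[0] != self.times.shape[0]:
                raise ValueError("z must have one row per time point")
        if self.latent is not None and len(self.latent) != len(self.times):
            raise ValueError("latent states must align with times")
        if self.impacts is not None and len(self.impacts) != len(self.times) - 1:
            raise ValueError("impacts must have one entry per interval")
        if self.latent is not None:
            d = np.array([s.d for s in self.latent])
            if np.any(np.diff(d) < 0):
                raise ValueError("latent degradation path must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_intervals(self) -> int:
        return len(self.times) - 1

    @property
    def p_covariates(self) -> int:
        return 0 if self.z is None else self.z.shape[1]

    def prefix(self, n_obs: int) -> "Trajectory":
        """Return the leading ``n_obs`` observations (leakage-free history)."""
        if not 1 <= n_obs <= len(self.times):
            raise ValueError(f"n_obs must be in [1, {len(self.times)}]")
        return Trajectory(
            subject_id=self.subject_id,
            times=self.times[:n_obs].copy(),
            y=self.y[:n_obs].copy(),
            z=None if self.z is None else self.z[:n_obs].copy(),
            latent=None if self.latent is None else list(self.latent[:n_obs]),
            impacts=None if self.impacts is None else list(self.impacts[: n_obs - 1]),
        )
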