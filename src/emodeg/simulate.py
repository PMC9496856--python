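"""Synthetic-data generation from the full generative model.

Five shipped presets reproduce the synthetic study design: groups of 20
sequences x 21 observations on a unit grid, differing in the gamma-process
amplitude (settings 1 vs 2) and in the balance of positive vs negative
emotional-impact rates (settings 3-5; setting 5 switches the rates halfway,
so negative impacts dominate up to t10 and positive impacts afterwards).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import model
from .params import ImpactSeries, LatentState, ModelParameters, Trajectory

__all__ = [
    "SettingPreset",
    "Dataset",
    "SETTINGS",
    "get_setting",
    "sample_impacts",
    "simulate_trajectory",
    "generate_setting",
    "generate_dataset",
    "clip_score",
]


@dataclass(frozen=True)
class SettingPreset:
    """A named simulation condition: parameters plus study dimensions."""

    setting_id: int
    params: ModelParameters
    n_sequences: int = 20
    n_obs: int = 21
    dt: float = 1.0
    # (switch_index, params_after): params_after applies to intervals whose
    # right endpoint index exceeds switch_index.
    regime_switch: Optional[Tuple[int, ModelParameters]] = None


@dataclass
class Dataset:
    """A collection of trajectories sharing a covariate dimension."""

    trajectories: List[Trajectory]
    preset: Optional[SettingPreset] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        dims = {t.p_covariates for t in self.trajectories}
        if len(dims) > 1:
            raise ValueError(f"trajectories have mixed covariate dimensions {dims}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def p_covariates(self) -> int:
        return self.trajectories[0].p_covariates if self.trajectories else 0

    def subset(self, indices) -> "Dataset":
        return Dataset([self.trajectories[i] for i in indices],
                       preset=self.preset, seed=self.seed)


def _base_params(c_ga: float, k_pos: float, k_neg: float) -> ModelParameters:
    return ModelParameters(
        k_pos=k_pos, k_neg=k_neg, lambda_pos=3.0, lambda_neg=3.0,
        w_delta_pos=0.1, w_delta_neg=-0.1, w_z=np.zeros(0), w_d=0.05, w_0=0.0,
        c_mu=3.0, sigma=0.5, c_ga=c_ga, beta=10.0,
        h_0=30.0, h_d=-1.0, h_m=-0.5, sigma_eps=1.0,
    )


def _make_settings() -> dict:
    s5_before = _base_params(5.0, k_pos=3.0, k_neg=5.0)
    s5_after = _base_params(5.0, k_pos=5.0, k_neg=3.0)
    return {
        1: SettingPreset(1, _base_params(10.0, k_pos=5.0, k_neg=4.0)),
        2: SettingPreset(2, _base_params(5.0, k_pos=5.0, k_neg=4.0)),
        3: SettingPreset(3, _base_params(5.0, k_pos=5.0, k_neg=3.0)),
        4: SettingPreset(4, _base_params(5.0, k_pos=3.0, k_neg=5.0)),
        5: SettingPreset(5, s5_before, regime_switch=(10, s5_after)),
    }


SETTINGS = _make_settings()


def get_setting(setting_id: int) -> SettingPreset:
    try:
        return SETTINGS[int(setting_id)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown setting id {setting_id!r}; valid ids are 1-5") from exc


def sample_impacts(k: float, lam: float, dt: float,
                   rng: np.random.Generator) -> Tuple[int, float]:
    """Draw one interval's compound-Poisson impact: (count, cumulative total).

    count ~ Poisson(k*dt); total is the sum of count iid Exponential(lam)
    magnitudes, hence zero exactly when count is zero. ``k = 0`` is accepted
    as the empty process for degenerate tests.
    """
    for name, v in (("k", k), ("lam", lam), ("dt", dt)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if k < 0 or lam <= 0 or dt <= 0:
        raise ValueError("require k >= 0, lam > 0, dt > 0")
    if k == 0:
        return 0, 0.0
    n = int(rng.poisson(k * dt))
    total = float(rng.gamma(shape=n, scale=1.0 / lam)) if n > 0 else 0.0
    return n, total


def simulate_trajectory(params: ModelParameters, times, z=None,
                        rng: Optional[np.random.Generator] = None,
                        init: LatentState = LatentState(0.0, 0.0),
                        subject_id: str = "sim",
                        params_by_interval: Optional[List[ModelParameters]] = None,
                        ) -> Trajectory:
    """Simulate one subject's full record, latent paths included.

    Per interval, in order: draw the compound-Poisson impacts; move the
    emotional state using the *previous* degradation level; move the
    degradation level using the *previous* emotional state; then emit the
    observation from the new latent pair. ``params_by_interval`` optionally
    overrides the parameters interval-by-interval (regime switches).
    """
    rng = np.random.default_rng() if rng is None else rng
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D sequence")
    n = len(times) - 1
    if params_by_interval is not None and len(params_by_interval) != n:
        raise ValueError("params_by_interval must have one entry per interval")
    if z is not None:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[0] != len(times):
            raise ValueError("z must have one row per time point")

    d = np.empty(n + 1)
    m = np.empty(n + 1)
    d[0], m[0] = init.d, init.m
    impacts: List[ImpactSeries] = []

    def emit(i: int, p: ModelParameters) -> float:
        mean = p.h_0 + p.h_d * d[i] + p.h_m * m[i]
        return mean + (p.sigma_eps * rng.standard_normal() if p.sigma_eps > 0 else 0.0)

    y = np.empty(n + 1)
    p0 = params_by_interval[0] if params_by_interval else params
    y[0] = emit(0, p0)
    for i in range(1, n + 1):
        p = params_by_interval[i - 1] if params_by_interval else params
        dt = times[i] - times[i - 1]
        n_neg, delta_neg = sample_impacts(p.k_neg, p.lambda_neg, dt, rng)
        n_pos, delta_pos = sample_impacts(p.k_pos, p.lambda_pos, dt, rng)
        impacts.append(ImpactSeries(i - 1, n_neg, n_pos, delta_neg, delta_pos))
        zi = z[i - 1] if z is not None else np.zeros(p.p_covariates)
        mu = model.drift_mu(p, delta_neg, delta_pos, zi, d[i - 1], dt)
        noise = p.sigma * np.sqrt(dt) * rng.standard_normal() if p.sigma > 0 else 0.0
        m[i] = m[i - 1] + mu + noise
        if p.c_ga > 0:
            shape = model.gamma_shape(p, m[i - 1], dt)
            d[i] = d[i - 1] + rng.standard_gamma(shape) / p.beta
        else:
            d[i] = d[i - 1]
        y[i] = emit(i, p)

    latent = [LatentState(float(d[i]), float(m[i])) for i in range(n + 1)]
    return Trajectory(subject_id=subject_id, times=times, y=y, z=z,
                      latent=latent, impacts=impacts)


def generate_setting(setting_id: int, rng=None, n_sequences: Optional[int] = None,
                     n_obs: Optional[int] = None, dt: Optional[float] = None,
                     seed: Optional[int] = None) -> Dataset:
    """Generate one preset's group of sequences on a uniform grid.

    Accepts either a Generator/SeedSequence via ``rng`` or an integer
    ``seed``. Each trajectory uses an independent child stream, so changing
    ``n_sequences`` never perturbs earlier trajectories.
    """
    preset = get_setting(setting_id)
    n_sequences = preset.n_sequences if n_sequences is None else int(n_sequences)
    n_obs = preset.n_obs if n_obs is None else int(n_obs)
    dt = preset.dt if dt is None else float(dt)
    if n_sequences < 1 or n_obs < 2 or dt <= 0:
        raise ValueError("require n_sequences >= 1, n_obs >= 2, dt > 0")

    if rng is None:
        ss = np.random.SeedSequence(0 if seed is None else seed)
    elif isinstance(rng, np.random.SeedSequence):
        ss = rng
    elif isinstance(rng, np.random.Generator):
        ss = rng.bit_generator.seed_seq.spawn(1)[0]
    else:
        ss = np.random.SeedSequence(int(rng))

    times = np.arange(n_obs) * dt
    n_intervals = n_obs - 1
    if preset.regime_switch is not None:
        switch_index, params_after = preset.regime_switch
        per_interval = [preset.params if i + 1 <= switch_index else params_after
                        for i in range(n_intervals)]
    else:
        per_interval = None

    trajs = []
    for j, child in enumerate(ss.spawn(n_sequences)):
        trajs.append(simulate_trajectory(
            preset.params, times, rng=np.random.default_rng(child),
            subject_id=f"s{setting_id}-{j:03d}", params_by_interval=per_interval))
    return Dataset(trajs, preset=preset, seed=seed)


def generate_dataset(params: ModelParameters, n_sequences: int, n_obs: int,
                     dt: float = 1.0, seed: int = 0, z=None) -> Dataset:
    """Generate sequences from arbitrary parameters (uniform grid)."""
    ss = np.random.SeedSequence(seed)
    times = np.arange(n_obs) * dt
    trajs = [simulate_trajectory(params, times, z=z,
                                 rng=np.random.default_rng(child),
                                 subject_id=f"sim-{j:03d}")
             for j, child in enumerate(ss.spawn(n_sequences))]
    return Dataset(trajs, seed=seed)


def clip_score(y, lo: float = 0.0, hi: float = 30.0):
    """Clamp emitted scores to the instrument range (off by default upstream:
    the observation model is unbounded Gaussian and inference relies on that)."""
    if lo >= hi:
        raise ValueError("require lo < hi")
    return np.clip(y, lo, hi)
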