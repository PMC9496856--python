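"""Delimited-text formats and run configuration.

The longitudinal table is a comma-separated, UTF-8, headered file with one
row per (subject, visit): ``subject_id, time, y`` plus optional covariate
columns ``z_1..z_p`` and optional per-interval impact columns ``delta_neg,
delta_pos`` (and counts ``n_neg, n_pos``) recorded on the row that closes
the interval. Missing optional columns mean "not recorded", never zero.
Times are real offsets from each subject's first visit. All writers store
full float precision so write-then-read round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .forecast import Forecast
from .inference import (McmcConfig, PosteriorFit, Prior, PriorSpec,
                        adni_style_priors, synthetic_priors)
from .params import ImpactSeries, Trajectory
from .simulate import Dataset

__all__ = [
    "read_longitudinal", "write_longitudinal",
    "dataset_from_frame", "dataset_to_frame",
    "write_latent_sidecar",
    "write_draws", "write_summary",
    "forecasts_to_frame", "write_forecasts", "read_forecasts",
    "write_evaluation",
    "RunConfig", "load_config", "prior_spec_from_dict", "prior_spec_to_dict",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# Longitudinal table
# ---------------------------------------------------------------------------

def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    p = dataset.p_covariates
    has_impacts = any(t.impacts is not None for t in dataset.trajectories)
    for traj in dataset.trajectories:
        for i, (t, y) in enumerate(zip(traj.times, traj.y)):
            row: Dict[str, object] = {"subject_id": traj.subject_id,
                                      "time": t, "y": y}
            for j in range(p):
                row[f"z_{j + 1}"] = traj.z[i, j] if traj.z is not None else np.nan
            if has_impacts:
                if traj.impacts is not None and i >= 1:
                    imp = traj.impacts[i - 1]
                    row.update(delta_neg=imp.delta_neg, delta_pos=imp.delta_pos,
                               n_neg=imp.n_neg, n_pos=imp.n_pos)
                else:
                    row.update(delta_neg=np.nan, delta_pos=np.nan,
                               n_neg=np.nan, n_pos=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def dataset_from_frame(df: pd.DataFrame, source: str = "<frame>") -> Dataset:
    required = {"subject_id", "time", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source}: missing required columns {sorted(missing)}")
    df = df.copy()
    for col in ("time", "y"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = (np.nonzero(bad.isna().to_numpy() & df[col].notna().to_numpy())[0] + 2)
            raise ValueError(
                f"{source}: non-numeric values in column {col!r} at file "
                f"row(s) {rows[:5].tolist()}") from None
    dup = df.duplicated(subset=["subject_id", "time"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["subject_id", "time"]].drop_duplicates()
        raise ValueError(
            f"{source}: duplicate (subject_id, time) pairs: "
            f"{offenders.to_records(index=False).tolist()[:10]}")
    zcols = sorted([c for c in df.columns if c.startswith("z_")],
                   key=lambda c: int(c.split("_")[1]))
    has_impacts = "delta_neg" in df.columns and "delta_pos" in df.columns
    has_counts = "n_neg" in df.columns and "n_pos" in df.columns
    trajs: List[Trajectory] = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("time")
        times = sub["time"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        z = sub[zcols].to_numpy(dtype=float) if zcols else None
        impacts = None
        if has_impacts:
            dn = sub["delta_neg"].to_numpy(dtype=float)[1:]
            dp = sub["delta_pos"].to_numpy(dtype=float)[1:]
            if not (np.isnan(dn).any() or np.isnan(dp).any()):
                if has_counts:
                    nn = sub["n_neg"].to_numpy(dtype=float)[1:]
                    npos = sub["n_pos"].to_numpy(dtype=float)[1:]
                else:
                    nn = npos = np.full(dn.shape, np.nan)
                impacts = [
                    ImpactSeries(
                        i,
                        None if np.isnan(nn[i]) else int(nn[i]),
                        None if np.isnan(npos[i]) else int(npos[i]),
                        float(dn[i]), float(dp[i]))
                    for i in range(dn.shape[0])]
        trajs.append(Trajectory(subject_id=str(sid), times=times, y=y, z=z,
                                impacts=impacts))
    return Dataset(trajs)


def read_longitudinal(path) -> Dataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return dataset_from_frame(df, source=str(path))


def write_longitudinal(dataset: Dataset, path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_latent_sidecar(dataset: Dataset, path) -> None:
    """True latent paths and impacts of a simulated dataset (for testing)."""
    rows = []
    for traj in dataset.trajectories:
        if traj.latent is None:
            continue
        for i, (t, s) in enumerate(zip(traj.times, traj.latent)):
            row = {"subject_id": traj.subject_id, "time": t, "d": s.d, "m": s.m}
            if traj.impacts is not None and i >= 1:
                imp = traj.impacts[i - 1]
                row.update(n_pos=imp.n_pos, n_neg=imp.n_neg,
                           delta_pos=imp.delta_pos, delta_neg=imp.delta_neg)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Posterior artifacts
# ---------------------------------------------------------------------------

def write_draws(fit: PosteriorFit, path) -> None:
    """Tidy draw table: (chain, iteration, parameter, value)."""
    recs = []
    for c in range(fit.n_chains):
        for j, name in enumerate(fit.param_names):
            col = fit.draws[c, :, j]
            recs.append(pd.DataFrame({
                "chain": c, "iteration": np.arange(col.shape[0]),
                "parameter": name, "value": col}))
    out = (pd.concat(recs, ignore_index=True) if recs
           else pd.DataFrame(columns=["chain", "iteration", "parameter", "value"]))
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_summary(fit: PosteriorFit, path) -> None:
    fit.summary.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Forecast artifacts
# ---------------------------------------------------------------------------

def forecasts_to_frame(forecasts: Sequence[Forecast]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": f.subject_id, "target_time": f.target_time,
        "predictive_mean": f.predictive_mean, "q05": f.q05, "q95": f.q95,
    } for f in forecasts])


def write_forecasts(forecasts: Sequence[Forecast], path) -> None:
    forecasts_to_frame(forecasts).to_csv(path, index=False,
                                         float_format=_FLOAT_FMT)


def read_forecasts(path) -> List[Forecast]:
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"subject_id", "target_time", "predictive_mean", "q05", "q95"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing forecast columns {sorted(missing)}")
    return [Forecast(str(r.subject_id), float(r.target_time),
                     float(r.predictive_mean), float(r.q05), float(r.q95))
            for r in df.itertuples()]


def write_evaluation(report, path) -> None:
    """Small key-value text table."""
    lines = [
        f"mse\t{report.mse:.10g}",
        f"mean_subject_mse\t{report.mean_subject_mse:.10g}",
        f"n_predictions\t{report.n_predictions}",
        f"coverage_05_95\t{report.coverage_05_95:.10g}",
    ]
    lines += [f"mse[{s}]\t{v:.10g}" for s, v in sorted(report.per_subject_mse.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_PROFILES = {"synthetic": synthetic_priors, "adni_style": adni_style_priors}


def prior_spec_from_dict(spec: object) -> PriorSpec:
    """Build a PriorSpec from a profile name or an explicit mapping
    ``{priors: {name: {family, loc, scale}}, fixed: {name: value}}``."""
    if isinstance(spec, str):
        try:
            return _PROFILES[spec]()
        except KeyError:
            raise ValueError(
                f"unknown prior profile {spec!r}; known: {sorted(_PROFILES)}") from None
    if not isinstance(spec, dict):
        raise ValueError("priors must be a profile name or a mapping")
    priors = {name: Prior(d["family"], float(d["loc"]), float(d["scale"]))
              for name, d in spec.get("priors", {}).items()}
    fixed = {name: (np.asarray(v, dtype=float) if isinstance(v, (list, tuple))
                    else float(v))
             for name, v in spec.get("fixed", {}).items()}
    return PriorSpec(priors=priors, fixed=fixed)


def prior_spec_to_dict(spec: PriorSpec) -> dict:
    return {
        "priors": {n: {"family": p.family, "loc": p.loc, "scale": p.scale}
                   for n, p in spec.priors.items()},
        "fixed": {n: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
                  for n, v in spec.fixed.items()},
    }


@dataclass
class RunConfig:
    """Structured run configuration mirroring the CLI modes."""

    mode: str
    seed: int
    out_dir: str = "."
    setting_id: Optional[int] = None
    data_path: Optional[str] = None
    priors: object = "synthetic"
    n_chains: int = 3
    n_warmup: int = 1000
    n_samples: int = 1000
    n_particles: int = 512
    latent_treatment: str = "impacts_observed"
    n_sequences: Optional[int] = None
    n_obs: Optional[int] = None
    dt: Optional[float] = None
    i_min: int = 1
    n_theta: int = 200
    n_forecast_draws: int = 400

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fit", "predict", "evaluate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.seed is None:
            raise ValueError("an explicit seed is required")

    def prior_spec(self) -> PriorSpec:
        return prior_spec_from_dict(self.priors)

    def mcmc_config(self) -> McmcConfig:
        return McmcConfig(n_chains=self.n_chains, n_warmup=self.n_warmup,
                          n_samples=self.n_samples, seed=self.seed,
                          latent_treatment=self.latent_treatment,
                          n_particles=self.n_particles)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(**raw)


def write_manifest(out_dir, seed: int, config: Optional[dict] = None) -> Path:
    """Machine-readable run provenance written beside the outputs."""
    from . import __version__
    payload = {"seed": seed, "config": config or {}, "version": __version__}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    payload["config_hash"] = digest
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n",
                    encoding="utf-8")
    return path
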