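"""Presentation-only plotting: traces, posterior densities, prediction bands
and simulated-dataset overviews. No numeric contracts live here."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .forecast import Forecast  # noqa: E402
from .inference import PosteriorFit  # noqa: E402
from .params import Trajectory  # noqa: E402
from .simulate import Dataset  # noqa: E402

__all__ = ["plot_traces", "plot_posteriors", "plot_forecast_band",
           "plot_dataset", "plot_diagnostics"]

logger = logging.getLogger(__name__)


def _empty(obj) -> bool:
    if obj is None:
        return True
    if isinstance(obj, PosteriorFit):
        return not obj.param_names
    if isinstance(obj, Dataset):
        return len(obj.trajectories) == 0
    try:
        return len(obj) == 0
    except TypeError:
        return False


def plot_traces(fit: PosteriorFit, path) -> Optional[Path]:
    """One trace panel per free parameter, one line per chain."""
    if _empty(fit):
        warnings.warn("nothing to plot: no free parameters")
        return None
    k = len(fit.param_names)
    fig, axes = plt.subplots(k, 1, figsize=(7, 1.8 * k), sharex=True,
                             squeeze=False)
    for j, name in enumerate(fit.param_names):
        ax = axes[j, 0]
        for c in range(fit.n_chains):
            ax.plot(fit.draws[c, :, j], lw=0.6)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("iteration (post warm-up)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_posteriors(fit: PosteriorFit, path) -> Optional[Path]:
    """Per-parameter posterior densities (histograms), chains overlaid."""
    if _empty(fit):
        warnings.warn("nothing to plot: no free parameters")
        return None
    k = len(fit.param_names)
    ncol = min(4, k)
    nrow = int(np.ceil(k / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow),
                             squeeze=False)
    for j, name in enumerate(fit.param_names):
        ax = axes[j // ncol, j % ncol]
        for c in range(fit.n_chains):
            ax.hist(fit.draws[c, :, j], bins=40, histtype="step", density=True)
        ax.set_title(name, fontsize=9)
    for j in range(k, nrow * ncol):
        axes[j // ncol, j % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_forecast_band(trajectory: Trajectory, forecasts: Sequence[Forecast],
                       path) -> Optional[Path]:
    """Observed curve with the 5-95% predictive band and, when the latent
    degradation path is known (simulated data), its overlay."""
    if _empty(forecasts):
        warnings.warn("nothing to plot: no forecasts")
        return None
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trajectory.times, trajectory.y, "k.-", label="observed")
    ts = np.array([f.target_time for f in forecasts])
    means = np.array([f.predictive_mean for f in forecasts])
    lo = np.array([f.q05 for f in forecasts])
    hi = np.array([f.q95 for f in forecasts])
    order = np.argsort(ts)
    ax.fill_between(ts[order], lo[order], hi[order], color="red", alpha=0.25,
                    label="5-95% prediction interval")
    ax.plot(ts[order], means[order], "r.-", label="predicted")
    if trajectory.latent is not None:
        d = [s.d for s in trajectory.latent]
        ax2 = ax.twinx()
        ax2.plot(trajectory.times, d, "b--", lw=1, label="latent D")
        ax2.set_ylabel("degradation D(t)", color="b")
    ax.set_xlabel("time")
    ax.set_ylabel("score")
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_dataset(dataset: Dataset, path, max_subjects: int = 6) -> Optional[Path]:
    """Score curves with impact intervals shaded by the dominant sign
    (positive impacts pink, negative blue)."""
    if _empty(dataset):
        warnings.warn("nothing to plot: empty dataset")
        return None
    trajs = dataset.trajectories[:max_subjects]
    fig, axes = plt.subplots(len(trajs), 1, figsize=(7, 2.2 * len(trajs)),
                             sharex=True, squeeze=False)
    for ax, traj in zip(axes[:, 0], trajs):
        ax.plot(traj.times, traj.y, "k.-", lw=0.8)
        if traj.impacts is not None:
            for i, imp in enumerate(traj.impacts):
                if imp.delta_pos == imp.delta_neg:
                    continue
                color = "pink" if imp.delta_pos > imp.delta_neg else "lightblue"
                ax.axvspan(traj.times[i], traj.times[i + 1], color=color,
                           alpha=0.5, lw=0)
        ax.set_ylabel(traj.subject_id, fontsize=8)
    axes[-1, 0].set_xlabel("time")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_diagnostics(obj, out_dir) -> List[Path]:
    """Dispatch on the artifact type and write the matching figure files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if isinstance(obj, PosteriorFit):
        for fn, name in ((plot_traces, "traces.png"),
                         (plot_posteriors, "posteriors.png")):
            p = fn(obj, out_dir / name)
            if p:
                written.append(p)
    elif isinstance(obj, Dataset):
        p = plot_dataset(obj, out_dir / "dataset.png")
        if p:
            written.append(p)
    else:
        raise TypeError(f"cannot plot object of type {type(obj)}")
    return written
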