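"""Likelihood evaluation of simulated metric trajectories against reference
trajectories, and the (sigma0, sigma_m) grid sweep.

The log-likelihood compares simulation means to reference means under a
Gaussian error model, summed over the selected metrics and passages:
``sum -(mean_sim - mu)^2 / (2 sd^2)``.  Additive constants are dropped, so
the maximum attainable value is 0, reached exactly when every simulated mean
equals its reference mean.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .metrics import MetricSeries
from .protocol import ExperimentConfig, run_iterated_experiment

__all__ = [
    "ReferenceMetrics",
    "LikelihoodGrid",
    "loglikelihood",
    "grid_sweep",
    "best_fit",
    "sim_metric_means",
]

# canonical metric names used in reference tables
METRICS = ("clones_remaining_fraction", "gini")


class ReferenceMetrics:
    """Mean and SD of each (metric, passage) across biological replicates."""

    def __init__(self, frame: pd.DataFrame):
        required = {"metric", "passage", "mean", "sd"}
        if not required.issubset(frame.columns):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        if (frame["sd"] <= 0).any():
            raise ValueError("every reference SD must be positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_series(cls, series: MetricSeries, metrics, passages) -> "ReferenceMetrics":
        """Aggregate a simulated/experimental MetricSeries into a reference."""
        rows = []
        for m in metrics:
            mean = series.mean(m)
            sd = series.sd(m)
            for p in passages:
                rows.append((m, int(p), float(mean[p]), float(sd[p])))
        return cls(pd.DataFrame(rows, columns=["metric", "passage", "mean", "sd"]))

    def restricted(self, metrics) -> "ReferenceMetrics":
        return ReferenceMetrics(self.frame[self.frame["metric"].isin(metrics)])

    @property
    def passages(self) -> list[int]:
        return sorted(self.frame["passage"].unique().tolist())

    @property
    def metrics(self) -> list[str]:
        return sorted(self.frame["metric"].unique().tolist())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceMetrics":
        return cls(pd.read_csv(path))


def sim_metric_means(series: MetricSeries, metrics, passages) -> dict:
    """Replicate-mean of each requested (metric, passage) from a run."""
    out = {}
    for m in metrics:
        mean = series.mean(m)
        for p in passages:
            if p not in mean.index:
                raise KeyError(f"simulation has no passage {p} for metric {m}")
            out[(m, int(p))] = float(mean[p])
    return out


def loglikelihood(sim_means: dict, ref: ReferenceMetrics) -> float:
    """Gaussian log-likelihood of simulated means given the reference.

    ``sim_means`` maps ``(metric, passage)`` to the replicate-mean simulated
    value; every (metric, passage) pair in the reference must be present.
    """
    total = 0.0
    for row in ref.frame.itertuples(index=False):
        key = (row.metric, int(row.passage))
        if key not in sim_means:
            raise KeyError(f"simulated means missing {key}")
        if row.sd <= 0:
            raise ValueError("reference SD must be positive")
        total -= (sim_means[key] - row.mean) ** 2 / (2.0 * row.sd**2)
    return total


class LikelihoodGrid:
    """Rectangular (sigma0, sigma_m) grid of log-likelihood values."""

    def __init__(self, sigma0_values, sigma_m_values, frame: pd.DataFrame):
        self.sigma0_values = list(sigma0_values)
        self.sigma_m_values = list(sigma_m_values)
        self.frame = frame

    def loglik_matrix(self) -> np.ndarray:
        return (
            self.frame.pivot(index="sigma0", columns="sigma_m", values="loglik")
            .reindex(index=self.sigma0_values, columns=self.sigma_m_values)
            .to_numpy()
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def grid_sweep(
    sigma0_values,
    sigma_m_values,
    config: ExperimentConfig,
    initial_counts,
    ref: ReferenceMetrics,
    n_reps: int = 10,
    rng: np.random.Generator | None = None,
) -> LikelihoodGrid:
    """Evaluate the log-likelihood on every (sigma0, sigma_m) grid point.

    Each point runs ``n_reps`` fresh replicates of the agent-based
    experiment with its own child RNG stream; all points share the reference
    and the rest of the configuration.  A point whose simulation fails is
    recorded with a NaN log-likelihood rather than dropped.
    """
    sigma0_values = list(sigma0_values)
    sigma_m_values = list(sigma_m_values)
    if not sigma0_values or not sigma_m_values:
        raise ValueError("grids must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for s0 in sigma0_values:
        for sm in sigma_m_values:
            point_cfg = replace(
                config,
                model="abm",
                n_replicates=n_reps,
                abm=replace(config.abm, sigma0=float(s0), sigma_m=float(sm)),
            )
            point_rng = rng.spawn(1)[0]
            row = {"sigma0": float(s0), "sigma_m": float(sm)}
            try:
                series = run_iterated_experiment(point_cfg, initial_counts, point_rng)
                means = sim_metric_means(series, ref.metrics, ref.passages)
                row["loglik"] = loglikelihood(means, ref)
                for (m, p), v in means.items():
                    row[f"{m}@{p}"] = v
            except Exception as exc:  # record failed points as missing
                warnings.warn(f"grid point {s0, sm} failed: {exc}")
                row["loglik"] = np.nan
            rows.append(row)
    return LikelihoodGrid(sigma0_values, sigma_m_values, pd.DataFrame(rows))


def best_fit(grid: LikelihoodGrid) -> tuple[float, float]:
    """(sigma0, sigma_m) maximizing the log-likelihood.

    Ties are broken by the smallest sigma_m, then the smallest sigma0.
    A warning is emitted when the argmax sits on the grid boundary.
    """
    df = grid.frame.dropna(subset=["loglik"])
    if df.empty:
        raise ValueError("no evaluated grid points")
    best = df["loglik"].max()
    tied = df[df["loglik"] == best].sort_values(["sigma_m", "sigma0"])
    s0 = float(tied.iloc[0]["sigma0"])
    sm = float(tied.iloc[0]["sigma_m"])
    on_edge = (
        s0 in (min(grid.sigma0_values), max(grid.sigma0_values))
        or sm in (min(grid.sigma_m_values), max(grid.sigma_m_values))
    )
    if on_edge and (len(grid.sigma0_values) > 1 and len(grid.sigma_m_values) > 1):
        warnings.warn("best fit lies on the grid boundary; widen the grid")
    return s0, sm
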