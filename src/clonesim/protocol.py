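"""The iterated growth-and-passage experiment.

One experiment = initialize a population of ``n_pass`` cells from barcode
read counts, then repeat: grow until ``n_crit`` cells, record metrics, pass
a random sample of ``n_pass`` cells to the next generation.  Any of the four
growth engines (deterministic, stochastic clone-level, stem-cell, agent
based) can drive the growth phase; passage is always sampling without
replacement, except for the deterministic engine whose real-valued clone
sizes are sampled multinomially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import abm as _abm
from .growth import (
    CSCCloneState,
    CSCParams,
    GrowthParams,
    csc_init,
    csc_tau_leap_grow,
    deterministic_grow,
    tau_leap_grow,
)
from .metrics import (
    MetricSeries,
    clones_remaining_fraction,
    count_major_clones,
    gini_coefficient,
)
from .tables import CloneSizeTable

__all__ = [
    "ExperimentConfig",
    "init_from_counts",
    "passage_sample",
    "run_iterated_experiment",
]

MODELS = ("deterministic", "stochastic", "csc", "abm")


@dataclass
class ExperimentConfig:
    """Configuration of one iterated growth-and-passage experiment.

    ``model`` selects the growth engine; the matching parameter block is
    used and the others are ignored.  ``eval_point`` controls whether the
    per-passage metrics are computed on the ``n_pass``-cell sample taken at
    passage ("post") or on the full grown population just before passage
    ("pre").  ``scale`` divides ``n_pass``/``n_crit`` (and the agent-model
    population sizes) by a common factor for desk-scale runs, preserving the
    fold expansion per passage.
    """

    model: str = "stochastic"
    n_pass: int = 300_000
    n_crit: int = 4_000_000
    n_passages: int = 30
    n_replicates: int = 10
    seed: int = 0
    eval_point: str = "post"
    # deterministic engine
    det_r: float = 24.0 / 19.0 * math.log(2.0)
    det_t_growth: float = 3.0
    # clone-level stochastic engine
    growth: GrowthParams = field(default_factory=GrowthParams)
    # stem-cell engine
    csc: CSCParams = field(default_factory=CSCParams)
    tau: float = 0.0005
    # agent-based engine
    abm: "_abm.ABMParams" = field(default_factory=lambda: _abm.ABMParams())

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not self.n_pass < self.n_crit:
            raise ValueError("n_pass must be smaller than n_crit")
        if self.n_passages < 0:
            raise ValueError("n_passages must be >= 0")
        if self.eval_point not in ("post", "pre"):
            raise ValueError("eval_point must be 'post' or 'pre'")

    def scaled(self, factor: float) -> "ExperimentConfig":
        """Shrink all population sizes by ``factor`` (fold expansion kept)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        abm_params = replace(
            self.abm,
            n_master=max(1, round(self.abm.n_master / factor)),
            n_init=max(1, round(self.abm.n_init / factor)),
        )
        return replace(
            self,
            n_pass=max(1, round(self.n_pass / factor)),
            n_crit=max(2, round(self.n_crit / factor)),
            growth=replace(self.growth, n_crit=max(2, round(self.n_crit / factor))),
            abm=abm_params,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "model",
            "n_pass",
            "n_crit",
            "n_passages",
            "n_replicates",
            "seed",
            "eval_point",
            "det_r",
            "det_t_growth",
            "tau",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "growth" in raw:
            kwargs["growth"] = GrowthParams(**raw["growth"])
        if "csc" in raw:
            kwargs["csc"] = CSCParams(**raw["csc"])
        if "abm" in raw:
            kwargs["abm"] = _abm.ABMParams(**raw["abm"])
        cfg = cls(**kwargs)
        if "growth" not in raw:
            cfg = replace(cfg, growth=replace(cfg.growth, n_crit=cfg.n_crit))
        return cfg


def init_from_counts(read_counts, n_pass: int) -> CloneSizeTable:
    """Initial clone sizes proportional to read counts, totalling ``n_pass``.

    Barcodes with zero reads are dropped; ``C0`` is the number of barcodes
    with nonzero reads.  Largest-remainder rounding makes the total exactly
    ``n_pass`` for any input.
    """
    if hasattr(read_counts, "to_dict"):
        read_counts = read_counts.to_dict()
    items = [(b, c) for b, c in read_counts.items() if c > 0]
    if not items:
        raise ValueError("all read counts are zero")
    barcodes = [b for b, _ in items]
    weights = np.array([c for _, c in items], dtype=float)
    sizes = _abm._largest_remainder(weights, n_pass)
    return CloneSizeTable(barcodes, sizes)


def passage_sample(population, n_pass: int, rng: np.random.Generator):
    """Random sample of ``n_pass`` cells without replacement.

    Dispatches on the population type: clone tables use a multivariate
    hypergeometric draw across clones; the stem-cell state samples jointly
    across all (clone, species) cells so stem/age identity is preserved;
    agent populations sample individual cells; real-valued tables (from the
    deterministic engine) fall back to a multinomial draw with probabilities
    proportional to clone size.
    """
    if isinstance(population, _abm.CellPopulation):
        return _abm.abm_passage(population, n_pass, rng)
    if isinstance(population, CSCCloneState):
        flat = population.counts.ravel()
        if int(flat.sum()) < n_pass:
            raise ValueError("population smaller than n_pass")
        sampled = rng.multivariate_hypergeometric(flat, n_pass, method="marginals")
        return CSCCloneState(
            counts=sampled.reshape(population.counts.shape).astype(np.int64),
            x=population.x,
            barcodes=population.barcodes,
        )
    if isinstance(population, CloneSizeTable):
        sizes = np.asarray(population.sizes)
        total = sizes.sum()
        if total < n_pass:
            raise ValueError("population smaller than n_pass")
        if np.issubdtype(sizes.dtype, np.integer):
            sampled = rng.multivariate_hypergeometric(
                sizes, n_pass, method="marginals"
            )
        else:
            sampled = rng.multinomial(n_pass, sizes / total)
        return population.with_sizes(sampled.astype(np.int64))
    raise TypeError(f"cannot passage object of type {type(population)!r}")


def _clone_table(population) -> CloneSizeTable:
    if isinstance(population, _abm.CellPopulation):
        return population.to_clone_table()
    if isinstance(population, CSCCloneState):
        return population.to_table()
    return population


def _metrics(population, table: CloneSizeTable, elapsed: float = 0.0) -> dict:
    out = {
        "clones_remaining_fraction": clones_remaining_fraction(table),
        "gini": gini_coefficient(table),
        "major_clone_count": count_major_clones(table),
        "n_cells": float(table.n),
        "elapsed_days": elapsed,
    }
    if isinstance(population, _abm.CellPopulation):
        out["mean_division_rate"] = population.mean_rate
    return out


def run_iterated_experiment(
    config: ExperimentConfig, initial_counts, rng: np.random.Generator | None = None
) -> MetricSeries:
    """Run all replicates of the experiment and collect per-passage metrics.

    Passage 0 metrics are those of the initialized ``n_pass``-cell
    population.  A stem-cell replicate that goes extinct before reaching
    ``n_crit`` is flagged and keeps its metrics up to the last completed
    passage.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rep_rngs = rng.spawn(config.n_replicates)
    series = MetricSeries()

    table0 = init_from_counts(initial_counts, config.n_pass)
    master = None
    if config.model == "abm":
        master = _abm.build_master_population(table0.to_counts(), config.abm)

    for rep, rep_rng in enumerate(rep_rngs):
        pop = _init_replicate(config, table0, master, rep_rng)
        series.record(rep, 0, _metrics(pop, _clone_table(pop)))
        for passage in range(1, config.n_passages + 1):
            pop, elapsed, extinct = _grow(config, pop, rep_rng)
            if extinct:
                series.flag_extinct(rep)
                break
            if config.eval_point == "pre":
                series.record(
                    rep, passage, _metrics(pop, _clone_table(pop), elapsed)
                )
                pop = passage_sample(pop, config.n_pass, rep_rng)
            else:
                pop = passage_sample(pop, config.n_pass, rep_rng)
                series.record(
                    rep, passage, _metrics(pop, _clone_table(pop), elapsed)
                )
    return series


def _init_replicate(config, table0, master, rng):
    if config.model == "abm":
        return _abm.draw_initial_population(master, config.abm.n_init, rng)
    if config.model == "csc":
        return csc_init(table0, config.csc, rng)
    if config.model == "deterministic":
        return table0.with_sizes(np.asarray(table0.sizes, dtype=float))
    return table0.copy()


def _grow(config, pop, rng):
    """Common growth contract: -> (population, elapsed_time, extinct)."""
    if config.model == "deterministic":
        grown = deterministic_grow(pop, config.det_r, config.det_t_growth)
        return grown, config.det_t_growth, False
    if config.model == "stochastic":
        params = replace(config.growth, n_crit=config.n_crit)
        grown, elapsed = tau_leap_grow(pop, params, rng)
        return grown, elapsed, False
    if config.model == "csc":
        grown, elapsed, extinct = csc_tau_leap_grow(
            pop, config.csc, config.tau, config.n_crit, rng
        )
        return grown, elapsed, extinct
    grown, elapsed = _abm.abm_grow(pop, config.n_crit, rng, sigma_m=config.abm.sigma_m)
    return grown, elapsed, False
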