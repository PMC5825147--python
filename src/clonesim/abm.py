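"""Agent-based model of cells with heritable, mutating division rates.

Every cell carries a barcode and its own division rate.  Division is driven
by a first-reaction event queue: at creation each cell draws an exponential
waiting time ``-ln(R) / r`` and events are processed in time order.  Upon
division both children draw a fresh rate ``r_parent * max(Y, 0)`` with
``Y ~ Normal(1, sigma_m)`` and inherit the barcode.  There is no death, so
the population size never decreases.

Replicates share a single *master population* whose barcode-to-rate
assignment is a pure function of the input counts, the parameters and
``master_seed``; each replicate then samples its starting cells from that
master with its own stream.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .tables import CloneSizeTable

__all__ = [
    "ABMParams",
    "CellPopulation",
    "build_master_population",
    "draw_initial_population",
    "schedule_division",
    "divide",
    "abm_grow",
]


@dataclass
class ABMParams:
    r0: float = 1.0
    sigma0: float = 0.0
    sigma_m: float = 0.0
    n_master: int = 5_000_000
    n_init: int = 300_000
    master_seed: int = 0

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")
        if self.sigma0 < 0 or self.sigma_m < 0:
            raise ValueError("rate SDs must be >= 0")
        if self.n_init > self.n_master:
            raise ValueError("n_init cannot exceed n_master")


class CellPopulation:
    """Cells with barcodes, rates and (optionally) scheduled division times.

    ``barcode_ids`` is the fixed barcode universe (index -> identifier);
    ``barcodes`` holds one index per cell.  A master population carries no
    event queue; populations entering a simulation do.
    """

    def __init__(self, barcode_ids, barcodes, rates, times=None, now=0.0):
        self.barcode_ids = list(barcode_ids)
        self.barcodes = list(barcodes)
        self.rates = list(rates)
        self.times = list(times) if times is not None else None
        self.now = now
        if self.times is not None:
            self.heap = [
                (t, i) for i, t in enumerate(self.times) if t != math.inf
            ]
            heapq.heapify(self.heap)
        else:
            self.heap = None

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates))

    def to_clone_table(self) -> CloneSizeTable:
        """Cell counts per barcode over the full barcode universe."""
        counts = np.bincount(
            np.asarray(self.barcodes, dtype=np.int64),
            minlength=len(self.barcode_ids),
        )
        return CloneSizeTable(self.barcode_ids, counts)

    def rate_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "barcode": [self.barcode_ids[b] for b in self.barcodes],
                "rate": self.rates,
            }
        )


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    quota = weights * (total / weights.sum())
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def build_master_population(counts, params: ABMParams) -> CellPopulation:
    """Create the shared master population from barcode read counts.

    ``n_master`` cells receive barcodes matching the input frequencies under
    largest-remainder rounding; every cell's rate is ``r0 * max(X, 0)`` with
    ``X ~ Normal(1, sigma0)`` drawn from a generator seeded with
    ``master_seed`` only, so the barcode-to-rate assignment is identical
    across replicates.
    """
    if hasattr(counts, "to_dict"):
        counts = counts.to_dict()
    ids = list(counts)
    weights = np.array([counts[b] for b in ids], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all barcode counts are zero")
    alloc = _largest_remainder(weights, params.n_master)
    barcodes = np.repeat(np.arange(len(ids)), alloc)
    master_rng = np.random.default_rng(params.master_seed)
    x = master_rng.normal(1.0, params.sigma0, size=params.n_master)
    rates = params.r0 * np.maximum(x, 0.0)
    return CellPopulation(ids, barcodes.tolist(), rates.tolist())


def schedule_division(rate: float, now: float, rng: np.random.Generator) -> float:
    """Absolute time of a cell's next division: ``now - ln(R) / rate``.

    ``R`` is uniform on (0, 1]; a cell with rate 0 never divides and gets
    an infinite event time.
    """
    if rate <= 0.0:
        return math.inf
    return now - math.log(1.0 - rng.random()) / rate


def divide(rate_parent: float, sigma_m: float, rng: np.random.Generator) -> tuple[float, float]:
    """Division rates of the two children of a dividing cell.

    Each child independently draws ``r_parent * max(Y, 0)`` with
    ``Y ~ Normal(1, sigma_m)``; with ``sigma_m == 0`` both children keep the
    parent's rate exactly.
    """
    if sigma_m <= 0.0:
        return rate_parent, rate_parent
    y1, y2 = rng.normal(1.0, sigma_m, size=2)
    return (
        rate_parent * (y1 if y1 > 0.0 else 0.0),
        rate_parent * (y2 if y2 > 0.0 else 0.0),
    )


def draw_initial_population(
    master: CellPopulation, n_init: int, rng: np.random.Generator
) -> CellPopulation:
    """Sample ``n_init`` cells uniformly without replacement from the master.

    Sampled cells keep their barcode and rate; division times are freshly
    scheduled from time 0.
    """
    if n_init > len(master):
        raise ValueError("n_init cannot exceed the master population size")
    idx = rng.choice(len(master), size=n_init, replace=False)
    barcodes = [master.barcodes[i] for i in idx]
    rates = [master.rates[i] for i in idx]
    times = [schedule_division(r, 0.0, rng) for r in rates]
    return CellPopulation(master.barcode_ids, barcodes, rates, times=times, now=0.0)


def abm_grow(
    pop: CellPopulation, n_crit: int, rng: np.random.Generator, sigma_m: float = 0.0
) -> tuple[CellPopulation, float]:
    """Process division events in time order until the population reaches
    ``n_crit`` cells.

    Mutates ``pop`` in place and returns it with the elapsed simulated time.
    Raises if the queue empties before ``n_crit`` is reached (no cell can
    divide).
    """
    if pop.heap is None:
        raise ValueError("population has no event queue; draw it for simulation first")
    heap = pop.heap
    barcodes = pop.barcodes
    rates = pop.rates
    times = pop.times
    start = pop.now
    now = start
    n = len(barcodes)
    if n >= n_crit:
        return pop, 0.0
    push = heapq.heappush
    pop_event = heapq.heappop
    log = math.log
    random = rng.random
    while n < n_crit:
        if not heap:
            raise RuntimeError("no divisible cells left; n_crit is unreachable")
        now, i = pop_event(heap)
        r1, r2 = divide(rates[i], sigma_m, rng)
        # child 1 reuses the parent's slot
        rates[i] = r1
        if r1 > 0.0:
            t1 = now - log(1.0 - random()) / r1
            times[i] = t1
            push(heap, (t1, i))
        else:
            times[i] = math.inf
        j = n
        barcodes.append(barcodes[i])
        rates.append(r2)
        if r2 > 0.0:
            t2 = now - log(1.0 - random()) / r2
            times.append(t2)
            push(heap, (t2, j))
        else:
            times.append(math.inf)
        n += 1
    pop.now = now
    return pop, now - start


def abm_passage(
    pop: CellPopulation, n_pass: int, rng: np.random.Generator
) -> CellPopulation:
    """Uniform sample of ``n_pass`` cells without replacement.

    Surviving cells keep their barcode, rate and scheduled division time
    (the exponential clock is memoryless, so the schedule remains valid).
    """
    if n_pass > len(pop):
        raise ValueError("cannot passage more cells than are present")
    idx = rng.choice(len(pop), size=n_pass, replace=False)
    barcodes = [pop.barcodes[i] for i in idx]
    rates = [pop.rates[i] for i in idx]
    times = [pop.times[i] for i in idx]
    return CellPopulation(pop.barcode_ids, barcodes, rates, times=times, now=pop.now)
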