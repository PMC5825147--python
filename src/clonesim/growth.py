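"""Clone-level growth engines.

Three ways to grow a population of clones until a critical size is reached:

* :func:`deterministic_grow` — exponential growth of real-valued clone sizes
  for a fixed duration.
* :func:`tau_leap_grow` — a pure-birth process advanced in fixed leaps, each
  clone gaining a Poisson number of cells per leap.
* :func:`csc_tau_leap_grow` — the same leaping scheme applied to an
  age-structured population of stem cells (unlimited self-renewal) and
  differentiated cells that divide at most ``M`` times and then die.

All stochastic engines draw exclusively from the ``numpy.random.Generator``
they are handed, so runs are reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tables import CloneSizeTable

__all__ = [
    "GrowthParams",
    "CSCParams",
    "CSCCloneState",
    "deterministic_grow",
    "tau_leap_grow",
    "csc_init",
    "csc_tau_leap_grow",
    "beta",
    "doubling_time",
    "doubling_time_scan",
    "poisson_field",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass
class GrowthParams:
    """Parameters of the stochastic birth process.

    ``r`` is the division rate (per day), ``tau`` the leap step (days) and
    ``n_crit`` the critical population size at which growth stops.
    """

    r: float = 1.0
    tau: float = 0.0005
    n_crit: int = 4_000_000

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("division rate must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.n_crit <= 0:
            raise ValueError("n_crit must be > 0")


@dataclass
class CSCParams:
    """Parameters of the stem-cell growth model.

    A stem-cell division yields two stem cells with probability ``p1``, a
    stem cell plus a fresh differentiated cell with probability ``p2``, or
    two differentiated cells with probability ``p3``.  Differentiated cells
    divide at rate ``r_dc``, age by one class per division, and die at rate
    ``r_dc`` once they reach age ``M``.  ``csc0`` is the initial stem-cell
    fraction.  ``sigma_r`` > 0 gives every clone a heritable rate multiplier
    drawn from Normal(1, sigma_r), clamped at 0.
    """

    p1: float = 0.5
    p2: float = 0.5
    p3: float = 0.0
    r_csc: float = 1.0
    r_dc: float = 24.0 / 19.0
    M: int = 10
    csc0: float = 0.05
    sigma_r: float = 0.0

    def __post_init__(self):
        probs = (self.p1, self.p2, self.p3)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("division probabilities must be in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("p1 + p2 + p3 must equal 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0.0 <= self.csc0 <= 1.0:
            raise ValueError("csc0 must be in [0, 1]")
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be >= 0")


def beta(params: CSCParams) -> tuple[float, str]:
    """Long-run growth parameter ``(p1 - p3) * r_csc`` and its regime.

    Returns the rate together with a label: ``"growth"`` for positive values,
    ``"equilibrium"`` at zero, ``"extinction"`` for negative values.
    """
    b = (params.p1 - params.p3) * params.r_csc
    if b > 0:
        regime = "growth"
    elif b < 0:
        regime = "extinction"
    else:
        regime = "equilibrium"
    return b, regime


# ---------------------------------------------------------------------------
# deterministic model

def deterministic_grow(table: CloneSizeTable, r: float, t_growth: float) -> CloneSizeTable:
    """Grow every clone exponentially: size -> size * exp(r * t_growth).

    Sizes become real-valued; relative clone frequencies are unchanged.
    """
    if r < 0:
        raise ValueError("division rate must be >= 0")
    if t_growth < 0:
        raise ValueError("growth duration must be >= 0")
    factor = math.exp(r * t_growth)
    return table.with_sizes(np.asarray(table.sizes, dtype=float) * factor)


# ---------------------------------------------------------------------------
# Poisson leaping

def poisson_field(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Independent Poisson draws for a vector of intensities.

    When the total intensity is small relative to the number of entries the
    draw is performed by Poisson superposition: sample the total event count
    once, then allocate events to entries proportionally to their intensity.
    This is distributionally identical to elementwise ``rng.poisson(lam)``
    (thinning of a Poisson process) but orders of magnitude faster for the
    sparse-event regime the leap step puts us in.
    """
    lam = np.asarray(lam, dtype=float)
    total = float(lam.sum())
    if total <= 0.0:
        return np.zeros(lam.size, dtype=np.int64)
    if total < 0.1 * lam.size:
        k = rng.poisson(total)
        counts = np.zeros(lam.size, dtype=np.int64)
        if k > 0:
            cum = np.cumsum(lam)
            idx = np.searchsorted(cum, rng.random(k) * total, side="right")
            np.minimum(idx, lam.size - 1, out=idx)
            counts = np.bincount(idx, minlength=lam.size).astype(np.int64)
        return counts
    return rng.poisson(lam).astype(np.int64)


def tau_leap_grow(
    table: CloneSizeTable,
    params: GrowthParams,
    rng: np.random.Generator,
    t_max: float | None = None,
) -> tuple[CloneSizeTable, float]:
    """Grow clones by Poisson leaps until the total reaches ``n_crit``.

    Each leap of length ``tau`` adds ``k_i ~ Poisson(r * N_i * tau)`` cells to
    clone ``i``.  Growth stops at the first leap where the total is at least
    ``n_crit`` (the overshoot is kept) or, if ``t_max`` is given, once the
    elapsed time reaches ``t_max``.

    Returns the grown table and the elapsed simulated time (days).
    """
    sizes = np.asarray(table.sizes)
    if not np.issubdtype(sizes.dtype, np.integer):
        if np.any(sizes != np.floor(sizes)):
            raise ValueError("stochastic growth requires integer clone sizes")
        sizes = sizes.astype(np.int64)
    else:
        sizes = sizes.astype(np.int64)
    total = int(sizes.sum())
    if total == 0:
        raise ValueError("cannot grow an empty population")
    t = 0.0
    r_tau = params.r * params.tau
    while total < params.n_crit:
        if t_max is not None and t >= t_max:
            break
        k = poisson_field(rng, r_tau * sizes)
        sizes = sizes + k
        total += int(k.sum())
        t += params.tau
    return table.with_sizes(sizes), t


# ---------------------------------------------------------------------------
# stem-cell model

@dataclass
class CSCCloneState:
    """Age-structured per-clone counts for the stem-cell model.

    ``counts`` has shape ``(C, M + 2)``: column 0 holds stem cells, columns
    ``1 .. M+1`` hold differentiated cells of age ``0 .. M``.  ``x`` is the
    per-clone heritable rate multiplier.
    """

    counts: np.ndarray
    x: np.ndarray
    barcodes: np.ndarray = field(default=None)

    @property
    def M(self) -> int:
        return self.counts.shape[1] - 2

    @property
    def clone_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def csc_fraction(self) -> float:
        tot = self.total
        return float(self.counts[:, 0].sum()) / tot if tot else 0.0

    def to_table(self) -> CloneSizeTable:
        barcodes = self.barcodes
        if barcodes is None:
            barcodes = np.array(
                [f"clone{i}" for i in range(self.counts.shape[0])], dtype=object
            )
        return CloneSizeTable(barcodes, self.clone_sizes)


def csc_init(
    table: CloneSizeTable, params: CSCParams, rng: np.random.Generator
) -> CSCCloneState:
    """Split each clone into stem cells and aged differentiated cells.

    Per clone of size ``N``: ``round(csc0 * N)`` stem cells; the remainder is
    spread evenly (with floor) over all ``M + 1`` differentiated-cell age
    classes ``0 .. M``; any cells left over by the rounding are placed
    uniformly at random over the differentiated-cell classes of that clone.
    Per-clone totals are preserved exactly.

    Spreading over all age classes (rather than only the ``M`` dividing
    ones) and keeping the stem-cell count at its rounded value is what
    reproduces the documented 19 h population doubling time at the default
    parameters; the deterministic limit of the alternative conventions lands
    more than 1 h further away.
    """
    sizes = np.asarray(table.sizes)
    if np.any(sizes != np.floor(sizes)):
        raise ValueError("stem-cell model requires integer clone sizes")
    sizes = sizes.astype(np.int64)
    C = sizes.size
    M = params.M
    n_csc = np.minimum(np.floor(params.csc0 * sizes + 0.5).astype(np.int64), sizes)
    rem = sizes - n_csc
    per_class = rem // (M + 1)
    counts = np.zeros((C, M + 2), dtype=np.int64)
    counts[:, 0] = n_csc
    counts[:, 1:] = per_class[:, None]
    leftover = rem - per_class * (M + 1)
    if leftover.sum() > 0:
        clone_idx = np.repeat(np.arange(C), leftover)
        species = rng.integers(1, M + 2, size=clone_idx.size)
        np.add.at(counts, (clone_idx, species), 1)
    if params.sigma_r > 0:
        x = rng.normal(1.0, params.sigma_r, size=C)
        np.maximum(x, 0.0, out=x)
    else:
        x = np.ones(C)
    return CSCCloneState(counts=counts, x=x, barcodes=table.barcodes)


def csc_tau_leap_grow(
    state: CSCCloneState,
    params: CSCParams,
    tau: float,
    n_crit: int,
    rng: np.random.Generator,
    t_max: float | None = None,
) -> tuple[CSCCloneState, float, bool]:
    """Advance the stem-cell model by Poisson leaps until ``n_crit`` cells.

    Five transitions fire per clone and leap, each with a Poisson count of
    mean ``rate * count * tau`` (rates scaled by the clone multiplier):
    stem self-renewal, asymmetric division, symmetric commitment (two fresh
    differentiated cells), differentiated division into the next age class,
    and death of the oldest age class.  Counts removed by a transition are
    clamped to the cells available at the start of the leap so no count goes
    negative.

    Returns ``(state, elapsed_time, extinct)``; extinction of the whole
    population is a valid terminal outcome, not an error.
    """
    counts = state.counts.astype(np.int64, copy=True)
    x = state.x
    M = state.M
    t = 0.0
    total = int(counts.sum())
    if total == 0:
        raise ValueError("cannot grow an empty population")
    uniform_x = not np.any(x != 1.0)
    l1 = params.p1 * params.r_csc * tau
    l2 = params.p2 * params.r_csc * tau
    l3 = params.p3 * params.r_csc * tau
    ld = params.r_dc * tau
    while 0 < total < n_crit:
        if t_max is not None and t >= t_max:
            break
        # Event counts are drawn by Poisson superposition: one Poisson draw
        # for the total of each transition family, then events allocated to
        # (clone, species) entries proportionally to their intensities.
        # This is distributionally identical to an entrywise Poisson leap
        # but costs O(events) instead of O(C * M) in the updates.
        # intensity profiles, all from the state at the start of the leap
        csc = counts[:, 0]
        wcsc = csc if uniform_x else x * csc
        scsc = float(wcsc.sum())
        cum_csc = np.cumsum(wcsc) if scsc > 0.0 else None
        dc = counts[:, 1:]
        wdc = dc.ravel() if uniform_x else (x[:, None] * dc).ravel()
        sdc = float(wdc.sum())
        cum_dc = np.cumsum(wdc) if sdc > 0.0 else None
        delta = 0

        def _allocate(cum, s, K):
            u = rng.random(K) * s
            idx = np.searchsorted(cum, u, side="right")
            np.minimum(idx, cum.size - 1, out=idx)
            return np.unique(idx, return_counts=True)

        # stem-cell transitions share the same per-clone intensity profile
        k3_info = None
        if cum_csc is not None:
            K1 = rng.poisson(l1 * scsc)
            if K1:
                pos, k = _allocate(cum_csc, scsc, K1)
                counts[pos, 0] += k
                delta += K1
            K2 = rng.poisson(l2 * scsc)
            if K2:
                pos, k = _allocate(cum_csc, scsc, K2)
                counts[pos, 1] += k
                delta += K2
            if l3 > 0.0:
                K3 = rng.poisson(l3 * scsc)
                if K3:
                    k3_info = _allocate(cum_csc, scsc, K3)

        # differentiated cells: one weight field over all age classes;
        # events in ages < M are divisions, events at age M are deaths
        if cum_dc is not None:
            Kd = rng.poisson(ld * sdc)
            if Kd:
                pos, k = _allocate(cum_dc, sdc, Kd)
                ci, mi = np.divmod(pos, M + 1)
                np.minimum(k, counts[ci, 1 + mi], out=k)  # clamp removals
                counts[ci, 1 + mi] -= k
                div = mi < M
                counts[ci[div], 2 + mi[div]] += 2 * k[div]
                delta += int(k[div].sum()) - int(k[~div].sum())

        # symmetric commitment applied last, clamped to available stem cells
        if k3_info is not None:
            pos, k = k3_info
            np.minimum(k, counts[pos, 0], out=k)
            counts[pos, 0] -= k
            counts[pos, 1] += 2 * k
            delta += int(k.sum())

        total += delta
        t += tau
    new_state = CSCCloneState(counts=counts, x=x, barcodes=state.barcodes)
    return new_state, t, total == 0


# ---------------------------------------------------------------------------
# doubling time

def doubling_time(n_start: float, n_end: float, t_growth: float) -> float:
    """Population doubling time inferred from one growth phase.

    ``t_growth * ln(2) / ln(n_end / n_start)``; the result carries the same
    time unit as ``t_growth``.
    """
    if n_start <= 0 or n_end <= n_start:
        raise ValueError("doubling time requires n_end > n_start > 0")
    if t_growth <= 0:
        raise ValueError("growth duration must be positive")
    return t_growth * math.log(2.0) / math.log(n_end / n_start)


def doubling_time_scan(
    M_values,
    r_dc_values,
    params: CSCParams,
    initial_table: CloneSizeTable,
    n_crit: int,
    tau: float,
    reps: int,
    rng: np.random.Generator,
    target_hours: float = 19.0,
):
    """Deviation of the simulated doubling time from a target, on a grid.

    For every combination of maximum differentiated-cell age ``M`` and
    differentiated division rate ``r_dc``, runs ``reps`` growth phases from
    ``initial_table`` to ``n_crit`` and reports the mean doubling time (hours)
    minus ``target_hours``.  Parameter sets whose populations go extinct
    before reaching ``n_crit`` are reported as NaN.
    """
    from dataclasses import replace

    M_values = list(M_values)
    r_dc_values = list(r_dc_values)
    if not M_values or not r_dc_values:
        raise ValueError("scan grids must be non-empty")
    out = np.full((len(M_values), len(r_dc_values)), np.nan)
    for i, M in enumerate(M_values):
        for j, r_dc in enumerate(r_dc_values):
            p = replace(params, M=int(M), r_dc=float(r_dc))
            times = []
            for _ in range(reps):
                state = csc_init(initial_table, p, rng)
                n0 = state.total
                grown, elapsed, extinct = csc_tau_leap_grow(
                    state, p, tau, n_crit, rng
                )
                if extinct or grown.total <= n0:
                    times = None
                    break
                times.append(doubling_time(n0, grown.total, elapsed * 24.0))
            if times:
                out[i, j] = float(np.mean(times)) - target_hours
    return out
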