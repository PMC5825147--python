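"""Summary statistics of clonal dominance.

All metrics operate on a :class:`~clonesim.tables.CloneSizeTable` and are
normalized by the initial clone count ``C0``; extinct clones enter every
formula with size 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import CloneSizeTable

__all__ = [
    "gini_coefficient",
    "clone_loss",
    "clones_remaining_fraction",
    "count_major_clones",
    "dominance_curve",
    "MetricSeries",
]


def gini_coefficient(table: CloneSizeTable) -> float:
    """Gini coefficient of the clone-size distribution.

    Computes ``sum_i sum_j |N_i - N_j| / (2 * C0 * n)`` over all ``C0``
    initial clones (extinct clones contribute size 0), using the sorted-rank
    identity rather than the O(C0^2) double sum.

    Returns a value in ``[0, 1)``: 0 for perfect equality, ``(C0-1)/C0``
    when a single clone holds the whole population.

    Raises
    ------
    ValueError
        If the population is empty (``n == 0``).
    """
    n = table.n
    if n <= 0:
        raise ValueError("Gini coefficient is undefined for an empty population")
    c0 = table.C0
    x = np.sort(np.asarray(table.sizes, dtype=float))
    # sum_{i,j} |x_i - x_j| = 2 * sum_i (2i - C0 - 1) x_(i), i = 1..C0 ascending
    ranks = 2.0 * np.arange(1, c0 + 1) - c0 - 1.0
    return float(np.dot(ranks, x) / (c0 * n))


def clone_loss(table: CloneSizeTable) -> float:
    """Percentage of the initial clones that are extinct (size 0)."""
    return 100.0 * (table.C0 - table.n_alive) / table.C0


def clones_remaining_fraction(table: CloneSizeTable) -> float:
    """Fraction of the initial clones still alive, in [0, 1]."""
    return table.n_alive / table.C0


def count_major_clones(table: CloneSizeTable, threshold: float = 0.01) -> int:
    """Number of clones holding strictly more than ``threshold`` of all cells.

    The default threshold of 1% defines a "major clone"; the comparison is
    strict, so a clone at exactly 1% does not count.
    """
    n = table.n
    if n <= 0:
        raise ValueError("major clones are undefined for an empty population")
    return int(np.count_nonzero(np.asarray(table.sizes, dtype=float) / n > threshold))


def dominance_curve(table: CloneSizeTable) -> np.ndarray:
    """Cumulative clone fraction vs cumulative population fraction.

    Clones are sorted from large to small; the k-th point gives the
    percentage of clones (out of ``C0``) in the k largest clones and the
    percentage of the population those clones hold.  The curve is monotone
    non-decreasing, concave in the population coordinate, and ends at
    (100, 100).

    Returns
    -------
    ndarray of shape (C0, 2)
        Columns ``(percent_of_clones, percent_of_population)``.
    """
    n = table.n
    if n <= 0:
        raise ValueError("dominance curve is undefined for an empty population")
    sizes = np.sort(np.asarray(table.sizes, dtype=float))[::-1]
    pct_clones = 100.0 * np.arange(1, table.C0 + 1) / table.C0
    pct_pop = 100.0 * np.cumsum(sizes) / n
    return np.column_stack([pct_clones, pct_pop])


class MetricSeries:
    """Per-passage metrics across replicates of an iterated experiment.

    Stored as long-format rows (replicate, passage, metric, value); the
    ``mean``/``sd`` helpers aggregate across replicates the way the
    experiments are reported (metric computed per replicate first, then
    averaged).
    """

    def __init__(self):
        self._rows = []
        self.extinct_replicates: set[int] = set()

    def record(self, replicate: int, passage: int, metrics: dict) -> None:
        for name, value in metrics.items():
            self._rows.append((replicate, passage, name, float(value)))

    def flag_extinct(self, replicate: int) -> None:
        self.extinct_replicates.add(replicate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._rows, columns=["replicate", "passage", "metric", "value"]
        )

    def values(self, metric: str) -> pd.DataFrame:
        """Replicate x passage matrix for one metric."""
        df = self.to_frame()
        df = df[df["metric"] == metric]
        return df.pivot(index="replicate", columns="passage", values="value")

    def mean(self, metric: str) -> pd.Series:
        return self.values(metric).mean(axis=0)

    def sd(self, metric: str) -> pd.Series:
        return self.values(metric).std(axis=0, ddof=1)

    @property
    def metrics(self) -> list[str]:
        return sorted({r[2] for r in self._rows})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MetricSeries":
        out = cls()
        df = pd.read_csv(path)
        for row in df.itertuples(index=False):
            out._rows.append(
                (int(row.replicate), int(row.passage), str(row.metric), float(row.value))
            )
        return out
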