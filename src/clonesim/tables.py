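"""Clone-size bookkeeping.

A :class:`CloneSizeTable` records the size of every clone that was present at
initialization.  Extinct clones are retained with size 0 so that the initial
clone count ``C0`` stays fixed for the lifetime of the table; all dominance
metrics are normalized by ``C0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CloneSizeTable"]


class CloneSizeTable:
    """Per-barcode clone sizes with a fixed initial clone count.

    Parameters
    ----------
    barcodes : sequence of str
        Barcode identifier per clone; one entry per initial clone.
    sizes : array-like
        Cell count per clone.  Integer for the stochastic models; the
        deterministic growth model is allowed to hold real-valued sizes.

    Notes
    -----
    ``C0`` equals the number of clones at initialization and never changes;
    clones that later go extinct keep their row with size 0.
    """

    def __init__(self, barcodes, sizes):
        barcodes = np.asarray(barcodes, dtype=object)
        sizes = np.asarray(sizes)
        if barcodes.shape != sizes.shape or barcodes.ndim != 1:
            raise ValueError("barcodes and sizes must be 1-D and equal length")
        if sizes.size == 0:
            raise ValueError("a clone table needs at least one clone")
        if np.any(sizes < 0):
            raise ValueError("clone sizes must be non-negative")
        self.barcodes = barcodes
        self.sizes = sizes.copy()

    # -- basic accessors ---------------------------------------------------

    @property
    def C0(self) -> int:
        """Number of clones at initialization (fixed)."""
        return self.sizes.size

    @property
    def n(self) -> float:
        """Total number of cells."""
        return self.sizes.sum()

    @property
    def n_alive(self) -> int:
        """Number of clones with at least one cell."""
        return int(np.count_nonzero(self.sizes))

    def with_sizes(self, sizes) -> "CloneSizeTable":
        """Return a new table with the same barcodes but different sizes."""
        return CloneSizeTable(self.barcodes, sizes)

    def copy(self) -> "CloneSizeTable":
        return CloneSizeTable(self.barcodes, self.sizes)

    def __len__(self) -> int:
        return self.C0

    def __repr__(self) -> str:
        return (
            f"CloneSizeTable(C0={self.C0}, alive={self.n_alive}, n={self.n})"
        )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_counts(cls, counts) -> "CloneSizeTable":
        """Build a table from a mapping/Series of barcode -> count."""
        if isinstance(counts, pd.Series):
            counts = counts.to_dict()
        barcodes = list(counts)
        sizes = [counts[b] for b in barcodes]
        return cls(barcodes, sizes)

    def to_counts(self) -> dict:
        return dict(zip(self.barcodes.tolist(), self.sizes.tolist()))

    @classmethod
    def from_tsv(cls, path) -> "CloneSizeTable":
        """Read a two-column (barcode, count) TSV, with or without header."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError("expected two tab-separated columns")
        first = str(df.iloc[0, 1])
        try:
            float(first)
        except ValueError:  # header row
            df = df.iloc[1:]
        sizes = pd.to_numeric(df.iloc[:, 1])
        vals = sizes.to_numpy()
        if np.all(vals == np.floor(vals)):
            vals = vals.astype(np.int64)
        return cls(df.iloc[:, 0].astype(str).to_numpy(), vals)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"barcode": self.barcodes, "count": self.sizes}).to_csv(
            path, sep="\t", index=False, header=False
        )
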