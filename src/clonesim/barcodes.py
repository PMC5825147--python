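"""Barcode sequence I/O and synthetic-data generation.

Covers the read-level side of the pipeline: counting exact barcode matches
in FASTQ data above a quality threshold, building a filtered reference
library from replicate plasmid counts, and the generators used to test the
whole pipeline without external downloads — synthetic initial clone-size
distributions, synthetic FASTQ reads, and a spurious-read contamination
model confined to the reference library.

No clustering or error correction is performed anywhere: counting is by
exact sequence identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReferenceLibrary",
    "BarcodeLocator",
    "extract_barcodes",
    "build_reference_library",
    "filter_counts_by_library",
    "synth_initial_distribution",
    "synth_fastq",
    "synth_library",
    "contaminate_with_spurious_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class BarcodeLocator:
    """Fixed position of the barcode within a read: ``offset`` and ``length``.

    ``length=None`` takes the rest of the read.  The read layout of any
    particular library is not knowable from counts alone, so both fields are
    plain configuration.
    """

    offset: int = 0
    length: int | None = None

    def slice(self, seq: str) -> str:
        end = None if self.length is None else self.offset + self.length
        return seq[self.offset : end]


class ReferenceLibrary:
    """Admitted barcode sequences with their pooled frequencies.

    Frequencies are normalized to sum to 1 over the admitted barcodes;
    ``n_library`` is the number of admitted barcodes.
    """

    def __init__(self, frequencies: dict):
        if not frequencies:
            raise ValueError("a reference library cannot be empty")
        total = float(sum(frequencies.values()))
        if total <= 0:
            raise ValueError("library frequencies must have a positive sum")
        self.frequencies = {b: f / total for b, f in frequencies.items()}

    @property
    def n_library(self) -> int:
        return len(self.frequencies)

    @property
    def barcodes(self) -> list[str]:
        return list(self.frequencies)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.frequencies

    def __len__(self) -> int:
        return self.n_library

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for b, f in self.frequencies.items():
                fh.write(f"{b}\t{f:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceLibrary":
        freqs = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                seq, freq = line.split("\t")[:2]
                freqs[seq] = float(freq)
        return cls(freqs)


def _mean_phred(qual: str, offset: int) -> float:
    return sum(ord(c) - offset for c in qual) / len(qual)


def extract_barcodes(
    handle,
    quality_threshold: float = 56.0,
    locator: BarcodeLocator = BarcodeLocator(),
    phred_offset: int = 33,
) -> dict:
    """Exact-match barcode counts from a FASTQ stream.

    The barcode region of every read whose quality statistic (mean per-base
    Phred score over the barcode region) is at least ``quality_threshold``
    is counted by exact sequence identity; reads below the threshold
    contribute nothing.  No clustering is applied.

    ``handle`` may be a path or an open text handle.  Malformed records
    raise a ``ValueError`` naming the record index.
    """
    close = False
    if isinstance(handle, (str, bytes)) or hasattr(handle, "__fspath__"):
        handle = open(handle)
        close = True
    counts: dict[str, int] = {}
    index = 0
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}")
            barcode = locator.slice(seq)
            qregion = locator.slice(qual)
            if not barcode or len(barcode) != len(qregion):
                raise ValueError(f"malformed FASTQ record at index {index}")
            if any(ord(c) < phred_offset for c in qregion):
                raise ValueError(
                    f"quality characters below encoding offset {phred_offset} "
                    f"at record {index}; wrong quality encoding?"
                )
            if _mean_phred(qregion, phred_offset) >= quality_threshold:
                counts[barcode] = counts.get(barcode, 0) + 1
            index += 1
    finally:
        if close:
            handle.close()
    return counts


def build_reference_library(
    replicate_counts,
    min_freq: float = 2e-6,
    min_replicates: int = 2,
) -> ReferenceLibrary:
    """Merge replicate plasmid-library counts into a filtered reference.

    A barcode is admitted iff its pooled frequency (summed count over all
    replicates divided by the grand total) is at least ``min_freq`` — default
    0.0002% — AND it appears in at least ``min_replicates`` replicate tables.
    Frequencies of the admitted barcodes are renormalized to sum to 1.
    """
    replicate_counts = list(replicate_counts)
    if len(replicate_counts) < 2:
        raise ValueError("need at least two replicate tables")
    if any(not t for t in replicate_counts):
        raise ValueError("replicate tables must be non-empty")
    pooled: dict[str, float] = {}
    presence: dict[str, int] = {}
    for table in replicate_counts:
        for b, c in table.items():
            if c <= 0:
                continue
            pooled[b] = pooled.get(b, 0) + c
            presence[b] = presence.get(b, 0) + 1
    grand_total = float(sum(pooled.values()))
    admitted = {
        b: c
        for b, c in pooled.items()
        if c / grand_total >= min_freq and presence[b] >= min_replicates
    }
    if not admitted:
        raise ValueError("no barcode passed the library filters")
    return ReferenceLibrary(admitted)


def filter_counts_by_library(counts, library: ReferenceLibrary) -> tuple[dict, float]:
    """Restrict counts to library barcodes; report the dropped total."""
    kept = {b: c for b, c in counts.items() if b in library}
    dropped = sum(c for b, c in counts.items() if b not in library)
    return kept, dropped


# ---------------------------------------------------------------------------
# synthetic generators

def synth_initial_distribution(
    C: int,
    n: int,
    shape,
    rng: np.random.Generator,
    prefix: str = "bc",
) -> dict:
    """Synthetic initial clone sizes over ``C`` barcodes totalling ``n``.

    ``shape="uniform"`` gives sizes differing by at most one cell (largest
    remainder).  A numeric ``shape`` is the sigma of a log-normal from which
    relative clone sizes are drawn; every clone keeps at least one cell and
    the total is exactly ``n``.  Larger sigma gives a more right-skewed
    distribution (many small clones, few large ones).
    """
    if C > n:
        raise ValueError("cannot have more clones than cells")
    if C < 1:
        raise ValueError("need at least one clone")
    names = [f"{prefix}{i:06d}" for i in range(C)]
    if shape == "uniform":
        base = n // C
        extra = n - base * C
        sizes = np.full(C, base, dtype=np.int64)
        if extra:
            sizes[rng.choice(C, size=extra, replace=False)] += 1
    else:
        sigma = float(shape)
        if sigma < 0:
            raise ValueError("log-normal sigma must be >= 0")
        weights = rng.lognormal(mean=0.0, sigma=sigma, size=C)
        from .abm import _largest_remainder

        sizes = 1 + _largest_remainder(weights, n - C)
    return dict(zip(names, sizes.tolist()))


def synth_library(
    C: int,
    rng: np.random.Generator,
    barcode_length: int = 20,
    concentration: float = 5.0,
) -> ReferenceLibrary:
    """Random reference library of ``C`` distinct barcode sequences.

    Frequencies are Dirichlet-distributed with the given concentration.
    """
    seqs: set[str] = set()
    while len(seqs) < C:
        block = rng.integers(0, 4, size=(C - len(seqs), barcode_length))
        for row in block:
            seqs.add("".join(_BASES[row]))
    seqs = sorted(seqs)
    freqs = rng.dirichlet(np.full(C, concentration))
    return ReferenceLibrary(dict(zip(seqs, freqs)))


def synth_fastq(
    counts,
    sequences,
    rng: np.random.Generator,
    out,
    error_rate: float = 0.0,
    quality: int = 60,
    depth: int | None = None,
    phred_offset: int = 33,
) -> int:
    """Write synthetic FASTQ reads for a barcode count table.

    One read per counted cell by default, or ``depth`` reads drawn
    multinomially in proportion to the counts.  Each read is the barcode
    sequence with independent per-base substitution errors at ``error_rate``
    and a constant per-base Phred ``quality``.  ``sequences`` maps barcode
    identifiers to nucleotide sequences (a :class:`ReferenceLibrary` keyed
    by sequence works when the count table is keyed by sequence too).

    Returns the number of reads written.
    """
    if isinstance(sequences, ReferenceLibrary):
        sequences = {b: b for b in sequences.barcodes}
    items = [(b, c) for b, c in counts.items() if c > 0]
    for b, _ in items:
        if b not in sequences:
            raise KeyError(f"barcode {b!r} has no sequence")
    totals = np.array([c for _, c in items], dtype=np.int64)
    if depth is not None:
        if totals.sum() == 0:
            raise ValueError("cannot subsample an empty count table")
        totals = rng.multinomial(depth, totals / totals.sum())
    close = False
    if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        out = open(out, "w")
        close = True
    written = 0
    try:
        for (b, _), n_reads in zip(items, totals):
            seq = sequences[b]
            qline = chr(phred_offset + quality) * len(seq)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for _ in range(int(n_reads)):
                read = arr
                if error_rate > 0:
                    hit = rng.random(arr.size) < error_rate
                    if hit.any():
                        read = arr.copy()
                        shift = rng.integers(1, 4, size=int(hit.sum()))
                        idx = np.flatnonzero(hit)
                        read[idx] = _substitute(read[idx], shift)
                out.write(f"@read{written}\n{read.tobytes().decode()}\n+\n{qline}\n")
                written += 1
    finally:
        if close:
            out.close()
    return written


_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_TO_IDX = np.zeros(256, dtype=np.int64)
for _i, _c in enumerate(_BASE_CODES):
    _CODE_TO_IDX[_c] = _i


def _substitute(codes: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Replace each base by a uniformly chosen *different* base."""
    return _BASE_CODES[(_CODE_TO_IDX[codes] + shift) % 4]


def contaminate_with_spurious_reads(
    counts,
    library: ReferenceLibrary,
    contamination_rate: float,
    rng: np.random.Generator,
) -> dict:
    """Add spurious reads confined to the reference library.

    Every library barcode gains an independent Poisson count with mean
    ``contamination_rate * total_count * library_frequency``; no count is
    ever removed.  Barcodes absent from the input appear once contaminated,
    which is how spurious reads bias measured clone loss downward.
    """
    if contamination_rate < 0:
        raise ValueError("contamination rate must be >= 0")
    out = dict(counts)
    if contamination_rate == 0:
        return out
    total = sum(counts.values())
    barcodes = library.barcodes
    lam = contamination_rate * total * np.array(
        [library.frequencies[b] for b in barcodes]
    )
    spurious = rng.poisson(lam)
    for b, k in zip(barcodes, spurious):
        if k:
            out[b] = out.get(b, 0) + int(k)
    return out
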