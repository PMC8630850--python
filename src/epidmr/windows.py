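"""Genome windowing and one-hot sequence encoding.

A genome is tiled into fixed-size, non-overlapping windows (default 1000 bp,
anchored at position 0 of each chromosome). Each window is encoded as a
5 x window_size binary matrix over the alphabet (A, C, G, T, N); any IUPAC
ambiguity code or other non-ACGT character collapses to N. CpG statistics
(a cytosine immediately followed by a guanine on the same strand) drive the
negative-set and "maximum possible DMR" rules downstream.

Coordinates are 0-based half-open throughout, matching BED conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
DEFAULT_WINDOW_SIZE = 1000

# any byte not in ACGT maps to N
_TO_ACGTN = np.full(256, ord("N"), dtype=np.uint8)
for _b in b"ACGT":
    _TO_ACGTN[_b] = _b
for _b in b"acgt":
    _TO_ACGTN[_b] = _b - 32


@dataclass(frozen=True)
class GenomeWindow:
    """A fixed-size tile of a chromosome with 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError(
                f"window [{self.start},{self.end}) does not match sequence "
                f"length {len(self.seq)}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.start)

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CpGProfile:
    """CpG dinucleotide content of one window."""

    cpg_count: int
    cpg_density_pct: float


def normalize_seq(seq: str) -> str:
    """Uppercase a sequence and collapse every non-ACGT character to N."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _TO_ACGTN[arr].tobytes().decode("ascii")


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Returns an ordered mapping of record id to normalized sequence
    (uppercase, alphabet restricted to ACGTN). Raises ``ValueError`` for an
    empty file or content preceding the first header line.
    """
    genome: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"empty FASTA file: {path}")
        if not first.startswith(">"):
            raise ValueError(
                f"malformed FASTA (line 1 does not start with '>'): {path}"
            )
    for record in SeqIO.parse(path, "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate FASTA record id: {record.id}")
        genome[record.id] = normalize_seq(str(record.seq))
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def tile_windows(
    chrom: str, seq: str, window_size: int = DEFAULT_WINDOW_SIZE
) -> list[GenomeWindow]:
    """Tile a chromosome into non-overlapping windows anchored at 0.

    A trailing remainder shorter than ``window_size`` is dropped (the model
    input has fixed width). An empty sequence yields an empty list.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    seq = normalize_seq(seq)
    n = len(seq) // window_size
    return [
        GenomeWindow(
            chrom, i * window_size, (i + 1) * window_size,
            seq[i * window_size : (i + 1) * window_size],
        )
        for i in range(n)
    ]


def one_hot(seq_or_window) -> np.ndarray:
    """One-hot encode a sequence as a 5 x L float32 matrix.

    Row order is (A, C, G, T, N); column j has a single 1 in the row of
    base j. Raises ``ValueError`` on characters outside the alphabet.
    """
    seq = seq_or_window.seq if isinstance(seq_or_window, GenomeWindow) else seq_or_window
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        idx[arr == ord(base)] = i
    if (idx < 0).any():
        bad = seq[int(np.argmax(idx < 0))]
        raise ValueError(f"unexpected character {bad!r}; normalize first")
    mat = np.zeros((len(ALPHABET), len(seq)), dtype=np.float32)
    mat[idx, np.arange(len(seq))] = 1.0
    return mat


def one_hot_batch(seqs: Iterable[str | GenomeWindow]) -> np.ndarray:
    """Encode equal-length sequences as an (n, 5, L) float32 array."""
    mats = [one_hot(s) for s in seqs]
    if not mats:
        raise ValueError("empty batch")
    return np.stack(mats)


def decode_one_hot(mat: np.ndarray) -> str:
    """Invert :func:`one_hot` by per-column argmax."""
    return "".join(ALPHABET[i] for i in np.asarray(mat).argmax(axis=0))


def cpg_count(seq: str) -> int:
    """Number of CG dinucleotides (exact 'CG'; N never counts)."""
    return seq.count("CG")


def cpg_profile(window: GenomeWindow | str) -> CpGProfile:
    """CpG count and density (percent of window size) for one window."""
    seq = window.seq if isinstance(window, GenomeWindow) else window
    count = cpg_count(seq)
    return CpGProfile(count, 100.0 * count / len(seq))
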