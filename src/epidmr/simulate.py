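"""Synthetic labeled windows with the structure the pipeline assumes.

The generator emulates the two training classes: positives are background
sequence carrying a few mutated copies of a planted consensus motif plus a
realistic complement of CpG dinucleotides; negatives are background
sequence with every CpG destroyed (resampling the G), mirroring the
zero-CpG negative rule. The default consensus is CpG-dense, as real
DMR-associated motifs are, so most CpGs in a positive window are carried
by motif copies.

A companion stats-table generator assigns sub-threshold p-values to true
positives (in one random exposure each) and comfortably non-significant
p-values elsewhere, exercising the union-over-exposures labeling rule; a
toy-genome assembler concatenates shuffled windows into a FASTA-ready
chromosome with a matching truth table for end-to-end scan tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import GenomeWindow, cpg_count

BASES = "ACGT"

# the nine toxicant exposures of the training corpus
EXPOSURES = (
    "atrazine", "DDT", "glyphosate", "vinclozolin", "pesticides",
    "dioxin", "jet_fuel", "methoxychlor", "plastics",
)

# 20-mer with two internal CpGs, chosen with low self-overlap so that
# recovering it from a learned kernel has a unique alignment
DEFAULT_CONSENSUS = "TGCATTACGGTCACGATGCA"


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give a learnably separable dataset."""

    n_per_class: int = 1000
    window_size: int = 1000
    planted_motifs: tuple[str, ...] = (DEFAULT_CONSENSUS,)
    mutation_rate: float = 0.1
    motif_copies: int = 3
    pos_cpg_rate: int = 20  # expected CpGs per positive window
    background_base_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    cpg_free_negatives: bool = True  # False = harder CpG-matched negatives
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.background_base_probs), 1.0):
            raise ValueError("background_base_probs must sum to 1")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must be in [0, 0.5]")
        for m in self.planted_motifs:
            if len(m) > self.window_size:
                raise ValueError(f"motif longer than window: {m}")


@dataclass
class SyntheticDataset:
    """Generated windows, labels (1 = DMR-like positive) and ground truth."""

    windows: list[GenomeWindow]
    labels: np.ndarray
    motif_spans: list[list[tuple[int, int]]] = field(default_factory=list)
    spec: SyntheticSpec | None = None

    @property
    def sequences(self) -> list[str]:
        return [w.seq for w in self.windows]

    def encode(self) -> np.ndarray:
        from .windows import one_hot_batch

        return one_hot_batch(self.windows)


def _random_seq(rng, n, probs) -> np.ndarray:
    return rng.choice(np.frombuffer(BASES.encode(), dtype=np.uint8), size=n,
                      p=np.asarray(probs))


def _destroy_cpgs(arr: np.ndarray, rng) -> None:
    """Resample the G of every CG until none remain (in place)."""
    non_g = np.frombuffer(b"ACT", dtype=np.uint8)
    while True:
        hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if hits.size == 0:
            return
        arr[hits + 1] = rng.choice(non_g, size=hits.size)


def _mutate(motif: str, rate: float, rng) -> str:
    out = []
    for b in motif:
        if rng.random() < rate:
            out.append(rng.choice([c for c in BASES if c != b]))
        else:
            out.append(b)
    return "".join(out)


def _place_motifs(arr, spec: SyntheticSpec, rng) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    for motif in spec.planted_motifs:
        k = len(motif)
        for _ in range(spec.motif_copies):
            for _attempt in range(1000):
                start = int(rng.integers(0, spec.window_size - k + 1))
                if all(start + k <= s or start >= e for s, e in spans):
                    break
            else:  # pragma: no cover - windows far larger than motif load
                raise RuntimeError("could not place motif copies without overlap")
            copy = _mutate(motif, spec.mutation_rate, rng)
            arr[start : start + k] = np.frombuffer(copy.encode(), dtype=np.uint8)
            spans.append((start, start + k))
    return sorted(spans)


def _inject_cpgs(arr, spans, target: int, rng) -> None:
    """Add CG dinucleotides outside motif spans until count >= target."""
    need = target - cpg_count(arr.tobytes().decode())
    guard = 0
    while need > 0 and guard < 10000:
        guard += 1
        p = int(rng.integers(0, len(arr) - 1))
        if any(s - 1 <= p < e for s, e in spans):
            continue
        before = cpg_count(arr.tobytes().decode())
        old = arr[p : p + 2].copy()
        arr[p] = ord("C")
        arr[p + 1] = ord("G")
        after = cpg_count(arr.tobytes().decode())
        if after <= before:  # pragma: no cover - overwrite collision
            arr[p : p + 2] = old
            continue
        need -= after - before


def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate ``2 * n_per_class`` labeled windows, positives first.

    Positives: background + mutated motif copies at non-overlapping uniform
    positions + CpGs injected up to ``pos_cpg_rate`` (and at least one).
    Negatives: background with every CpG destroyed (default), or
    CpG-matched background without motifs (harder mode). Fully determined
    by ``spec.seed``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    windows: list[GenomeWindow] = []
    labels: list[int] = []
    motif_spans: list[list[tuple[int, int]]] = []

    for i in range(spec.n_per_class):
        arr = _random_seq(rng, spec.window_size, spec.background_base_probs)
        spans = _place_motifs(arr, spec, rng)
        _inject_cpgs(arr, spans, max(spec.pos_cpg_rate, 1), rng)
        seq = arr.tobytes().decode()
        start = i * spec.window_size
        windows.append(GenomeWindow("synth", start, start + spec.window_size, seq))
        labels.append(1)
        motif_spans.append(spans)

    for i in range(spec.n_per_class):
        arr = _random_seq(rng, spec.window_size, spec.background_base_probs)
        if spec.cpg_free_negatives:
            _destroy_cpgs(arr, rng)
        else:
            _inject_cpgs(arr, [], max(spec.pos_cpg_rate, 1), rng)
        seq = arr.tobytes().decode()
        start = (spec.n_per_class + i) * spec.window_size
        windows.append(GenomeWindow("synth", start, start + spec.window_size, seq))
        labels.append(0)
        motif_spans.append([])

    return SyntheticDataset(windows, np.array(labels), motif_spans, spec)


def generate_stats_table(
    dataset: SyntheticDataset,
    p_low: float = 1e-6,
    p_high: float = 1e-2,
    exposures: tuple[str, ...] = EXPOSURES,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region p-value table whose strict-threshold labeling recovers truth.

    True positives draw p ~ U(0, p_low) in one random exposure; every
    window additionally draws non-significant p ~ U(p_high, 1) in another
    random exposure, so labeling must use union semantics.
    """
    if not p_low < 1e-5 <= p_high:
        raise ValueError("need p_low < 1e-5 <= p_high")
    rng = np.random.default_rng(seed)
    rows = []
    for w, label in zip(dataset.windows, dataset.labels):
        if label == 1:
            rows.append({
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "exposure": exposures[rng.integers(len(exposures))],
                "p_value": float(rng.uniform(0, p_low)),
            })
        rows.append({
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "exposure": exposures[rng.integers(len(exposures))],
            "p_value": float(rng.uniform(p_high, 1.0)),
        })
    return pd.DataFrame(rows)


def assemble_toy_genome(
    dataset: SyntheticDataset,
    seed: int = 0,
    chrom_name: str = "synthchr1",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate shuffled windows into one synthetic chromosome.

    Returns the genome mapping and a truth table (chrom, start, end,
    label) aligned to the window tiling of the concatenated sequence.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset.windows))
    seq_parts, rows = [], []
    size = dataset.windows[0].size
    for pos, i in enumerate(order):
        seq_parts.append(dataset.windows[i].seq)
        rows.append({
            "chrom": chrom_name,
            "start": pos * size,
            "end": (pos + 1) * size,
            "label": int(dataset.labels[i]),
        })
    return {chrom_name: "".join(seq_parts)}, pd.DataFrame(rows)


def write_fasta(genome: dict[str, str], path, line_width: int = 80) -> None:
    """Write a chromosome mapping as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
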