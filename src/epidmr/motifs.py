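"""Kernel-to-motif conversion and motif export.

Each first-layer kernel is summarized as a position weight matrix (PWM):
over the whole training set, every length-k subsequence whose activation
reaches a fraction (default 0.5) of that kernel's dataset-wide maximum
activation contributes one count per position, and counts are normalized
column-wise over the 5-letter alphabet (A, C, G, T, N). The PWM carries
the kernel's detector class and activation difference so motif sets can be
ordered from most DMR-biased to most non-DMR-biased.

Export formats: a 5-row TSV (keeps the N row), and MEME minimal motif
format over ACGT for downstream motif-matching tools (the N column's mass
is redistributed uniformly over the four bases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import classify_detectors
from .windows import ALPHABET, one_hot_batch

logger = logging.getLogger(__name__)


@dataclass
class PWM:
    """Column-stochastic 5 x k base-probability matrix for one kernel."""

    values: np.ndarray  # (5, k), rows (A, C, G, T, N)
    n_subsequences: int
    kernel_id: int
    detector_class: str = ""
    activation_difference: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(ALPHABET):
            raise ValueError("PWM must be 5 x k")
        if (self.values < 0).any() or not np.allclose(
            self.values.sum(axis=0), 1.0, atol=1e-9
        ):
            raise ValueError("PWM columns must be probability vectors")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def consensus(self, exclude_n: bool = True) -> str:
        """Argmax base per column (over A,C,G,T by default)."""
        rows = 4 if exclude_n else 5
        idx = self.values[:rows].argmax(axis=0)
        return "".join(ALPHABET[i] for i in idx)


def activating_subsequences(
    trained,
    kernel_id: int,
    sequences: list[str],
    threshold_fraction: float = 0.5,
    mode: str = "all_positions",
    batch: int = 256,
) -> list[str]:
    """Subsequences driving one kernel past a fraction of its max activation.

    With ``mode="all_positions"`` (default), every window position whose
    (post-batchnorm/ReLU) activation is >= ``threshold_fraction`` times the
    kernel's maximum activation over the whole dataset contributes its
    length-k subsequence. With ``mode="per_window_max"`` only the single
    maximally-activating subsequence of each window is taken (still gated
    by the same threshold) — the convention of conv-kernel visualization
    tools, which keeps the motif estimate from being swamped by weak
    background hits. A kernel that never activates yields an empty list
    with a logged warning.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    if not 0 <= kernel_id < trained.block1_filters:
        raise ValueError(f"kernel_id must be in [0, {trained.block1_filters})")
    if mode not in ("all_positions", "per_window_max"):
        raise ValueError(f"unknown mode {mode!r}")
    k = trained.kernel_size
    acts = []
    for i in range(0, len(sequences), batch):
        X = one_hot_batch(sequences[i : i + batch])
        acts.append(trained.conv1_activations(X)[:, kernel_id, :])
    act = np.concatenate(acts, axis=0)  # (n, L - k + 1)
    max_act = float(act.max())
    if max_act <= 0.0:
        logger.warning("kernel %d never activates; no subsequences", kernel_id)
        return []
    cutoff = threshold_fraction * max_act
    if mode == "per_window_max":
        best = act.argmax(axis=1)
        return [
            sequences[w][p : p + k]
            for w, p in enumerate(best)
            if act[w, p] >= cutoff
        ]
    hits = np.argwhere(act >= cutoff)
    return [sequences[w][p : p + k] for w, p in hits]


def build_pwm(subsequences: list[str], kernel_id: int = -1) -> PWM:
    """Per-position base frequencies over equal-length subsequences."""
    if not subsequences:
        raise ValueError("cannot build a PWM from an empty subsequence list")
    k = len(subsequences[0])
    if any(len(s) != k for s in subsequences):
        raise ValueError("subsequences must have equal length")
    counts = np.zeros((len(ALPHABET), k))
    for s in subsequences:
        for j, b in enumerate(s):
            counts[ALPHABET.index(b), j] += 1
    return PWM(counts / len(subsequences), len(subsequences), kernel_id)


def build_kernel_motifs(
    trained,
    sequences: list[str],
    labels,
    threshold_fraction: float = 0.5,
    pooling: str = "max",
) -> list[PWM]:
    """One PWM per first-layer kernel, annotated with its detector class.

    Kernels are ordered DMR detectors first, each class sorted by the
    magnitude of its activation difference (most class-biased first).
    Kernels that never activate are skipped with a warning.
    """
    X = one_hot_batch(sequences)
    assignments = {
        a.feature_id: a
        for a in classify_detectors(trained, X, labels, pooling=pooling)
    }
    pwms: list[PWM] = []
    for kid in range(trained.block1_filters):
        subs = activating_subsequences(
            trained, kid, sequences, threshold_fraction
        )
        if not subs:
            continue
        pwm = build_pwm(subs, kernel_id=kid)
        a = assignments[kid]
        pwm.detector_class = a.detector_class
        pwm.activation_difference = a.activation_difference
        pwms.append(pwm)
    return sorted(
        pwms,
        key=lambda p: (p.detector_class != "DMR", -abs(p.activation_difference)),
    )


def write_pwm_tsv(pwms: list[PWM], path) -> None:
    """Long-format TSV keeping all five alphabet rows."""
    with open(path, "w") as fh:
        fh.write("kernel_id\tdetector_class\tactivation_difference\t"
                 "n_subsequences\tbase\t"
                 + "\t".join(f"pos{j}" for j in range(pwms[0].width)) + "\n")
        for pwm in pwms:
            for i, base in enumerate(ALPHABET):
                vals = "\t".join(f"{v:.6f}" for v in pwm.values[i])
                fh.write(f"{pwm.kernel_id}\t{pwm.detector_class}\t"
                         f"{pwm.activation_difference:.6f}\t"
                         f"{pwm.n_subsequences}\t{base}\t{vals}\n")


def write_meme(pwms: list[PWM], path) -> None:
    """MEME minimal motif format over ACGT.

    The N row is dropped by spreading its mass uniformly over A, C, G and
    T, since standard motif-comparison tools use the 4-letter alphabet.
    Motifs are written in the given order and named
    ``kernel<id>_<detectorclass>``.
    """
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            acgt = pwm.values[:4] + pwm.values[4] / 4.0
            name = f"kernel{pwm.kernel_id}_{pwm.detector_class or 'NA'}"
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {pwm.n_subsequences} E= 0\n"
            )
            for j in range(pwm.width):
                fh.write(" ".join(f"{acgt[i, j]:.6f}" for i in range(4)) + "\n")
            fh.write("\n")


def read_meme(path) -> list[tuple[str, np.ndarray]]:
    """Parse a MEME minimal file back to (name, 4 x w matrix) pairs."""
    motifs = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    motifs.append((name, np.array(rows).T))
                name, rows = line.split()[1], []
            elif name is not None and line and line[0].isdigit():
                rows.append([float(x) for x in line.split()])
    if name is not None and rows:
        motifs.append((name, np.array(rows).T))
    return motifs


def export_motifs(pwms: list[PWM], path, format: str = "MEME") -> None:
    """Write motifs in 'MEME' or 'TSV' format."""
    if format.upper() == "MEME":
        write_meme(pwms, path)
    elif format.upper() == "TSV":
        write_pwm_tsv(pwms, path)
    else:
        raise ValueError(f"unknown motif format {format!r}")


def consensus_match_fraction(found: str, planted: str) -> float:
    """Best ungapped-overlap agreement between two consensus strings.

    Slides one string over the other; matches are counted over the
    overlapping positions and divided by the planted length, so a shifted
    recovery is penalized by the lost overlap.
    """
    n = len(planted)
    best = 0
    for shift in range(-(len(found) - 1), n):
        m = sum(
            1
            for i in range(n)
            if 0 <= i - shift < len(found) and found[i - shift] == planted[i]
        )
        best = max(best, m)
    return best / n
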