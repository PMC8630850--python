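"""Re-expressing windows through first-conv-layer features.

After training, each of the 32 first-layer kernels acts as a learned motif
detector. Its activation map over a window (post-batchnorm, post-ReLU, so
non-negative) is pooled — global max by default, which reads as "strongest
occurrence of this motif anywhere in the window" and is invariant to motif
position — to a single value, giving a 32-dimensional feature vector per
window. These vectors are the input representation of the boosted
classifier.

A kernel whose mean pooled activation is higher over DMR windows than over
non-DMR windows is a *DMR detector*; lower, a *non-DMR detector*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

POOLING_METHODS = ("max", "mean")


@dataclass(frozen=True)
class DetectorAssignment:
    """Class bias of one first-layer kernel."""

    feature_id: int
    detector_class: str  # "DMR" or "nonDMR"
    activation_difference: float  # mean over DMRs minus mean over non-DMRs


def conv1_activations(trained, X) -> np.ndarray:
    """Activation maps of the first conv layer; shape (n, n_kernels, L_out)."""
    return trained.conv1_activations(X)


def pool_features(activation_maps: np.ndarray, method: str = "max") -> np.ndarray:
    """Pool per-position activations to one value per kernel.

    ``activation_maps`` has shape (n, n_kernels, L) — or (n_kernels, L) for
    a single window. Returns (n, n_kernels) (or (n_kernels,)).
    """
    if method not in POOLING_METHODS:
        raise ValueError(f"unknown pooling method {method!r}; use one of {POOLING_METHODS}")
    a = np.asarray(activation_maps)
    if method == "max":
        return a.max(axis=-1)
    return a.mean(axis=-1)


def reexpress(trained, X, pooling: str = "max") -> np.ndarray:
    """Feature matrix (n_windows, n_kernels): pooled conv-1 activations.

    Row order follows ``X``; the mapping is deterministic for a fixed
    trained network.
    """
    return pool_features(trained.conv1_activations(X), method=pooling)


def classify_detectors(
    trained, X, y, pooling: str = "max"
) -> list[DetectorAssignment]:
    """Assign each kernel as DMR or non-DMR detector, sorted by difference.

    The activation difference is the mean pooled activation over DMR
    examples minus the mean over non-DMR examples, computed on the given
    dataset. Positive difference -> DMR detector; negative -> non-DMR;
    an exact tie is assigned non-DMR with a logged note. Result is sorted
    by activation difference, descending.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("detector classification needs both classes")
    feats = reexpress(trained, X, pooling=pooling)
    pos_mean = feats[y == 1].mean(axis=0)
    neg_mean = feats[y == 0].mean(axis=0)
    diffs = pos_mean - neg_mean
    assignments = []
    for k, d in enumerate(diffs):
        if d == 0.0:
            logger.info("kernel %d has zero activation difference; "
                        "assigned non-DMR detector", k)
        cls = "DMR" if d > 0 else "nonDMR"
        assignments.append(DetectorAssignment(k, cls, float(d)))
    return sorted(assignments, key=lambda a: a.activation_difference, reverse=True)
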