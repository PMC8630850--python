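"""Labeled training-set construction for DMR prediction.

Positives (DMRs) are 1000 bp windows whose differential-methylation p-value
is below a threshold (default 1e-5, strict) in at least one toxicant
exposure — union semantics across exposures, since the goal is a general,
exposure-independent model. Negatives (non-DMRs) are windows with zero CpG
dinucleotides: without a CpG there is nothing to methylate, so these windows
are unambiguous negatives. Windows that carry CpGs but miss the p-value
threshold are left unlabeled — failing the threshold does not prove a window
is not a DMR — and are excluded from training.

The "maximum possible DMR" set (at least one CpG, at most 20% CpG density)
upper-bounds how many windows could ever be called DMR.

Two further negative rules (CpG-island windows and high-p-value windows)
are implemented but off by default: they enlarge the negative set by only a
percent or two while degrading the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import GenomeWindow, cpg_count, one_hot_batch

logger = logging.getLogger(__name__)

DMR_P_THRESHOLD = 1e-5
CPG_ISLAND_DENSITY_PCT = 20.0

STATS_COLUMNS = ["chrom", "start", "end", "exposure", "p_value"]


@dataclass
class LabeledDataset:
    """Windows with binary labels (1 = DMR, 0 = non-DMR)."""

    windows: list[GenomeWindow]
    labels: np.ndarray  # int array, 1 = DMR

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.windows) != len(self.labels):
            raise ValueError("windows and labels length mismatch")

    @property
    def n_dmr(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_nondmr(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def sequences(self) -> list[str]:
        return [w.seq for w in self.windows]

    def encode(self) -> np.ndarray:
        """One-hot encode all windows as an (n, 5, window_size) array."""
        return one_hot_batch(self.windows)

    def subset(self, chrom: str) -> "LabeledDataset":
        """Restrict to one chromosome, or return self for 'ALL'."""
        if chrom == "ALL":
            return self
        keep = [i for i, w in enumerate(self.windows) if w.chrom == chrom]
        return LabeledDataset(
            [self.windows[i] for i in keep], self.labels[keep]
        )


def read_stats_table(path) -> pd.DataFrame:
    """Read a per-region DMR statistics TSV (chrom, start, end, exposure, p_value)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(STATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    return df


def label_dmrs(
    stats: pd.DataFrame, threshold: float = DMR_P_THRESHOLD
) -> set[tuple[str, int]]:
    """Window keys that are DMRs: p-value < threshold in >= 1 exposure.

    Strict inequality; a p-value exactly at the threshold does not qualify.
    Duplicate (window, exposure) rows keep the minimum p-value with a
    logged warning.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if ((stats["p_value"] <= 0) | (stats["p_value"] > 1)).any():
        raise ValueError("p_value entries must lie in (0, 1]")
    dup = stats.duplicated(subset=["chrom", "start", "exposure"])
    if dup.any():
        logger.warning(
            "%d duplicate (window, exposure) rows; keeping minimum p-value",
            int(dup.sum()),
        )
        stats = (
            stats.groupby(["chrom", "start", "exposure"], as_index=False)
            .agg({"end": "first", "p_value": "min"})
        )
    hits = stats[stats["p_value"] < threshold]
    return {(str(c), int(s)) for c, s in zip(hits["chrom"], hits["start"])}


def select_non_dmrs(
    windows: list[GenomeWindow],
    dmr_keys: set[tuple[str, int]] | None = None,
) -> set[tuple[str, int]]:
    """Window keys eligible as negatives: exactly zero CpG dinucleotides.

    A window that is simultaneously in the DMR set and CpG-free indicates
    inconsistent input; it is excluded from the negatives with a logged
    conflict (differential methylation requires a CpG).
    """
    dmr_keys = dmr_keys or set()
    selected: set[tuple[str, int]] = set()
    for w in windows:
        if cpg_count(w.seq) == 0:
            if w.key in dmr_keys:
                logger.error(
                    "window %s:%d is labeled DMR but has no CpGs; "
                    "excluded from negatives", w.chrom, w.start,
                )
                continue
            selected.add(w.key)
    return selected


def max_possible_dmrs(
    windows: list[GenomeWindow],
    island_density_pct: float = CPG_ISLAND_DENSITY_PCT,
) -> set[tuple[str, int]]:
    """Windows that could possibly be DMRs: 1 <= CpG count <= density cutoff.

    The default cutoff is a CpG density of 20% (200 CpGs per 1000 bp);
    "more than" the cutoff is strict, so a window exactly at the bound is
    included.
    """
    keys: set[tuple[str, int]] = set()
    for w in windows:
        c = cpg_count(w.seq)
        if 1 <= c <= island_density_pct / 100.0 * w.size:
            keys.add(w.key)
    return keys


@dataclass
class DatasetBuildReport:
    """Bookkeeping from :func:`build_dataset`."""

    n_windows: int = 0
    n_dmr: int = 0
    n_nondmr: int = 0
    n_unlabeled: int = 0
    extra_negative_keys: set = field(default_factory=set)


def build_dataset(
    genome: dict[str, str] | list[GenomeWindow],
    stats: pd.DataFrame,
    threshold: float = DMR_P_THRESHOLD,
    window_size: int = 1000,
    chrom: str = "ALL",
    include_island_negatives: bool = False,
    include_high_p_negatives: bool = False,
    island_density_pct: float = CPG_ISLAND_DENSITY_PCT,
    high_p_cutoff: float = 0.5,
) -> LabeledDataset:
    """Assemble the labeled training set from a tiled genome and a stats table.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence (tiled here), or a
        pre-tiled window list.
    stats
        Per-region statistics with columns (chrom, start, end, exposure,
        p_value); coordinates must align to the tiling.
    chrom
        Restrict to one chromosome, or 'ALL' (default) for the whole genome.
    include_island_negatives, include_high_p_negatives
        Optional extra negative rules (CpG-island windows; windows whose
        minimum p-value across exposures exceeds ``high_p_cutoff``). Off by
        default.

    Raises
    ------
    ValueError
        If any stats row references coordinates not aligned to the tiling.
    """
    from .windows import tile_windows

    if isinstance(genome, dict):
        windows = [
            w for name, seq in genome.items()
            for w in tile_windows(name, seq, window_size)
        ]
    else:
        windows = list(genome)
    if chrom != "ALL":
        windows = [w for w in windows if w.chrom == chrom]
    window_keys = {w.key for w in windows}

    offenders = [
        f"{c}:{s}-{e}"
        for c, s, e in zip(stats["chrom"], stats["start"], stats["end"])
        if (str(c), int(s)) not in window_keys
        and (chrom == "ALL" or str(c) == chrom)
    ]
    if offenders:
        raise ValueError(
            "stats rows not aligned to the %d bp tiling: %s"
            % (window_size, ", ".join(offenders[:10]))
        )

    dmr_keys = label_dmrs(stats, threshold)
    if chrom != "ALL":
        dmr_keys = {k for k in dmr_keys if k[0] == chrom}
    neg_keys = select_non_dmrs(windows, dmr_keys)

    if include_island_negatives:
        for w in windows:
            if (
                cpg_count(w.seq) > island_density_pct / 100.0 * w.size
                and w.key not in dmr_keys
            ):
                neg_keys.add(w.key)
    if include_high_p_negatives:
        min_p = stats.groupby(["chrom", "start"])["p_value"].min()
        for (c, s), p in min_p.items():
            key = (str(c), int(s))
            if p > high_p_cutoff and key in window_keys and key not in dmr_keys:
                neg_keys.add(key)

    kept: list[GenomeWindow] = []
    labels: list[int] = []
    for w in windows:
        if w.key in dmr_keys:
            kept.append(w)
            labels.append(1)
        elif w.key in neg_keys:
            kept.append(w)
            labels.append(0)
    return LabeledDataset(kept, np.array(labels, dtype=np.int64))
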