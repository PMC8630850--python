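"""Whole-genome application of a trained hybrid model.

Streams a FASTA chromosome by chromosome, tiles it into fixed windows,
scores every window with the hybrid path (conv-1 features into the boosted
classifier) and emits one record per window. Summaries report, per
chromosome and in total, the number and percentage of predicted DMRs, the
"maximum possible DMR" bound (windows with 1..200 CpGs), and the recall of
a supplied training-DMR set. A small uniform sample of predicted DMRs can
be drawn for visualization tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .dataset import max_possible_dmrs
from .windows import GenomeWindow, one_hot_batch, read_fasta, tile_windows

logger = logging.getLogger(__name__)

DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ScanRecord:
    window: GenomeWindow
    probability: float

    @property
    def call(self) -> str:
        return "DMR" if self.probability >= DECISION_THRESHOLD else "nonDMR"


def scan_genome(
    model,
    genome: dict[str, str] | str,
    window_size: int = 1000,
    batch_size: int = 256,
) -> Iterator[ScanRecord]:
    """Score every full window of a genome; yields records in genome order.

    ``genome`` is a FASTA path or a chromosome->sequence mapping. Memory
    stays bounded by ``batch_size`` windows. Chromosomes shorter than one
    window are skipped with a log entry.
    """
    if isinstance(genome, str):
        genome = read_fasta(genome)
    for chrom, seq in genome.items():
        windows = tile_windows(chrom, seq, window_size)
        if not windows:
            logger.info("chromosome %s shorter than one window; skipped", chrom)
            continue
        for i in range(0, len(windows), batch_size):
            chunk = windows[i : i + batch_size]
            proba = model.predict_proba(one_hot_batch(chunk))[:, 1]
            for w, p in zip(chunk, proba):
                yield ScanRecord(w, float(p))


def summarize_scan(
    records: Iterable[ScanRecord],
    training_dmr_keys: set[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-chromosome and total ('ALL') scan summary.

    Columns: n_windows, n_predicted_dmr, pct_genome, n_max_possible,
    pct_max_possible, and (when a training DMR set is given) pct_recall —
    the percentage of training DMR windows called DMR.
    """
    records = list(records)
    by_chrom: dict[str, list[ScanRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.window.chrom, []).append(r)

    rows = []
    for chrom, recs in by_chrom.items():
        rows.append(_summary_row(chrom, recs, training_dmr_keys))
    rows.append(_summary_row("ALL", records, training_dmr_keys))
    return pd.DataFrame(rows)


def _summary_row(name, recs, training_dmr_keys):
    n = len(recs)
    called = [r for r in recs if r.call == "DMR"]
    max_poss = max_possible_dmrs([r.window for r in recs])
    row = {
        "chrom": name,
        "n_windows": n,
        "n_predicted_dmr": len(called),
        "pct_genome": 100.0 * len(called) / n if n else 0.0,
        "n_max_possible": len(max_poss),
        "pct_max_possible": 100.0 * len(max_poss) / n if n else 0.0,
    }
    if training_dmr_keys is not None:
        keys = (
            training_dmr_keys
            if name == "ALL"
            else {k for k in training_dmr_keys if k[0] == name}
        )
        if keys:
            hit = sum(1 for r in called if r.window.key in keys)
            row["pct_recall"] = 100.0 * hit / len(keys)
        else:
            row["pct_recall"] = float("nan")
    return row


def sample_track(
    records: Iterable[ScanRecord],
    fraction: float = 0.0002,
    seed: int = 0,
) -> list[ScanRecord]:
    """Uniform sample (without replacement) of the predicted-DMR records.

    Sample size is round(fraction * n_predicted_dmr); 0.02% is the rate
    used for genome-wide visualization tracks.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    called = [r for r in records if r.call == "DMR"]
    n = int(round(fraction * len(called)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(called), size=n, replace=False)
    return [called[i] for i in sorted(idx)]


def write_bed(records: Iterable[ScanRecord], path, auto_sort: bool = False) -> None:
    """Write records as BED6: chrom, start, end, call, 1000*probability, '.'.

    Records must be sorted by (chrom, start); pass ``auto_sort=True`` to
    sort here instead of raising.
    """
    records = list(records)
    keys = [(r.window.chrom, r.window.start) for r in records]
    if keys != sorted(keys):
        if not auto_sort:
            raise ValueError("records not sorted by (chrom, start)")
        records = sorted(records, key=lambda r: (r.window.chrom, r.window.start))
    with open(path, "w") as fh:
        for r in records:
            w = r.window
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{r.call}\t"
                f"{round(1000 * r.probability)}\t.\n"
            )
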