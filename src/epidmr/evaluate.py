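"""Cross-validated evaluation of the hybrid DMR classifier.

Fivefold stratified cross-validation: both stages of the hybrid model (the
CNN and the boosted classifier) are retrained inside each fold on that
fold's 80% training partition only, so no held-out window ever influences
the features it is scored with. Per-fold accuracy, precision, recall and
F1 are averaged arithmetically over folds.

Metric definitions (DMR = positive class):

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* precision = TP / (TP + FP) — correctly identified DMRs over predicted DMRs
* recall    = TP / (TP + FN) — correctly identified DMRs over all DMRs
* F1        = harmonic mean of precision and recall,
  2 * P * R / (P + R)

Zero-denominator precision or recall is defined as 0 with a logged note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


@dataclass
class CVReport:
    per_fold: list[Metrics]
    mean: Metrics
    n_dmr: int
    n_nondmr: int


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic-mean F1; 0 when precision + recall == 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(y_true, y_pred) -> Metrics:
    """Accuracy, precision, recall and F1 from binary label vectors (1 = DMR)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise ValueError("need at least one example")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    accuracy = (tp + tn) / y_true.size
    if tp + fp == 0:
        logger.info("no predicted DMRs; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.info("no true DMRs; recall defined as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return Metrics(accuracy, precision, recall,
                   f1_from_precision_recall(precision, recall))


def _mean_metrics(per_fold: list[Metrics]) -> Metrics:
    return Metrics(
        float(np.mean([m.accuracy for m in per_fold])),
        float(np.mean([m.precision for m in per_fold])),
        float(np.mean([m.recall for m in per_fold])),
        float(np.mean([m.f1 for m in per_fold])),
    )


def cross_validate(estimator, X, y, k: int = 5, seed: int = 0,
                   return_models: bool = False):
    """Stratified k-fold CV retraining the full hybrid model per fold.

    Parameters
    ----------
    estimator
        Unfitted prototype (cloned per fold); its ``random_state`` is set
        to ``seed`` + fold index.
    X : (n, 5, window_size) one-hot array
    y : binary labels (1 = DMR)

    Returns a :class:`CVReport` (optionally also the per-fold fitted
    models and test indices).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} examples; got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[Metrics] = []
    models = []
    for fold, (idx_tr, idx_te) in enumerate(skf.split(X, y)):
        assert len(np.intersect1d(idx_tr, idx_te)) == 0
        model = clone(estimator)
        model.set_params(random_state=seed + fold)
        model.fit(X[idx_tr], y[idx_tr])
        y_pred = model.predict(X[idx_te])
        per_fold.append(compute_metrics(y[idx_te], y_pred))
        if return_models:
            models.append((model, idx_te))
        logger.info("fold %d: %s", fold, per_fold[-1])
    report = CVReport(per_fold, _mean_metrics(per_fold),
                      n_dmr=int(counts[1]), n_nondmr=int(counts[0]))
    if return_models:
        return report, models
    return report


def summarize_reports(
    reports: dict[str, CVReport]
) -> tuple[pd.DataFrame, float]:
    """Per-chromosome summary table plus mean accuracy across chromosomes.

    The table mirrors the published layout (#nonDMRs, #DMRs, Accuracy,
    F1, Precision, Recall); the returned mean is the unweighted arithmetic
    mean of the per-chromosome accuracies.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for chrom, rep in reports.items():
        rows.append({
            "chrom": chrom,
            "n_nondmr": rep.n_nondmr,
            "n_dmr": rep.n_dmr,
            "accuracy": rep.mean.accuracy,
            "f1": rep.mean.f1,
            "precision": rep.mean.precision,
            "recall": rep.mean.recall,
        })
    df = pd.DataFrame(rows)
    return df, float(df["accuracy"].mean())


def load_published_cv_metrics() -> pd.DataFrame:
    """Published per-chromosome CV metrics of the hybrid model on the rat
    exposure data (reference values for metric-arithmetic checks)."""
    path = resources.files("epidmr.data").joinpath("published_cv_metrics.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def mean_chromosome_accuracy(table: pd.DataFrame) -> float:
    """Unweighted mean accuracy over per-chromosome rows (excludes 'All')."""
    per_chrom = table[table["chrom"] != "All"]
    return float(per_chrom["accuracy"].mean())
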