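"""Polyclonal-vs-monoclonal discrimination metrics for heterogeneity scores.

The positive class is *polyclonal*.  AUC is computed as the Mann-Whitney
pair statistic P(score_poly > score_mono) + 0.5 * P(tie); the ROC curve is
built over all distinct score thresholds and the operating point for
precision/recall maximises Youden's J (tpr - fpr), ties broken toward the
higher threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from cnvcomplexity.baselines import guo_pairwise_score, ma_centroid_score
from cnvcomplexity.complexity import complexity_score
from cnvcomplexity.simulator import SimulatedSample

__all__ = [
    "RocResult",
    "BenchmarkResult",
    "auc_score",
    "roc_curve",
    "benchmark_methods",
    "METHODS",
]

POSITIVE = "polyclonal"
NEGATIVE = "monoclonal"

METHODS = {
    "complexity": lambda m: complexity_score(m).entropy,
    "ma": ma_centroid_score,
    "guo": guo_pairwise_score,
}


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    precision: float
    recall: float
    operating_threshold: float


@dataclass
class BenchmarkResult:
    """Per-sample scores, per-method ROC results and N-correlations."""

    scores: pd.DataFrame  # sample_id, label, n_cells + one column per method
    roc: dict[str, RocResult]
    correlation_with_n: dict[str, float]

    def ranking(self) -> list[str]:
        """Method names ordered by decreasing AUC."""
        return sorted(self.roc, key=lambda m: self.roc[m].auc, reverse=True)


def _validate_labels(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([1 if str(l).startswith("poly") else 0 for l in labels])
    if y.all() or not y.any():
        raise ValueError("both monoclonal and polyclonal samples are required")
    return y


def auc_score(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Mann-Whitney AUC: P(poly outscores mono), ties half-credited."""
    s = np.asarray(scores, dtype=float)
    y = _validate_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    ranks = rankdata(s)  # average ranks handle ties exactly
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> RocResult:
    """Full ROC curve with AUC and Youden-optimal precision/recall.

    Thresholds are the distinct scores plus a +inf sentinel; a sample is
    predicted polyclonal iff its score >= threshold, so the curve starts at
    (0, 0) and ends at (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = _validate_labels(labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = s >= t
        tpr[i] = (pred & (y == 1)).sum() / n_pos
        fpr[i] = (pred & (y == 0)).sum() / n_neg

    auc = float(np.trapezoid(tpr, fpr))

    youden = tpr - fpr
    best = int(np.argmax(youden))  # argmax returns the first = highest threshold
    op = float(thresholds[best])
    pred = s >= op
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_pos
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        precision=float(precision),
        recall=float(recall),
        operating_threshold=op,
    )


def benchmark_methods(
    cohort: Sequence[SimulatedSample],
    methods: Iterable[str] = ("complexity", "ma", "guo"),
) -> BenchmarkResult:
    """Score every sample with every method and evaluate the discrimination.

    Also reports the Pearson correlation of each method's score with the
    per-sample cell count, the cell-number robustness diagnostic.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("at least one method is required")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}; choose from {sorted(METHODS)}")
    if not cohort:
        raise ValueError("empty cohort")

    records = []
    for sample in cohort:
        rec = {
            "sample_id": sample.sample_id,
            "label": sample.truth.label,
            "n_cells": sample.matrix.n_cells,
        }
        for name in methods:
            rec[name] = METHODS[name](sample.matrix)
        records.append(rec)
    scores = pd.DataFrame.from_records(records)

    labels = scores["label"].tolist()
    roc = {name: roc_curve(scores[name].to_numpy(), labels) for name in methods}
    corr = {
        name: float(pearsonr(scores[name], scores["n_cells"])[0])
        for name in methods
    }
    return BenchmarkResult(scores=scores, roc=roc, correlation_with_n=corr)
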