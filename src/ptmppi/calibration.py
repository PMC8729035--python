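"""Ensemble aggregation, calibration measurement and dual thresholding.

For an input x_j scored by M models, the ensemble posterior is the
member mean p(y_j = c) = (1/M) Σ_i p(y_i = c | x_j); the prediction is its
argmax ŷ_j, the confidence p̂_j its maximum, and the confidence SD the
population standard deviation (divisor M) of the members' probability for
ŷ_j. Calibration is measured with expected calibration error over K
equally spaced confidence bins:

    ECE = Σ_k (|B_k| / n) · |accu(B_k) − conf(B_k)|

Selective prediction uses per-class dual cutoffs — a minimum confidence and
a maximum confidence SD, both taken as a train-set percentile (default the
median) of the predictions of that class — so minority classes, whose
confidence range sits lower than the majority's, are thresholded on their
own scale rather than a global one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import (
    ALL_LABELS,
    NEGATIVE_LABEL,
    ClassThresholds,
    EnsemblePrediction,
)


def ensemble_aggregate(
    member_probs: np.ndarray,
    sample_id: str = "",
    labels: Sequence[str] = ALL_LABELS,
    gold_label: str | None = None,
    pubmed_id: str = "",
    pair: tuple[str, str] = ("", ""),
) -> EnsemblePrediction:
    """Aggregate an (M, C) member-probability matrix into one prediction.

    Mean over members; confidence is the max of the mean vector and the
    predicted class its argmax (lowest index on ties).
    """
    probs = np.asarray(member_probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError(f"member_probs must be 2-D (M, C), got shape {probs.shape}")
    if probs.shape[1] != len(labels):
        raise ValueError(
            f"{probs.shape[1]} columns but {len(labels)} labels"
        )
    mean = probs.mean(axis=0)
    pred_idx = int(np.argmax(mean))
    confidence = float(mean[pred_idx])
    sd = confidence_sd(probs, pred_idx)
    return EnsemblePrediction(
        sample_id=sample_id,
        member_probs=probs,
        mean_probs=mean,
        pred_class=labels[pred_idx],
        confidence=confidence,
        confidence_sd=sd,
        gold_label=gold_label,
        pubmed_id=pubmed_id,
        pair=pair,
    )


def confidence_sd(member_probs: np.ndarray, pred_idx: int) -> float:
    """Population SD (divisor M) of member probabilities for the predicted class."""
    probs = np.asarray(member_probs, dtype=float)
    col = probs[:, pred_idx]
    if np.all(col == col[0]):  # exact zero for identical members
        return 0.0
    return float(np.sqrt(np.mean((col - col.mean()) ** 2)))


@dataclass
class CalibrationReport:
    """Per-bin reliability statistics and the resulting ECE."""

    n_bins: int
    bin_counts: list[int]
    bin_accuracy: list[float]
    bin_confidence: list[float]
    n: int
    ece: float

    @property
    def bin_edges(self) -> list[float]:
        return [k / self.n_bins for k in range(self.n_bins + 1)]


def compute_ece(
    confidences: Sequence[float],
    correct: Sequence[bool],
    n_bins: int = 10,
) -> CalibrationReport:
    """Expected calibration error over equally spaced confidence bins.

    Bins are half-open ``(lower, upper]`` with the first bin closed at 0;
    empty bins contribute zero. Accuracy/confidence per bin are simple
    means over the bin's members.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    conf = np.asarray(confidences, dtype=float)
    corr = np.asarray(correct, dtype=bool)
    if conf.shape != corr.shape:
        raise ValueError("confidences and correctness must be aligned")
    n = len(conf)
    counts, accs, mean_confs = [], [], []
    ece = 0.0
    for k in range(n_bins):
        lo, hi = k / n_bins, (k + 1) / n_bins
        in_bin = (conf > lo) & (conf <= hi) if k > 0 else (conf >= 0) & (conf <= hi)
        cnt = int(in_bin.sum())
        counts.append(cnt)
        if cnt == 0:
            accs.append(0.0)
            mean_confs.append(0.0)
            continue
        acc = float(corr[in_bin].mean())
        mc = float(conf[in_bin].mean())
        accs.append(acc)
        mean_confs.append(mc)
        ece += cnt / n * abs(acc - mc)
    return CalibrationReport(
        n_bins=n_bins,
        bin_counts=counts,
        bin_accuracy=accs,
        bin_confidence=mean_confs,
        n=n,
        ece=float(ece),
    )


def ece_of_predictions(
    predictions: Sequence[EnsemblePrediction],
    n_bins: int = 10,
    population: str = "positive",
) -> CalibrationReport:
    """ECE of aggregated predictions against their gold labels.

    ``population`` selects which predictions are scored: ``"positive"``
    (default) keeps only those predicted as a PTM class, ``"all"`` keeps
    everything. Every scored prediction must carry a gold label.
    """
    if population not in ("positive", "all"):
        raise ValueError(f"unknown population {population!r}")
    preds = [
        p
        for p in predictions
        if population == "all" or p.pred_class != NEGATIVE_LABEL
    ]
    for p in preds:
        if p.gold_label is None:
            raise ValueError(f"prediction {p.sample_id!r} lacks a gold label")
    return compute_ece(
        [p.confidence for p in preds],
        [p.pred_class == p.gold_label for p in preds],
        n_bins,
    )


def derive_thresholds(
    predictions: Sequence[EnsemblePrediction],
    percentile: float = 50.0,
    classes: Iterable[str] | None = None,
) -> ClassThresholds:
    """Per-predicted-class percentile cutoffs from (train-set) predictions.

    For each class with at least one prediction, ``conf_min`` is the given
    percentile (linear interpolation) of its confidences and ``sd_max`` the
    same percentile of its confidence SDs. Classes without predictions are
    omitted with a warning.
    """
    wanted = list(classes) if classes is not None else sorted(
        {p.pred_class for p in predictions}
    )
    conf_min: dict[str, float] = {}
    sd_max: dict[str, float] = {}
    for cls in wanted:
        rows = [p for p in predictions if p.pred_class == cls]
        if not rows:
            warnings.warn(f"no predictions for class {cls!r}; threshold omitted")
            continue
        conf_min[cls] = float(
            np.percentile([p.confidence for p in rows], percentile)
        )
        sd_max[cls] = float(
            np.percentile([p.confidence_sd for p in rows], percentile)
        )
    return ClassThresholds(conf_min=conf_min, sd_max=sd_max, percentile=percentile)


def filter_high_quality(
    predictions: Sequence[EnsemblePrediction],
    thresholds: ClassThresholds,
) -> tuple[list[EnsemblePrediction], list[EnsemblePrediction]]:
    """Partition predictions into (selected, rejected) by the dual rule.

    Selected iff the predicted class is positive, covered by the
    thresholds, and confidence >= conf_min AND confidence SD <= sd_max
    (both inclusive). Negative-class and uncovered-class predictions are
    rejected.
    """
    selected: list[EnsemblePrediction] = []
    rejected: list[EnsemblePrediction] = []
    for p in predictions:
        if p.pred_class == NEGATIVE_LABEL or not thresholds.covers(p.pred_class):
            rejected.append(p)
            continue
        if (
            p.confidence >= thresholds.conf_min[p.pred_class]
            and p.confidence_sd <= thresholds.sd_max[p.pred_class]
        ):
            selected.append(p)
        else:
            rejected.append(p)
    return selected, rejected


__all__ = [
    "ensemble_aggregate",
    "confidence_sd",
    "CalibrationReport",
    "compute_ece",
    "ece_of_predictions",
    "derive_thresholds",
    "filter_high_quality",
]
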