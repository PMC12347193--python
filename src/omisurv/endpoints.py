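"""Task-specific evaluation: cancer-type classification metrics, Huber loss
for TLS-ratio regression, and TLS cohort handling.

Classification of the primary cancer type is a 33-way problem by default;
metrics delegate to scikit-learn and are assembled into a
:class:`ClassificationReport` mirroring the usual per-class
precision/recall/F1/support table plus the confusion matrix. The TLS ratio
(segmented tertiary-lymphoid-structure area over total tissue area, in
[0, 1]) is evaluated with the Huber loss, compared against manual annotation
by a paired t-test, and related to survival through a median split and
log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .matrix import InvalidInputError
from .simulate import TLSData
from .survival import SurvivalData, logrank_test

__all__ = [
    "ClassificationReport",
    "classification_report",
    "huber_loss",
    "tls_filter_and_split",
    "tls_group_compare",
    "tls_paired_compare",
]


@dataclass
class ClassificationReport:
    """Per-class and aggregate classification metrics.

    Classes with zero support have NaN precision/recall/F1 (no samples to
    score). Supports sum to n, each confusion-matrix row sums to its class's
    support, and accuracy equals trace / n.
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    confusion: np.ndarray
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    @property
    def n_classes(self) -> int:
        return len(self.support)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": np.arange(self.n_classes),
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        )


def classification_report(
    predicted: np.ndarray, true: np.ndarray, n_classes: int = 33
) -> ClassificationReport:
    """Standard multi-class metrics over integer labels in [0, n_classes)."""
    predicted = np.asarray(predicted, dtype=int)
    true = np.asarray(true, dtype=int)
    if predicted.shape != true.shape or predicted.ndim != 1:
        raise InvalidInputError("label vectors must be 1-d and equal length")
    for name, v in (("predicted", predicted), ("true", true)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise InvalidInputError(
                f"{name} labels out of range [0, {n_classes})"
            )
    labels = np.arange(n_classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        true, predicted, labels=labels, zero_division=np.nan
    )
    confusion = _sk_confusion(true, predicted, labels=labels)
    present = support > 0
    w = support[present] / support.sum()
    return ClassificationReport(
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        confusion=confusion,
        accuracy=float(np.trace(confusion) / len(true)),
        weighted_precision=float(np.nansum(w * prec[present])),
        weighted_recall=float(np.nansum(w * rec[present])),
        weighted_f1=float(np.nansum(w * f1[present])),
    )


def huber_loss(
    pred: np.ndarray, target: np.ndarray, delta: float = 1.0
) -> float:
    """Mean Huber loss: quadratic within ``|r| <= delta``, linear beyond.

    ``0.5 r^2`` for small residuals, ``delta (|r| - delta/2)`` otherwise —
    continuous and continuously differentiable at the crossover.
    """
    if delta <= 0:
        raise InvalidInputError(f"delta must be positive, got {delta}")
    pred = np.asarray(pred, dtype=np.float64).reshape(-1)
    target = np.asarray(target, dtype=np.float64).reshape(-1)
    if pred.shape != target.shape:
        raise InvalidInputError("pred and target must have equal length")
    r = np.abs(pred - target)
    return float(
        np.mean(np.where(r <= delta, 0.5 * r * r, delta * (r - 0.5 * delta)))
    )


def tls_filter_and_split(
    tls: TLSData, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Exclude records with missing TLS labels, then split 80/20.

    Returns ``(train_idx, test_idx, n_excluded)`` as indices into the
    original records; exclusion happens first, so the split fractions are
    computed on the retained set only.
    """
    retained = np.flatnonzero(~np.isnan(tls.ratio))
    n_excluded = len(tls.ratio) - retained.size
    if retained.size == 0:
        raise InvalidInputError("all TLS labels are missing")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(retained)
    n_test = int(round(test_fraction * retained.size))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test]), n_excluded


def tls_group_compare(
    ratios: np.ndarray, records: SurvivalData
) -> tuple[np.ndarray, float, float]:
    """Median-split the TLS ratios and log-rank test the two survival groups.

    Ties at the median go to the low group (<= median). Returns the
    per-sample 'high'/'low' labels and the log-rank (statistic, p).
    """
    ratios = np.asarray(ratios, dtype=np.float64).reshape(-1)
    if ratios.size < 4 or len(records) != ratios.size:
        raise InvalidInputError("need >= 4 aligned samples with TLS and survival")
    if np.isnan(ratios).any():
        raise InvalidInputError("ratios must not contain missing values here")
    med = float(np.median(ratios))
    labels = np.where(ratios <= med, "low", "high").astype(object)
    low = np.flatnonzero(labels == "low")
    high = np.flatnonzero(labels == "high")
    if low.size < 2 or high.size < 2:
        raise InvalidInputError("degenerate median split (a group has < 2 members)")
    stat, p = logrank_test(records.subset(low), records.subset(high))
    return labels, stat, p


def tls_paired_compare(
    predicted: np.ndarray, manual: np.ndarray
) -> tuple[float, float]:
    """Paired t-test of predicted vs. manually annotated TLS ratios.

    Returns (t statistic, two-sided p). A non-significant result indicates
    the predictions are unbiased relative to the manual annotations.
    """
    predicted = np.asarray(predicted, dtype=np.float64).reshape(-1)
    manual = np.asarray(manual, dtype=np.float64).reshape(-1)
    if predicted.shape != manual.shape or predicted.size < 2:
        raise InvalidInputError("need >= 2 aligned prediction/annotation pairs")
    t, p = stats.ttest_rel(predicted, manual)
    return float(t), float(p)
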