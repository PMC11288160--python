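"""Posterior analysis of attribute discriminative power and standard metrics.

Two per-attribute statistics drive the discriminatory plot:

* Fisher's ratio  FR = (mu1 - mu0)^2 / (s1^2 + s0^2) — between-class
  separation over within-class spread (unbiased class variances);
* fold change  FC = |mu1 - mu0| — the distance between the class-conditional
  centers (a log2 ratio variant is available for strictly positive
  attributes).

The posterior group-frequency analysis asks how often each attribute group
was sampled into the high-performing (selected) holdouts versus the rest:
groups carrying discriminative signal are over-represented among the
selected bags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .dataio import GROUPS, FeatureMatrix
from .errors import ContractError


def _split_classes(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise ContractError("values and labels must have equal length")
    v0, v1 = values[labels == 0], values[labels == 1]
    if v0.size == 0 or v1.size == 0:
        raise ContractError("both classes must be present")
    return v0, v1


def fisher_ratio(values, labels) -> float:
    """(mu1 - mu0)^2 / (s1^2 + s0^2) with unbiased class variances.

    Zero within-class variance with equal means gives 0; with different means
    the attribute separates the classes perfectly and +inf is returned as a
    degeneracy sentinel.
    """
    v0, v1 = _split_classes(values, labels)
    if v0.size < 2 or v1.size < 2:
        raise ContractError("each class needs >= 2 members for a variance")
    num = (v1.mean() - v0.mean()) ** 2
    den = v1.var(ddof=1) + v0.var(ddof=1)
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / den)


def fold_change(values, labels, *, log2_ratio: bool = False) -> float:
    """|mu1 - mu0|, the inter-class distance between distribution centers.

    With ``log2_ratio=True`` returns |log2(mu1 / mu0)| instead (both class
    means must be strictly positive).
    """
    v0, v1 = _split_classes(values, labels)
    m0, m1 = v0.mean(), v1.mean()
    if log2_ratio:
        if m0 <= 0 or m1 <= 0:
            raise ContractError("log2 fold change requires positive class means")
        return float(abs(np.log2(m1 / m0)))
    return float(abs(m1 - m0))


@dataclass(frozen=True)
class DiscriminatoryScore:
    attribute_name: str
    group: str
    fisher_ratio: float
    fold_change: float
    degenerate: bool = False


def discriminatory_table(data: FeatureMatrix) -> list[DiscriminatoryScore]:
    """Fisher's ratio and fold change for every attribute of labeled data.

    Constant attributes and attributes with perfect separation are flagged
    ``degenerate`` rather than dropped.
    """
    labels = data.labels
    if np.any(labels < 0):
        raise ContractError("discriminatory analysis requires fully labeled data")
    if len(np.unique(labels)) < 2:
        raise ContractError("both classes must be present")
    scores = []
    for j, name in enumerate(data.attribute_names):
        col = data.X[:, j]
        fr = fisher_ratio(col, labels)
        fc = fold_change(col, labels)
        scores.append(
            DiscriminatoryScore(
                attribute_name=name,
                group=data.attribute_groups[name],
                fisher_ratio=fr,
                fold_change=fc,
                degenerate=not np.isfinite(fr) or np.ptp(col) == 0,
            )
        )
    return scores


def group_frequency(holdouts, *, selected_only: bool = False) -> dict[str, float]:
    """Fraction of holdouts whose attribute subset contains each group.

    Accepts a list of holdouts or a ConsensusModel (whose ``selected`` list is
    used).  Groups never sampled appear with frequency 0.0.
    """
    if hasattr(holdouts, "selected"):
        holdouts = holdouts.selected
    holdouts = list(holdouts)
    if selected_only:
        holdouts = [h for h in holdouts if getattr(h, "fitted", True)]
    if not holdouts:
        raise ContractError("no holdouts to analyze")
    freq = {g: 0.0 for g in GROUPS}
    for h in holdouts:
        for g in h.groups:
            freq[g] += 1.0
    return {g: c / len(holdouts) for g, c in freq.items()}


@dataclass
class MetricsReport:
    """Standard two-class metrics with the confusion matrix oriented
    rows = predicted class, columns = target class."""

    confusion: np.ndarray  # [[TN, FN], [FP, TP]] i.e. confusion[pred, true]
    accuracy: float
    mcc: float
    precision: dict[int, float]
    fdr: dict[int, float]
    recall: dict[int, float]
    fnr: dict[int, float]
    auc: float | None = None
    roc_points: np.ndarray | None = None  # (k, 2) columns FPR, TPR

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "precision": {str(k): v for k, v in self.precision.items()},
            "fdr": {str(k): v for k, v in self.fdr.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "fnr": {str(k): v for k, v in self.fnr.items()},
            "auc": self.auc,
        }


def confusion_and_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Confusion matrix, accuracy, MCC and (optionally) the ROC curve / AUC.

    The AUC sweeps the threshold over the unique scores and integrates by the
    trapezoid rule, so tied scores contribute diagonal segments (equivalent to
    the Mann-Whitney U statistic with 0.5 per tie).  With single-class truth
    the AUC is undefined and left as None.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ContractError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ContractError("empty evaluation set")
    if (set(np.unique(y_true)) | set(np.unique(y_pred))) - {0, 1}:
        raise ContractError("labels must be 0/1")

    conf = np.zeros((2, 2), dtype=int)  # [pred, true]
    for p, t in ((0, 0), (0, 1), (1, 0), (1, 1)):
        conf[p, t] = int(np.sum((y_pred == p) & (y_true == t)))
    tn, fn, fp, tp = conf[0, 0], conf[0, 1], conf[1, 0], conf[1, 1]
    n = conf.sum()
    accuracy = (tp + tn) / n

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)

    precision, fdr, recall, fnr = {}, {}, {}, {}
    for cls, (tp_c, fp_c, fn_c) in {1: (tp, fp, fn), 0: (tn, fn, fp)}.items():
        pred_c = tp_c + fp_c
        true_c = tp_c + fn_c
        precision[cls] = tp_c / pred_c if pred_c else float("nan")
        fdr[cls] = fp_c / pred_c if pred_c else float("nan")
        recall[cls] = tp_c / true_c if true_c else float("nan")
        fnr[cls] = fn_c / true_c if true_c else float("nan")

    auc_val, roc_points = None, None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != y_true.shape:
            raise ContractError("scores must match y_true length")
        if len(np.unique(y_true)) == 2:
            fpr, tpr, _ = roc_curve(y_true, scores)
            roc_points = np.column_stack([fpr, tpr])
            auc_val = float(_trapezoid_auc(fpr, tpr))
    return MetricsReport(
        confusion=conf,
        accuracy=float(accuracy),
        mcc=float(mcc),
        precision=precision,
        fdr=fdr,
        recall=recall,
        fnr=fnr,
        auc=auc_val,
        roc_points=roc_points,
    )
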