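"""Multi-label evaluation suite.

Sample-based metrics: subset accuracy (exact label-vector match), pair
accuracy (per-sample Jaccard of positive-label sets) and per-label accuracy.
Label-based metrics build on per-label confusion counts: average label
accuracy, macro sensitivity, macro specificity and macro F1. Micro-averaged
ROC/AUC pools every (sample, label) decision.

Conventions (documented because the definitions leave them open):

* A sample with empty true and predicted positive sets contributes 1 to
  pair accuracy — a correctly predicted no-finding sample is not penalised.
* Macro ratios with a zero denominator are excluded from that ratio's mean
  (with a warning); ``zero_denominator='zero'`` counts them as 0 instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_curve

log = logging.getLogger(__name__)


class ShapeError(ValueError):
    pass


def _check_pair(Y, Yhat):
    Y = np.asarray(Y)
    Yhat = np.asarray(Yhat)
    if Y.shape != Yhat.shape or Y.ndim != 2:
        raise ShapeError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    return Y, Yhat


def subset_accuracy(Y, Yhat) -> float:
    """Fraction of samples whose whole predicted label vector matches."""
    Y, Yhat = _check_pair(Y, Yhat)
    return float((Y == Yhat).all(axis=1).mean())


def pair_accuracy(Y, Yhat) -> float:
    """Mean per-sample Jaccard similarity of positive-label sets."""
    Y, Yhat = _check_pair(Y, Yhat)
    inter = ((Y == 1) & (Yhat == 1)).sum(axis=1).astype(float)
    union = ((Y == 1) | (Yhat == 1)).sum(axis=1).astype(float)
    jac = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    return float(jac.mean())


def per_label_accuracy(Y, Yhat) -> np.ndarray:
    """Accuracy of each label over samples (length-L vector)."""
    Y, Yhat = _check_pair(Y, Yhat)
    return (Y == Yhat).mean(axis=0)


def confusion_counts(Y, Yhat) -> dict[str, np.ndarray]:
    """Per-label TP/FP/TN/FN; each quadruple sums to n."""
    Y, Yhat = _check_pair(Y, Yhat)
    tp = ((Y == 1) & (Yhat == 1)).sum(axis=0)
    fp = ((Y == 0) & (Yhat == 1)).sum(axis=0)
    tn = ((Y == 0) & (Yhat == 0)).sum(axis=0)
    fn = ((Y == 1) & (Yhat == 0)).sum(axis=0)
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def _macro_ratio(num: np.ndarray, den: np.ndarray, name: str, zero_denominator: str) -> float:
    den = den.astype(float)
    defined = den > 0
    if not defined.all():
        log.warning("%s undefined for %d label(s) (zero denominator)", name, int((~defined).sum()))
    if zero_denominator == "zero":
        vals = np.where(defined, num / np.where(defined, den, 1), 0.0)
        return float(vals.mean())
    if not defined.any():
        return float("nan")
    return float((num[defined] / den[defined]).mean())


def macro_summary(confusion: dict[str, np.ndarray], zero_denominator: str = "exclude") -> dict[str, float]:
    """Average label accuracy, macro sensitivity/specificity/F1 from counts."""
    tp, fp, tn, fn = (confusion[k].astype(float) for k in ("tp", "fp", "tn", "fn"))
    acc_avelab = _macro_ratio(tp + tn, tp + tn + fp + fn, "ACC_avelab", zero_denominator)
    sen = _macro_ratio(tp, tp + fn, "SEN", zero_denominator)
    spe = _macro_ratio(tn, tn + fp, "SPE", zero_denominator)
    f1 = _macro_ratio(2 * tp, 2 * tp + fp + fn, "F1", zero_denominator)
    return {"acc_avelab": acc_avelab, "sen": sen, "spe": spe, "f1": f1}


def roc_auc(Y, scores, average: str = "micro") -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC.

    ``micro`` pools all (sample, label) pairs into one binary problem;
    ``macro`` averages per-label AUCs over labels with both classes present.
    Returns (fpr, tpr, auc).
    """
    Y = np.asarray(Y)
    scores = np.asarray(scores, dtype=float)
    if Y.shape != scores.shape:
        raise ShapeError(f"shape mismatch: {Y.shape} vs {scores.shape}")
    if average == "micro":
        fpr, tpr, _ = roc_curve(Y.ravel(), scores.ravel())
        return fpr, tpr, float(np.trapezoid(tpr, fpr))
    if average == "macro":
        aucs = []
        for l in range(Y.shape[1]):
            col = Y[:, l]
            if col.min() == col.max():
                log.warning("label %d single-class; excluded from macro AUC", l)
                continue
            fpr, tpr, _ = roc_curve(col, scores[:, l])
            aucs.append(np.trapezoid(tpr, fpr))
        fpr, tpr, _ = roc_curve(Y.ravel(), scores.ravel())
        return fpr, tpr, float(np.mean(aucs)) if aucs else float("nan")
    raise ValueError(f"unknown averaging {average!r}")


@dataclass
class EvaluationReport:
    """Every metric for one evaluation (one fold, or one held-out split)."""

    acc: float
    acc_pair: float
    acc_lab: np.ndarray
    confusion: dict[str, np.ndarray]
    acc_avelab: float
    sen: float
    spe: float
    f1: float
    auc: float
    roc_points: tuple[np.ndarray, np.ndarray] | None = None

    def scalars(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "acc_pair": self.acc_pair,
            "acc_avelab": self.acc_avelab,
            "sen": self.sen,
            "spe": self.spe,
            "f1": self.f1,
            "auc": self.auc,
        }

    def to_dict(self) -> dict:
        d = dict(self.scalars())
        d["acc_lab"] = np.asarray(self.acc_lab).tolist()
        d["confusion"] = {k: np.asarray(v).tolist() for k, v in self.confusion.items()}
        return d


def evaluate(Y, Yhat, scores=None, zero_denominator: str = "exclude", keep_roc: bool = False) -> EvaluationReport:
    """Compute the full report; ``scores`` (real-valued) enable ROC/AUC."""
    conf = confusion_counts(Y, Yhat)
    macro = macro_summary(conf, zero_denominator)
    if scores is not None:
        fpr, tpr, auc = roc_auc(Y, scores)
        roc_pts = (fpr, tpr) if keep_roc else None
    else:
        auc, roc_pts = float("nan"), None
    return EvaluationReport(
        acc=subset_accuracy(Y, Yhat),
        acc_pair=pair_accuracy(Y, Yhat),
        acc_lab=per_label_accuracy(Y, Yhat),
        confusion=conf,
        acc_avelab=macro["acc_avelab"],
        sen=macro["sen"],
        spe=macro["spe"],
        f1=macro["f1"],
        auc=auc,
        roc_points=roc_pts,
    )
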