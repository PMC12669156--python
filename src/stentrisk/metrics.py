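"""Classifier evaluation: discrimination, calibration, and clinical utility.

The report covers the six headline metrics (precision, sensitivity,
specificity, accuracy, F1, ROC-AUC) plus PR-AUC, a binned calibration
curve with the Brier score, and decision-curve analysis. Net benefit at a
risk threshold p_t is

    NB = TP/N - (FP/N) * p_t / (1 - p_t),

traded against the treat-all line ``prevalence - (1 - prevalence) * p_t /
(1 - p_t)`` and the treat-none line at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, precision_recall_curve


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    PRE: float
    SEN: float
    SPE: float
    ACC: float
    F1: float
    ROC_AUC: float = float("nan")
    PR_AUC: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "PRE": self.PRE, "SEN": self.SEN, "SPE": self.SPE, "ACC": self.ACC,
            "F1": self.F1, "ROC-AUC": self.ROC_AUC, "PR-AUC": self.PR_AUC,
        }


@dataclass
class CalibrationCurve:
    bin_edges: np.ndarray
    mean_predicted: np.ndarray  # per non-empty bin
    observed_fraction: np.ndarray
    counts: np.ndarray  # per bin, including empty ones
    brier: float


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )


def _check_pairs(y, p):
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    return y, p


def confusion(y, p, threshold: float = 0.5) -> ConfusionCounts:
    """Counts at a decision threshold; ties (p == threshold) predict positive."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    y, p = _check_pairs(y, p)
    pred = p >= threshold
    return ConfusionCounts(
        TP=int((pred & (y == 1)).sum()),
        FP=int((pred & (y == 0)).sum()),
        TN=int((~pred & (y == 0)).sum()),
        FN=int((~pred & (y == 1)).sum()),
    )


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """The six-metric panel from a confusion table (areas filled separately).

    0/0 ratios (e.g. precision with no predicted positives) are reported as
    0 with a warning.
    """
    if c.N <= 0:
        raise ValueError("empty confusion table")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (0/0); reporting 0")
            return 0.0
        return num / den

    pre = ratio(c.TP, c.TP + c.FP, "precision")
    sen = ratio(c.TP, c.TP + c.FN, "sensitivity")
    spe = ratio(c.TN, c.TN + c.FP, "specificity")
    acc = (c.TP + c.TN) / c.N
    f1 = 2 * pre * sen / (pre + sen) if (pre + sen) > 0 else 0.0
    return MetricsReport(pre, sen, spe, acc, f1)


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (recall)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2 * precision * sensitivity / (precision + sensitivity)


def roc_auc(y, p) -> float:
    """Trapezoidal ROC area; equals the tie-adjusted concordance probability."""
    y, p = _check_pairs(y, p)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC requires both classes")
    return float(roc_auc_score(y, p))


def pr_auc(y, p) -> float:
    """Average-precision (step-interpolated) area under precision-recall."""
    y, p = _check_pairs(y, p)
    if len(np.unique(y)) < 2:
        raise ValueError("PR-AUC requires both classes")
    return float(average_precision_score(y, p))


def full_report(y, p, threshold: float = 0.5) -> MetricsReport:
    base = classification_metrics(confusion(y, p, threshold))
    return MetricsReport(
        base.PRE, base.SEN, base.SPE, base.ACC, base.F1, roc_auc(y, p), pr_auc(y, p)
    )


def brier_and_calibration(y, p, bins: int = 10) -> CalibrationCurve:
    """Brier score plus an equal-width reliability curve.

    Empty bins keep a zero count but contribute no curve point. The right
    edge of the last bin is inclusive.
    """
    y, p = _check_pairs(y, p)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    brier = float(np.mean((p - y) ** 2))
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    mean_pred, obs = [], []
    for b in range(bins):
        m = idx == b
        if m.any():
            mean_pred.append(float(p[m].mean()))
            obs.append(float(y[m].mean()))
    return CalibrationCurve(edges, np.array(mean_pred), np.array(obs), counts, brier)


def net_benefit(c: ConfusionCounts, p_t: float) -> float:
    """NB = TP/N - (FP/N) * p_t / (1 - p_t)."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("threshold probability must lie in (0, 1)")
    return c.TP / c.N - (c.FP / c.N) * p_t / (1.0 - p_t)


def dca_curve(y, p, thresholds=None) -> NetBenefitCurve:
    """Decision-curve analysis over a grid of risk thresholds.

    At each p_t patients with predicted risk >= p_t are treated; the model
    curve is compared with treat-all and treat-none reference strategies.
    """
    y, p = _check_pairs(y, p)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds <= 0).any() or (thresholds >= 1).any():
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    prev = float(np.mean(y))
    nb_model = np.array([net_benefit(confusion(y, p, t), t) for t in thresholds])
    nb_all = prev - (1.0 - prev) * thresholds / (1.0 - thresholds)
    return NetBenefitCurve(thresholds, nb_model, nb_all, np.zeros_like(thresholds))


def roc_points(y, p) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(y, p)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_points(y, p) -> pd.DataFrame:
    prec, rec, thr = precision_recall_curve(y, p)
    return pd.DataFrame({"recall": rec, "precision": prec})
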