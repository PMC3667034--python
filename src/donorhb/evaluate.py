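"""Predictive-accuracy assessment for dynamic Hb predictions.

Covers the visit-wise mean squared prediction error
MSPE_t = sum_i (yhat_it - y_it)^2 / N_t, information criteria, eligibility
classification at the clinical cut-off, ROC/AUC, and a paired bootstrap test
for the difference between two models' AUCs.

Classification convention: the positive class is *deferral* (observed Hb
below the clinical cut-off), so sensitivity is the true-positive rate on
deferrals and specificity the true-negative rate on eligible visits.  The
ROC score is the negated predicted Hb (a lower prediction means deferral is
more likely).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .panel import EligibilityRule, Gender
from .results import FitResult, PredictionSet

__all__ = [
    "ClassificationResult",
    "EvaluationReport",
    "mspe_by_visit",
    "overall_mspe",
    "information_criteria",
    "classification_at_cutoff",
    "roc_auc",
    "compare_auc_bootstrap",
    "evaluate_predictions",
]


def mspe_by_visit(pred: PredictionSet) -> pd.DataFrame:
    """Mean squared prediction error per visit number.

    Returns a frame with columns ``visit``, ``mspe`` and ``n`` (the number of
    donors observed at that visit).
    """
    if len(pred) == 0:
        raise ValueError("empty prediction set")
    df = pred.data
    err2 = (df["y_pred"] - df["y_obs"]) ** 2
    out = (
        pd.DataFrame({"visit": df["visit"], "err2": err2})
        .groupby("visit", as_index=False)
        .agg(mspe=("err2", "mean"), n=("err2", "size"))
    )
    return out


def overall_mspe(pred: PredictionSet) -> float:
    """MSPE pooled over all visits."""
    df = pred.data
    return float(np.mean((df["y_pred"] - df["y_obs"]) ** 2))


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(AIC, BIC) from the fit's maximized log-likelihood.

    AIC = -2 l + 2k and BIC = -2 l + k log(n) with k the number of free
    parameters and n the number of observations.
    """
    if fit.loglik is None or not math.isfinite(fit.loglik):
        raise ValueError("fit has no finite log-likelihood")
    aic = -2.0 * fit.loglik + 2.0 * fit.n_params
    bic = -2.0 * fit.loglik + fit.n_params * math.log(fit.n_obs)
    return float(aic), float(bic)


@dataclass(frozen=True)
class ClassificationResult:
    """2x2 table at the clinical cut-off; positive class = deferral."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int


def _labels(pred: PredictionSet, rule: EligibilityRule) -> tuple[np.ndarray, np.ndarray]:
    cutoff = rule.cutoff(pred.gender)
    truth = (pred.data["y_obs"].to_numpy() < cutoff)
    score = -pred.data["y_pred"].to_numpy()  # higher = more deferral-like
    return truth, score


def classification_at_cutoff(
    pred: PredictionSet, rule: EligibilityRule = EligibilityRule()
) -> ClassificationResult:
    """Sensitivity/specificity of predicted deferral at the clinical cut-off.

    Both the state variable (observed Hb below cut-off) and the predicted
    label (predicted Hb below the same cut-off) use the clinical threshold.
    When a truth class is absent the corresponding rate is None, not 0.
    """
    cutoff = rule.cutoff(pred.gender)
    truth = pred.data["y_obs"].to_numpy() < cutoff
    pos = pred.data["y_pred"].to_numpy() < cutoff
    tp = int(np.sum(truth & pos))
    fn = int(np.sum(truth & ~pos))
    fp = int(np.sum(~truth & pos))
    tn = int(np.sum(~truth & ~pos))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return ClassificationResult(sens, spec, tp, fp, tn, fn)


def roc_auc(
    pred: PredictionSet,
    rule: EligibilityRule = EligibilityRule(),
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """ROC curve and AUC for discriminating deferral from eligibility.

    The AUC is the Mann-Whitney statistic (ties weighted 0.5); its standard
    error comes from a stratified bootstrap over prediction entries
    (resampling within each truth class, ``n_boot`` replicates, seeded).
    Returns (roc points with columns fpr/tpr/threshold, auc, se).
    """
    truth, score = _labels(pred, rule)
    if truth.all() or not truth.any():
        raise ValueError("ROC requires both deferral and eligible entries")
    fpr, tpr, thr = roc_curve(truth, score)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    auc = float(roc_auc_score(truth, score))
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(truth)[0]
    neg_idx = np.nonzero(~truth)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ineg = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = roc_auc_score(truth[idx], score[idx])
    return points, auc, float(np.std(aucs, ddof=1))


def compare_auc_bootstrap(
    pred_a: PredictionSet,
    pred_b: PredictionSet,
    n_boot: int = 2000,
    seed: int = 0,
    rule: EligibilityRule = EligibilityRule(),
) -> tuple[float, float]:
    """Paired bootstrap test for a difference in AUC between two models.

    Both prediction sets must cover the same (donor, visit) entries.  Entry
    indices are resampled jointly (the same indices for both models,
    stratified by truth class), which preserves the correlation between the
    two AUCs; the two-sided p-value uses a normal approximation for
    D / sd(D*).  Returns (auc_a - auc_b, p_value).
    """
    a, b = pred_a.data, pred_b.data
    if len(a) != len(b) or not (
        a[["donor_id", "visit"]].reset_index(drop=True)
        .equals(b[["donor_id", "visit"]].reset_index(drop=True))
    ):
        raise ValueError("prediction sets are not paired on (donor, visit)")
    if Gender(pred_a.gender) is not Gender(pred_b.gender):
        raise ValueError("prediction sets have different genders")
    truth, score_a = _labels(pred_a, rule)
    _, score_b = _labels(pred_b, rule)
    if truth.all() or not truth.any():
        raise ValueError("AUC comparison requires both truth classes")
    diff = float(roc_auc_score(truth, score_a) - roc_auc_score(truth, score_b))
    rng = np.random.default_rng(seed)
    pos_idx = np.nonzero(truth)[0]
    neg_idx = np.nonzero(~truth)[0]
    diffs = np.empty(n_boot)
    for rep in range(n_boot):
        ip = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ineg = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([ip, ineg])
        t = truth[idx]
        diffs[rep] = roc_auc_score(t, score_a[idx]) - roc_auc_score(t, score_b[idx])
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        return diff, 1.0 if diff == 0.0 else 0.0
    z = diff / sd
    p = float(2.0 * norm.sf(abs(z)))
    return diff, min(p, 1.0)


@dataclass
class EvaluationReport:
    """Everything the model-comparison table needs for one model."""

    model: str
    mspe_by_visit: pd.DataFrame
    overall_mspe: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    auc: Optional[float] = None
    auc_se: Optional[float] = None
    roc: Optional[pd.DataFrame] = None
    aic: Optional[float] = None
    bic: Optional[float] = None

    def summary_row(self) -> dict:
        return {
            "model": self.model,
            "aic": self.aic,
            "bic": self.bic,
            "mspe": self.overall_mspe,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "auc_se": self.auc_se,
        }


def evaluate_predictions(
    pred: PredictionSet,
    rule: EligibilityRule = EligibilityRule(),
    fit: Optional[FitResult] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the full evaluation report for one model's predictions.

    AIC/BIC are taken from ``fit`` (training-set likelihood) when given; the
    MSPE, classification and ROC metrics describe ``pred`` (typically the
    validation set).  The ROC block is skipped when only one truth class is
    present.
    """
    cls = classification_at_cutoff(pred, rule)
    truth = pred.data["y_obs"].to_numpy() < rule.cutoff(pred.gender)
    auc = auc_se = None
    roc_points = None
    if truth.any() and not truth.all():
        roc_points, auc, auc_se = roc_auc(pred, rule, n_boot=n_boot, seed=seed)
    aic = bic = None
    if fit is not None:
        aic, bic = information_criteria(fit)
    return EvaluationReport(
        model=pred.model,
        mspe_by_visit=mspe_by_visit(pred),
        overall_mspe=overall_mspe(pred),
        sensitivity=cls.sensitivity,
        specificity=cls.specificity,
        auc=auc,
        auc_se=auc_se,
        roc=roc_points,
        aic=aic,
        bic=bic,
    )
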