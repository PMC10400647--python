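"""Scoring, cross-validation, growth classification and variability analyses.

Q2 is the coefficient of determination computed on held-out predictions
(R2 with the same formula on fitted data). Repeated stratified k-fold
cross-validation aggregates validation-fold predictions so every point is
predicted once per repeat. The variability ceiling resamples each measured
point from Normal(mean, sd) to estimate the best Q2 experimental noise
allows, and the box-intersection fraction counts points whose measurement
and prediction error boxes touch the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CVResult",
    "q2_score",
    "repeated_stratified_cv",
    "classify_growth",
    "variability_ceiling_q2",
    "box_intersection_fraction",
]


def q2_score(y_true, y_pred) -> float:
    """1 - SS_res / SS_tot; requires >= 2 points and non-constant y_true."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two same-length vectors of >= 2 points")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true is constant; Q2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class CVResult:
    """Pooled predictions from repeated stratified k-fold cross-validation."""

    fold_assignments: np.ndarray  # repeats x n, validation fold per point
    predictions: np.ndarray       # repeats x n, out-of-fold prediction
    q2: float                     # pooled over all repeats
    q2_per_repeat: list
    pred_mean: np.ndarray = field(default=None)
    pred_sd: np.ndarray = field(default=None)


def repeated_stratified_cv(model_builder: Callable,
                           X, y,
                           k: int = 10,
                           repeats: int = 3,
                           seeds: Sequence[int] | None = None,
                           groups=None) -> CVResult:
    """Out-of-fold predictions with growth-rate-stratified folds.

    ``model_builder(seed)`` must return an unfitted estimator with
    fit/predict. Stratification bins ``y`` into ``k`` quantile bins (or
    uses ``groups`` when given); each repeat predicts every point exactly
    once from the fold that held it out.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValueError("need one seed per repeat")
    strata = None
    if groups is not None:
        strata = np.asarray(groups)
    elif n // k >= 2:
        # balanced rank bins on the growth rate, each bin >= k points
        n_bins = min(k, n // k)
        strata = np.empty(n, dtype=int)
        strata[np.argsort(y, kind="stable")] = np.arange(n) * n_bins // n
    assignments = np.zeros((repeats, n), dtype=int)
    preds = np.zeros((repeats, n))
    q2s = []
    for r, seed in enumerate(seeds):
        if strata is None:
            splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
            split = splitter.split(X)
        else:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=seed)
            split = splitter.split(X, strata)
        for fold, (train, val) in enumerate(split):
            est = model_builder(seed)
            est.fit(X[train], y[train])
            preds[r, val] = np.asarray(est.predict(X[val]), dtype=float).ravel()
            assignments[r, val] = fold
        q2s.append(q2_score(y, preds[r]))
    pooled = q2_score(np.tile(y, repeats), preds.ravel())
    return CVResult(assignments, preds, pooled, q2s,
                    pred_mean=preds.mean(axis=0), pred_sd=preds.std(axis=0))


def classify_growth(scores, measured, threshold_frac: float = 0.05) -> dict:
    """Growth / no-growth classification from continuous predictions.

    The measured rates are binarized at ``threshold_frac`` of their maximum
    (5% by default); predictions serve as continuous ROC scores, and
    accuracy is also reported by thresholding the predictions at the same
    absolute value. ``positive_rule="nonzero"`` behavior (any nonzero
    prediction is a growth call) is obtained by passing threshold 0 scores.
    """
    from sklearn.metrics import auc, roc_curve

    scores = np.asarray(scores, dtype=float).ravel()
    measured = np.asarray(measured, dtype=float).ravel()
    if scores.size == 0:
        raise ValueError("empty input")
    if np.allclose(measured, measured[0]):
        raise ValueError("measured vector is constant; cannot binarize")
    threshold = threshold_frac * measured.max()
    y_true = (measured > threshold).astype(int)
    fpr, tpr, roc_thr = roc_curve(y_true, scores)
    y_call = (scores > threshold).astype(int)
    return {
        "threshold": float(threshold),
        "labels": y_true,
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "auc": float(auc(fpr, tpr)),
        "accuracy": float(np.mean(y_call == y_true)),
    }


def variability_ceiling_q2(y_mean, y_sd, n_draws: int = 1000,
                           seed: int = 0, clip_negative: bool = False):
    """Best Q2 achievable at the observed replicate variability.

    Each draw resamples every point from Normal(mean, sd) and scores the
    resampled vector against the means; returns (mean, sd) of Q2 over
    draws. Negative resampled rates are kept unless ``clip_negative``.
    """
    y_mean = np.asarray(y_mean, dtype=float).ravel()
    y_sd = np.asarray(y_sd, dtype=float).ravel()
    if np.any(y_sd < 0):
        raise ValueError("standard deviations must be nonnegative")
    if np.allclose(y_mean, y_mean[0]):
        raise ValueError("constant means; Q2 undefined")
    rng = np.random.default_rng(seed)
    draws = rng.normal(y_mean, y_sd, size=(n_draws, y_mean.size))
    if clip_negative:
        draws = np.maximum(draws, 0.0)
    q2s = np.array([q2_score(y_mean, d) for d in draws])
    return float(q2s.mean()), float(q2s.std())


def box_intersection_fraction(pred_mean, pred_sd, meas_mean, meas_sd) -> float:
    """Fraction of points whose error boxes intersect the identity line.

    The box [meas-sd, meas+sd] x [pred-sd, pred+sd] meets y = x exactly
    when the two one-dimensional intervals overlap.
    """
    pred_mean = np.asarray(pred_mean, dtype=float).ravel()
    pred_sd = np.asarray(pred_sd, dtype=float).ravel()
    meas_mean = np.asarray(meas_mean, dtype=float).ravel()
    meas_sd = np.asarray(meas_sd, dtype=float).ravel()
    lo = np.maximum(pred_mean - pred_sd, meas_mean - meas_sd)
    hi = np.minimum(pred_mean + pred_sd, meas_mean + meas_sd)
    return float(np.mean(lo <= hi))
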