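"""Regression metrics, stratified diagnostics and permutation feature
importance for stability predictions.

The metric bundle follows the field's convention: Pearson, Spearman and
Kendall (tau-b) correlations, RMSE, MAE, and the mean signed error — the
average of (prediction - truth), i.e. a bias measure, reported here as
``mse_signed`` to avoid confusion with mean *squared* error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport",
    "compute_metrics",
    "stratified_report",
    "antisymmetry_diagnostics",
    "permutation_importance",
]


@dataclass(frozen=True)
class MetricReport:
    pearson_r: float
    spearman_s: float
    kendall_k: float
    rmse: float
    mae: float
    mse_signed: float
    n: int

    def as_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r, "spearman_s": self.spearman_s,
            "kendall_k": self.kendall_k, "rmse": self.rmse, "mae": self.mae,
            "mse_signed": self.mse_signed, "n": self.n,
        }


def compute_metrics(pred, true) -> MetricReport:
    """Correlations and error statistics between predictions and labels.

    Constant inputs make the correlations undefined; they are reported as
    NaN while the error terms are still computed.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction and truth vectors differ in length")
    if pred.size < 2:
        raise ValueError("need at least two points")
    err = pred - true
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    bias = float(np.mean(err))
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        r = s = k = float("nan")
    else:
        r = float(stats.pearsonr(pred, true)[0])
        s = float(stats.spearmanr(pred, true)[0])
        k = float(stats.kendalltau(pred, true)[0])  # tau-b
    return MetricReport(r, s, k, rmse, mae, bias, int(pred.size))


def stratified_report(pred, true, meta: dict) -> dict[str, MetricReport]:
    """Metric reports per stratum.

    ``meta`` may provide per-record arrays: ``direction`` (forward/reverse)
    and ``multiplicity`` (1/2/3). Strata are direction x sign of the true
    ddG (stabilising: >= 0, destabilising: < 0), plus double/triple when
    multiplicity is present. Strata with < 2 records are omitted.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    masks: dict[str, np.ndarray] = {}
    direction = meta.get("direction")
    if direction is not None:
        direction = np.asarray(direction)
        for d in ("forward", "reverse"):
            masks[d] = direction == d
    masks["stabilising"] = true >= 0.0
    masks["destabilising"] = true < 0.0
    if direction is not None:
        for d in ("forward", "reverse"):
            masks[f"{d}_stabilising"] = (direction == d) & (true >= 0.0)
            masks[f"{d}_destabilising"] = (direction == d) & (true < 0.0)
    multiplicity = meta.get("multiplicity")
    if multiplicity is not None:
        multiplicity = np.asarray(multiplicity)
        masks["double"] = multiplicity == 2
        masks["triple"] = multiplicity == 3
    out = {}
    for name, mask in masks.items():
        if mask.sum() >= 2:
            out[name] = compute_metrics(pred[mask], true[mask])
    return out


def antisymmetry_diagnostics(pred_fwd, pred_rev) -> dict:
    """Anti-symmetry health of paired forward/reverse predictions: their
    Pearson correlation (exactly -1 for a structurally anti-symmetric
    model) and the mean residual bias f + r."""
    pred_fwd = np.asarray(pred_fwd, dtype=float).ravel()
    pred_rev = np.asarray(pred_rev, dtype=float).ravel()
    if pred_fwd.shape != pred_rev.shape:
        raise ValueError("paired vectors differ in length")
    if np.ptp(pred_fwd) == 0 or np.ptp(pred_rev) == 0:
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(pred_fwd, pred_rev)[0])
    return {"pearson_fwd_rev": corr, "bias": float(np.mean(pred_fwd + pred_rev)),
            "n": int(pred_fwd.size)}


def permutation_importance(model, X, y, feature_idx, n_repeats: int = 10,
                           seed: int = 0, paired_idx=None) -> dict:
    """Pearson-correlation drop when one feature column is shuffled.

    A permutation preserves the column's mean and variance exactly. When
    ``paired_idx`` is given (the same feature in the reverse-orientation
    half of a siamese record), both columns are shuffled with the same
    permutation so each row stays internally consistent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not 0 <= feature_idx < X.shape[1]:
        raise KeyError(f"unknown feature index {feature_idx}")
    rng = np.random.default_rng(seed)
    baseline = float(stats.pearsonr(model.predict(X), y)[0])
    drops = []
    for _ in range(n_repeats):
        perm = rng.permutation(X.shape[0])
        Xp = X.copy()
        Xp[:, feature_idx] = X[perm, feature_idx]
        if paired_idx is not None:
            Xp[:, paired_idx] = X[perm, paired_idx]
        drops.append(float(stats.pearsonr(model.predict(Xp), y)[0]))
    return {
        "feature": int(feature_idx),
        "baseline_pearson": baseline,
        "permuted_pearson_mean": float(np.mean(drops)),
        "importance": baseline - float(np.mean(drops)),
        "n_repeats": int(n_repeats),
    }
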