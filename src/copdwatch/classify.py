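"""Logistic classification of stable vs prodromal periods, with repeated
10-fold cross-validation and mean-ROC reporting.

The classifier is plain (unregularised by default) logistic regression on
the six trend features: p(prodromal | x) = s(theta^T [1, x]) with the
sigmoid s(y) = 1/(1+e^-y), fitted by minimising the mean cross-entropy
cost — a convex problem with a unique optimum, solved here with a
quasi-Newton optimiser from a zero start so the fit is deterministic.

Evaluation repeats unstratified 10-fold cross-validation many times
(1000 in the full protocol): per repeat, out-of-fold probabilities are
pooled over the ten folds into a single ROC curve; curves are averaged
vertically (fixed false-positive-rate grid) and the 95% band is the
2.5/97.5 percentile envelope across repeats.  A correctly classified
prodromal period is a true positive; a correctly classified stable period
is a true negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "LogisticModel",
    "RocSummary",
    "sigmoid",
    "cost",
    "fit_logistic",
    "predict_proba",
    "roc_curve",
    "auc",
    "crossvalidate",
    "specificity_at_sensitivity",
    "compare_feature_sets",
    "VITAL_FEATURE_SETS",
]

logger = logging.getLogger(__name__)

#: probability clipping floor for the cross-entropy cost
PROB_EPS = 1e-12
#: fixed false-positive-rate grid for vertical ROC averaging
FPR_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)

#: the seven single/combined vital-sign feature subsets
VITAL_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "PR": ("pr_mean", "pr_grad"),
    "SpO2": ("spo2_mean", "spo2_grad"),
    "RR": ("rr_mean", "rr_grad"),
    "PR+SpO2": ("pr_mean", "pr_grad", "spo2_mean", "spo2_grad"),
    "RR+PR": ("rr_mean", "rr_grad", "pr_mean", "pr_grad"),
    "RR+SpO2": ("rr_mean", "rr_grad", "spo2_mean", "spo2_grad"),
    "RR+PR+SpO2": ("rr_mean", "rr_grad", "pr_mean", "pr_grad", "spo2_mean", "spo2_grad"),
}


class ClassifierError(ValueError):
    pass


def sigmoid(y):
    """Numerically stable logistic sigmoid 1/(1+e^-y)."""
    return expit(y)


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ClassifierError(f"labels must be in {{0, 1}}; got values {np.unique(y)}")
    return y.astype(float)


def cost(theta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> float:
    """Mean cross-entropy of the logistic model (clipped at saturation)."""
    y = _check_labels(y)
    p = np.clip(sigmoid(_augment(X) @ np.asarray(theta, dtype=float)), PROB_EPS, 1 - PROB_EPS)
    c = -float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    if ridge:
        c += 0.5 * ridge * float(np.sum(np.asarray(theta, dtype=float)[1:] ** 2)) / len(y)
    return c


def _cost_grad(theta, Xa, y, ridge):
    p = sigmoid(Xa @ theta)
    pc = np.clip(p, PROB_EPS, 1 - PROB_EPS)
    c = -np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc))
    g = Xa.T @ (p - y) / len(y)
    if ridge:
        c += 0.5 * ridge * np.sum(theta[1:] ** 2) / len(y)
        g = g + ridge * np.concatenate([[0.0], theta[1:]]) / len(y)
    return c, g


def _newton_polish(theta, Xa, y, ridge, max_steps: int = 50):
    """Refine the optimum to near machine precision with guarded Newton steps.

    The cost is convex, so at the interior optimum Newton converges
    quadratically; on (near-)separable data the Hessian degenerates and the
    loop backs off, keeping the quasi-Newton solution.
    """
    n = len(y)
    reg = np.zeros(Xa.shape[1])
    reg[1:] = ridge / n
    c_cur, g = _cost_grad(theta, Xa, y, ridge)
    for _ in range(max_steps):
        gnorm = float(np.max(np.abs(g)))
        if gnorm < 1e-12:
            break
        p = sigmoid(Xa @ theta)
        H = (Xa * (p * (1 - p))[:, None]).T @ Xa / n + np.diag(reg)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        cand = theta - delta
        if not np.all(np.isfinite(cand)):
            break
        c_new, g_new = _cost_grad(cand, Xa, y, ridge)
        if not np.isfinite(c_new) or c_new > c_cur + 1e-12:
            break
        theta, c_cur, g = cand, c_new, g_new
    return theta, float(np.max(np.abs(g)))


@dataclass
class LogisticModel:
    """Fitted logistic model with its training-fold standardisation.

    ``theta`` applies to z-scored features; ``theta_original`` is the
    equivalent parameter vector on the raw feature scale.
    """

    theta: np.ndarray
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    converged: bool = True
    grad_norm: float = 0.0

    @property
    def theta_original(self) -> np.ndarray:
        slopes = self.theta[1:] / self.scale
        intercept = self.theta[0] - float(np.sum(self.theta[1:] * self.center / self.scale))
        return np.concatenate([[intercept], slopes])


def fit_logistic(
    X,
    y,
    *,
    feature_names: Optional[Sequence[str]] = None,
    standardize: bool = True,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> LogisticModel:
    """Fit by minimising the convex cross-entropy cost from a zero start.

    Features are z-scored internally (training statistics only) for
    conditioning; predictions are invariant to this at the optimum.  The
    fit is deterministic and permutation-invariant up to optimiser
    tolerance.  Raises on single-class data; warns on non-convergence,
    reporting the final gradient norm.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns) if feature_names is None else tuple(feature_names)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_labels(y)
    if len(np.unique(y)) < 2:
        raise ClassifierError("training data contains a single class")
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))

    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        center = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xa = _augment((X - center) / scale)

    res = optimize.minimize(
        _cost_grad,
        np.zeros(Xa.shape[1]),
        args=(Xa, y, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    theta, gnorm = _newton_polish(res.x, Xa, y, ridge)
    res.x = theta
    if not res.success and gnorm > 1e-4:
        warnings.warn(
            f"logistic fit did not converge: {res.message} (grad norm {gnorm:.2e})",
            stacklevel=2,
        )
    return LogisticModel(
        theta=res.x,
        feature_names=tuple(feature_names),
        center=center,
        scale=scale,
        converged=bool(res.success),
        grad_norm=gnorm,
    )


def predict_proba(model: LogisticModel, X) -> np.ndarray:
    """Probability of the prodromal class for each row of X."""
    if isinstance(X, pd.DataFrame):
        missing = set(model.feature_names) - set(X.columns)
        if missing:
            raise ClassifierError(f"missing features: {sorted(missing)}")
        X = X[list(model.feature_names)].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise ClassifierError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    z = (X - model.center) / model.scale
    return sigmoid(_augment(z) @ model.theta)


def wald_standard_errors(model: LogisticModel, X, y) -> np.ndarray:
    """Wald standard errors on the raw feature scale (observed information)."""
    if isinstance(X, pd.DataFrame):
        X = X[list(model.feature_names)].to_numpy(dtype=float)
    Xa = _augment(X)
    p = np.clip(predict_proba(model, X), 1e-10, 1 - 1e-10)
    info = Xa.T @ (Xa * (p * (1 - p))[:, None])
    return np.sqrt(np.diag(np.linalg.inv(info)))


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve over all score thresholds (ties grouped, anchored at the
    corners); prodromal (label 1) is the positive class."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ClassifierError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr


def auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve."""
    return float(np.trapezoid(tpr, fpr))


def _interp_tpr(fpr: np.ndarray, tpr: np.ndarray, grid: np.ndarray) -> np.ndarray:
    out = np.interp(grid, fpr, tpr)
    out[0] = 0.0  # the (0, 0) anchor
    return out


@dataclass
class RocSummary:
    """Mean ROC over repeated cross-validation, with percentile bands."""

    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    tpr_lo: np.ndarray
    tpr_hi: np.ndarray
    aucs: np.ndarray  # one per repeat
    curves: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_ci(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.aucs, 2.5)),
            float(np.percentile(self.aucs, 97.5)),
        )

    @property
    def mean_curve_auc(self) -> float:
        return float(np.trapezoid(self.mean_tpr, self.fpr_grid))

    def to_dict(self) -> dict:
        lo, hi = self.auc_ci
        return {
            "fpr_grid": self.fpr_grid.tolist(),
            "mean_tpr": self.mean_tpr.tolist(),
            "tpr_lo": self.tpr_lo.tolist(),
            "tpr_hi": self.tpr_hi.tolist(),
            "aucs": self.aucs.tolist(),
            "mean_auc": self.mean_auc,
            "auc_ci": [lo, hi],
            "mean_curve_auc": self.mean_curve_auc,
        }


def _partition(rng: np.random.Generator, n: int, k: int, y: np.ndarray,
               groups: Optional[np.ndarray]) -> list[np.ndarray]:
    """Random unstratified k-fold partition; resampled (and logged) until
    every training split contains both classes."""
    for attempt in range(200):
        if groups is None:
            folds = np.array_split(rng.permutation(n), k)
        else:
            uniq = rng.permutation(np.unique(groups))
            gf = np.array_split(uniq, k)
            folds = [np.flatnonzero(np.isin(groups, g)) for g in gf]
        ok = True
        for f in folds:
            train_mask = np.ones(n, dtype=bool)
            train_mask[f] = False
            if len(np.unique(y[train_mask])) < 2 or f.size == 0:
                ok = False
                break
        if ok:
            if attempt:
                logger.info("resampled degenerate fold partition %d time(s)", attempt)
            return folds
    raise ClassifierError("could not draw a fold partition with both classes in every training split")


def crossvalidate(
    X,
    y,
    k: int = 10,
    reps: int = 1000,
    seed: Optional[int] = None,
    *,
    groups: Optional[Sequence] = None,
    ridge: float = 0.0,
    fpr_grid: np.ndarray = FPR_GRID,
    keep_curves: bool = False,
) -> RocSummary:
    """Repeated unstratified k-fold cross-validation with pooled-fold ROCs.

    Per repeat the data are randomly split into k folds; out-of-fold
    probabilities are pooled over the folds into one ROC for the whole
    dataset.  The mean ROC averages true-positive rates on a fixed
    false-positive-rate grid; the 95% band is the 2.5/97.5 percentile
    envelope; the headline AUC is the mean of per-repeat trapezoidal AUCs.
    Reproducible from ``seed``.  ``groups`` optionally keeps all periods of
    one patient in the same fold.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    y = np.asarray(y, dtype=int)
    if reps < 1 or k < 2:
        raise ClassifierError(f"need reps >= 1 and k >= 2, got reps={reps}, k={k}")
    n = len(y)
    groups_arr = None if groups is None else np.asarray(groups)
    rng = np.random.default_rng(seed)

    tprs = np.empty((reps, fpr_grid.size))
    aucs = np.empty(reps)
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for r in range(reps):
        folds = _partition(rng, n, k, y, groups_arr)
        scores = np.empty(n)
        for f in folds:
            train = np.ones(n, dtype=bool)
            train[f] = False
            model = fit_logistic(
                X[train], y[train], feature_names=feature_names, ridge=ridge
            )
            scores[f] = predict_proba(model, X[f])
        fpr, tpr = roc_curve(scores, y)
        aucs[r] = auc(fpr, tpr)
        tprs[r] = _interp_tpr(fpr, tpr, fpr_grid)
        if keep_curves:
            curves.append((fpr, tpr))

    return RocSummary(
        fpr_grid=fpr_grid.copy(),
        mean_tpr=tprs.mean(axis=0),
        tpr_lo=np.percentile(tprs, 2.5, axis=0),
        tpr_hi=np.percentile(tprs, 97.5, axis=0),
        aucs=aucs,
        curves=curves,
    )


def specificity_at_sensitivity(
    summary: RocSummary, sens_levels: Sequence[float] = (0.6, 0.7, 0.8)
) -> dict[float, Optional[float]]:
    """Specificity read off the mean ROC curve at requested sensitivities.

    For each level, the smallest grid FPR whose mean TPR reaches the level
    gives specificity = 1 - FPR; unattained levels map to None.
    """
    out: dict[float, Optional[float]] = {}
    for s in sens_levels:
        idx = np.flatnonzero(summary.mean_tpr >= s)
        out[s] = float(1.0 - summary.fpr_grid[idx[0]]) if idx.size else None
    return out


def compare_feature_sets(
    X: pd.DataFrame,
    y,
    subsets: Optional[Mapping[str, Sequence[str]]] = None,
    k: int = 10,
    reps: int = 100,
    seed: Optional[int] = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Cross-validate each vital-sign feature subset with a shared seed.

    All subsets see identical fold partitions (the partition stream
    depends only on the seed and n), so AUC differences reflect the
    features rather than fold luck.  Returns one row per subset with the
    mean AUC, its percentile CI and specificity at 60/80% sensitivity.
    """
    if subsets is None:
        subsets = VITAL_FEATURE_SETS
    seen: dict[str, tuple[str, ...]] = {}
    for name, cols in subsets.items():
        key = tuple(cols)
        if key in seen.values() or name in seen:
            warnings.warn(f"duplicate feature subset {name!r} ignored", stacklevel=2)
            continue
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ClassifierError(f"unknown feature columns in subset {name!r}: {missing}")
        seen[name] = key

    rows = []
    summaries: dict[str, RocSummary] = {}
    for name, cols in seen.items():
        summary = crossvalidate(X[list(cols)], y, k=k, reps=reps, seed=seed, **cv_kwargs)
        spec = specificity_at_sensitivity(summary, (0.6, 0.8))
        lo, hi = summary.auc_ci
        rows.append(
            {
                "subset": name,
                "features": ",".join(cols),
                "mean_auc": summary.mean_auc,
                "auc_lo": lo,
                "auc_hi": hi,
                "spec_at_60_sens": spec[0.6],
                "spec_at_80_sens": spec[0.8],
            }
        )
        summaries[name] = summary
    table = pd.DataFrame(rows)
    table.attrs["summaries"] = summaries
    return table
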