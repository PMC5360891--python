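"""Least-squares trend features over 7-day periods.

Self-monitoring sessions arrive at irregular times and with gaps, so
classical fixed-step time-series features do not apply.  Instead, for each
vital sign in each 7-day period a straight line y = m*x + c is fitted by
ordinary least squares, with session times normalised so the first session
of the period is at x = 0.  The (mean, gradient) pair per vital sign —
pulse rate, SpO2 and respiratory rate, six numbers in all — forms the
feature vector for the stable-vs-prodromal classifier.  The standard
deviation and y-intercept are available behind a flag but excluded by
default (they did not add discriminative value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .periods import Period

__all__ = [
    "TrendFit",
    "FeatureExtractionError",
    "fit_trend",
    "extract_features",
    "build_dataset",
    "FEATURE_COLUMNS",
    "EXTRA_FEATURE_COLUMNS",
    "VITAL_COLUMNS",
]

logger = logging.getLogger(__name__)

#: canonical column order of the feature matrix
FEATURE_COLUMNS = ["pr_mean", "pr_grad", "spo2_mean", "spo2_grad", "rr_mean", "rr_grad"]
EXTRA_FEATURE_COLUMNS = [
    "pr_sd", "pr_intercept", "spo2_sd", "spo2_intercept", "rr_sd", "rr_intercept",
]
#: vital-sign prefix -> DiarySession attribute
VITAL_COLUMNS = {"pr": "pulse_rate", "spo2": "spo2", "rr": "resp_rate"}


class FeatureExtractionError(ValueError):
    """Raised when a trend cannot be fitted (too few points, ties in time)."""


@dataclass(frozen=True)
class TrendFit:
    """OLS line fit over one vital sign in one period.

    ``m`` is the gradient in vital units/day, ``c`` the intercept at the
    (period-local) time origin, ``mean`` the unweighted session mean.
    """

    m: float
    c: float
    mean: float
    n: int
    sd: float = 0.0


def fit_trend(times: Sequence[float], values: Sequence[float]) -> TrendFit:
    """Least-squares straight line through (time, value) points.

    Times are shifted so the first session is at 0; (m, c) minimise the sum
    of squared residuals sum_i (y_i - (m*x_i + c))^2.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FeatureExtractionError("times and values must be 1-D of equal length")
    if x.size < 2:
        raise FeatureExtractionError(f"need at least 2 points for a line fit, got {x.size}")
    x = x - x[0]
    if np.ptp(x) == 0:
        raise FeatureExtractionError("all session times identical; gradient undefined")
    m, c = np.polyfit(x, y, 1)
    return TrendFit(m=float(m), c=float(c), mean=float(y.mean()), n=int(x.size),
                    sd=float(y.std(ddof=0)))


def extract_features(period: Period, include_extras: bool = False) -> Optional[dict]:
    """Per-vital (mean, gradient) features for one labeled period.

    Sessions missing one vital are excluded for that vital only, so the
    per-vital point counts may differ; any vital left with fewer than two
    points drops the whole period (returns None, with a logged reason).
    """
    if period.label not in ("stable", "prodromal"):
        raise FeatureExtractionError(f"unknown period label {period.label!r}")
    row: dict = {
        "patient_id": period.patient_id,
        "start_t": period.start_t,
        "label": 1 if period.label == "prodromal" else 0,
    }
    for prefix, attr in VITAL_COLUMNS.items():
        pts = [(s.t, getattr(s, attr)) for s in period.sessions if getattr(s, attr) is not None]
        pts = [(t, v) for t, v in pts if np.isfinite(v)]
        if len(pts) < 2:
            logger.info(
                "dropping %s period at t=%.2f for %s: vital %r has %d value(s)",
                period.label, period.start_t, period.patient_id, prefix, len(pts),
            )
            return None
        fit = fit_trend([t for t, _ in pts], [v for _, v in pts])
        row[f"{prefix}_mean"] = fit.mean
        row[f"{prefix}_grad"] = fit.m
        if include_extras:
            row[f"{prefix}_sd"] = fit.sd
            row[f"{prefix}_intercept"] = fit.c
    return row


def build_dataset(
    periods: Sequence[Period], include_extras: bool = False
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Feature matrix, labels and metadata for a list of periods.

    Rows are sorted deterministically by (patient_id, start_t); duplicate
    (patient_id, start_t) keys are rejected.  Returns (X, y, meta) where X
    has the canonical feature columns, y is 0 (stable) / 1 (prodromal) and
    meta carries patient_id/start_t/label per row.  Warns if only one
    class is present (cross-validation would fail downstream).
    """
    if not periods:
        raise FeatureExtractionError("no periods supplied")
    rows = []
    for p in periods:
        row = extract_features(p, include_extras=include_extras)
        if row is not None:
            rows.append(row)
    if not rows:
        raise FeatureExtractionError("no period yielded a complete feature vector")
    df = pd.DataFrame(rows).sort_values(["patient_id", "start_t"], kind="mergesort")
    dup = df.duplicated(subset=["patient_id", "start_t"])
    if dup.any():
        raise FeatureExtractionError(
            f"duplicate periods for keys: {df.loc[dup, ['patient_id', 'start_t']].values.tolist()}"
        )
    df = df.reset_index(drop=True)
    y = df["label"].to_numpy(dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn(
            f"single-class dataset (stable={n_neg}, prodromal={n_pos}); "
            "classifier training will fail",
            stacklevel=2,
        )
    logger.info("feature dataset: %d stable, %d prodromal periods", n_neg, n_pos)
    cols = FEATURE_COLUMNS + (EXTRA_FEATURE_COLUMNS if include_extras else [])
    return df[cols].copy(), y, df[["patient_id", "start_t", "label"]].copy()
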