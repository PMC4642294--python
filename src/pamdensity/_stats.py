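"""Shared statistical helpers: ratio-estimator variance and reporting rounding."""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def cochran_ratio(values, weights):
    """Weighted ratio estimate with Cochran's finite-sample variance.

    Estimates ``R = sum(w_i * y_i) / sum(w_i)`` where each ``y_i`` is a
    per-unit rate (e.g. a weekly click rate) and ``w_i`` the unit's size
    (e.g. seconds of effort in the week).  The variance of the ratio is the
    classical survey-sampling ratio-estimator form

        var(R) = n / ((n - 1) * W^2) * sum(w_i^2 * (y_i - R)^2),  W = sum(w_i)

    Returns ``(ratio, cv)``.  A single unit carries no variance information;
    the CV is reported as 0 with a warning.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape or y.ndim != 1:
        raise ValueError("values and weights must be 1-d arrays of equal length")
    if y.size == 0:
        raise ValueError("need at least one value")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    W = w.sum()
    ratio = float(np.sum(w * y) / W)
    n = y.size
    if n == 1:
        warnings.warn("single sampling unit: CV of the weighted mean reported as 0",
                      stacklevel=2)
        return ratio, 0.0
    var = n / ((n - 1) * W**2) * float(np.sum(w**2 * (y - ratio) ** 2))
    cv = float(np.sqrt(var) / ratio) if ratio != 0 else float("inf")
    return ratio, cv


def mean_se_cv(values):
    """Mean, standard error and CV (= SE/mean) of an unweighted sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    mean = float(x.mean())
    if x.size == 1:
        return mean, 0.0, 0.0
    se = float(x.std(ddof=1) / np.sqrt(x.size))
    cv = se / mean if mean != 0 else float("inf")
    return mean, se, cv


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (as in the reported density tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
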