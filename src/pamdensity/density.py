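"""Weekly density estimation with delta-method variance and lognormal CIs.

Two point-transect cue-count estimators convert weekly detection counts
``n_kt`` over effort ``T_kt`` at site ``k`` into animal density (animals per
1000 km^2):

* click counting:  ``D = (n/T) (1 - c) / (r P_k pi w^2)``
* group counting:  ``D = (n/T) (1 - c) S / (P_k P_v pi w^2)``

where ``c`` is the false-detection proportion, ``r`` the click production
rate (clicks/s), ``S`` the mean group size, ``P_v`` the group vocal-activity
probability per 5-min bin, ``P_k`` the detection probability within the
monitoring radius ``w`` (km).  CVs of the components combine by the delta
method (root of the summed squared CVs) and confidence intervals assume the
density is lognormal, precluding negative bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._stats import cochran_ratio, round_half_away
from .clicklog import FalseDetectionRate, week_start_of
from .multipliers import ClickRateEstimate, GroupSizeEstimate, GroupVocalProbability

__all__ = [
    "DetectionSummary",
    "MultiplierSet",
    "DensityEstimate",
    "delta_cv",
    "lognormal_ci",
    "click_density",
    "group_density",
    "weekly_series",
    "pooled_density",
]


@dataclass(frozen=True)
class DetectionSummary:
    """Disc-averaged detection probability within the monitoring radius."""
    p_k: float
    cv: float
    w_km: float

    def __post_init__(self):
        if not 0.0 <= self.p_k <= 1.0:
            raise ValueError("p_k must lie in [0, 1]")
        if self.w_km <= 0:
            raise ValueError("monitoring radius must be positive")


@dataclass
class MultiplierSet:
    """All multipliers one estimator mode needs, each with a CV.

    Click mode requires ``click_rate``; group mode requires ``group_size``
    and ``group_vocal``.  ``detection`` must come from the matching
    simulation mode.
    """
    false_rate: FalseDetectionRate
    detection: DetectionSummary
    click_rate: ClickRateEstimate | None = None
    group_size: GroupSizeEstimate | None = None
    group_vocal: GroupVocalProbability | None = None

    def require(self, method: str):
        missing = []
        if method == "click":
            if self.click_rate is None:
                missing.append("click_rate (r)")
        elif method == "group":
            if self.group_size is None:
                missing.append("group_size (S)")
            if self.group_vocal is None:
                missing.append("group_vocal (P_v)")
        else:
            raise ValueError(f"unknown method {method!r}; use 'click' or 'group'")
        if missing:
            raise ValueError(f"method {method!r} is missing multipliers: "
                             + ", ".join(missing))


@dataclass(frozen=True)
class DensityEstimate:
    """Density in animals per 1000 km^2 with delta-method uncertainty."""
    density: float
    cv: float
    sd: float
    ci_low: float
    ci_high: float
    method: str
    week_start: float | None = None
    site: str | None = None
    species: str | None = None

    def rounded(self, ndigits: int = 2) -> float:
        return round_half_away(self.density, ndigits)


def delta_cv(components) -> float:
    """Delta-method CV: the root of the sum of the squared component CVs."""
    c = np.asarray(list(components), dtype=float)
    if np.any(c < 0):
        raise ValueError("CVs must be non-negative")
    return float(np.sqrt(np.sum(c**2)))


def lognormal_ci(density: float, cv: float, level: float = 0.95):
    """Lognormal confidence bounds ``(D / C, D * C)``.

    ``C = exp(z * sqrt(ln(1 + cv^2)))`` with ``z`` the two-sided normal
    quantile for ``level``; bounds are multiplicative, so they are
    log-symmetric about the estimate and never negative.
    """
    if density < 0 or cv < 0:
        raise ValueError("density and cv must be non-negative")
    if density == 0:
        return 0.0, 0.0
    z = float(norm.ppf(0.5 + level / 2))
    c = float(np.exp(z * np.sqrt(np.log1p(cv**2))))
    return density / c, density * c


def _assemble(density_per_km2: float, cvs, method: str, level: float,
              **ids) -> DensityEstimate:
    d = density_per_km2 * 1000.0  # report per 1000 km^2
    cv = delta_cv(cvs)
    lo, hi = lognormal_ci(d, cv, level)
    return DensityEstimate(density=d, cv=cv, sd=d * cv, ci_low=lo, ci_high=hi,
                           method=method, **ids)


def click_density(n_clicks: float, t_seconds: float, m: MultiplierSet,
                  count_cv: float = 0.0, level: float = 0.95,
                  **ids) -> DensityEstimate:
    """Cue-count density from a weekly click count over effort seconds."""
    m.require("click")
    if t_seconds <= 0:
        raise ValueError("effort must be positive")
    r, pk, w = m.click_rate.rate, m.detection.p_k, m.detection.w_km
    if r <= 0 or pk <= 0:
        raise ValueError("zero click rate or detection probability: "
                         "configuration fault")
    d = (n_clicks / t_seconds) * (1.0 - m.false_rate.proportion) / (r * pk * np.pi * w**2)
    cvs = (count_cv, m.false_rate.cv, m.click_rate.cv, m.detection.cv)
    return _assemble(d, cvs, "click", level, **ids)


def group_density(n_bins_detected: float, t_bins: float, m: MultiplierSet,
                  count_cv: float = 0.0, level: float = 0.95,
                  **ids) -> DensityEstimate:
    """Group-count density from weekly detecting-bin counts over effort bins."""
    m.require("group")
    if t_bins <= 0:
        raise ValueError("effort must be positive")
    pk, w = m.detection.p_k, m.detection.w_km
    pv, s = m.group_vocal.p_v, m.group_size.mean
    if pk <= 0 or pv <= 0:
        raise ValueError("zero detection or vocal-activity probability: "
                         "configuration fault")
    d = (n_bins_detected / t_bins) * (1.0 - m.false_rate.proportion) * s / (pk * pv * np.pi * w**2)
    cvs = (count_cv, m.false_rate.cv, m.group_size.cv, m.group_vocal.cv,
           m.detection.cv)
    return _assemble(d, cvs, "group", level, **ids)


def _bootstrap_count_cv(bin_values: np.ndarray, rng, n_boot: int) -> float:
    """CV of a weekly count by nonparametric bootstrap over its 5-min bins."""
    total = bin_values.sum()
    if total == 0 or bin_values.size < 2:
        return 0.0
    n = bin_values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    sums = bin_values[idx].sum(axis=1)
    return float(sums.std(ddof=1) / total)


def weekly_series(weekly_counts: pd.DataFrame, m: MultiplierSet, method: str,
                  bins: pd.DataFrame | None = None, n_boot: int = 500,
                  seed=None, level: float = 0.95) -> pd.DataFrame:
    """Weekly density estimates for one site/species.

    ``weekly_counts`` is the output of :func:`pamdensity.clicklog.weekly_aggregate`.
    When the 5-min bin series is supplied, the weekly count CV is estimated
    by a seeded nonparametric bootstrap over the week's bins (resampling bin
    click counts for the click method, detection flags for the group
    method); without it the count CV is taken as 0 with a warning.
    """
    m.require(method)
    rng = np.random.default_rng(seed)
    if bins is None and len(weekly_counts):
        warnings.warn("no bin series supplied: weekly count CVs set to 0",
                      stacklevel=2)
    bin_week = (week_start_of(bins["bin_start"].to_numpy())
                if bins is not None and len(bins) else None)
    rows = []
    for rec in weekly_counts.itertuples(index=False):
        count_cv = 0.0
        if bin_week is not None:
            sel = bin_week == rec.week_start
            values = (bins.loc[sel, "n_clicks"].to_numpy(dtype=float)
                      if method == "click"
                      else bins.loc[sel, "detected"].to_numpy(dtype=float))
            if values.size:
                count_cv = _bootstrap_count_cv(values, rng, n_boot)
        if method == "click":
            est = click_density(rec.n_clicks, rec.t_seconds, m, count_cv, level,
                                week_start=rec.week_start, site=rec.site,
                                species=rec.species)
        else:
            if rec.t_bins == 0:
                continue
            est = group_density(rec.n_bins_detected, rec.t_bins, m, count_cv,
                                level, week_start=rec.week_start, site=rec.site,
                                species=rec.species)
        rows.append(est)
    return pd.DataFrame([{
        "week_start": e.week_start, "site": e.site, "species": e.species,
        "method": e.method, "density_per_1000km2": e.density, "cv": e.cv,
        "sd": e.sd, "ci_low": e.ci_low, "ci_high": e.ci_high,
    } for e in rows])


def pooled_density(weekly_counts: pd.DataFrame, m: MultiplierSet, method: str,
                   level: float = 0.95, site=None, species=None) -> DensityEstimate:
    """Average density over the whole record (total counts / total effort).

    The count-level CV is the Cochran ratio-estimator CV of the weekly rates
    weighted by weekly effort, capturing the empirical week-to-week
    variation of the encounter rate.
    """
    m.require(method)
    if not len(weekly_counts):
        raise ValueError("no weekly counts")
    if method == "click":
        n = weekly_counts["n_clicks"].to_numpy(dtype=float)
        t = weekly_counts["t_seconds"].to_numpy(dtype=float)
    else:
        n = weekly_counts["n_bins_detected"].to_numpy(dtype=float)
        t = weekly_counts["t_bins"].to_numpy(dtype=float)
    keep = t > 0
    n, t = n[keep], t[keep]
    rate, count_cv = cochran_ratio(n / t, t)
    if method == "click":
        return click_density(rate, 1.0, m, count_cv, level, site=site,
                             species=species)
    return group_density(rate, 1.0, m, count_cv, level, site=site,
                         species=species)
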