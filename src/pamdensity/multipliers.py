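"""Vocal-behaviour multipliers for cue-count and group-count estimators.

Converting detection counts into animal density requires behavioural
multipliers estimated from ancillary data:

* ``r`` -- mean click production rate (clicks/s), the product of the
  proportion of the dive cycle spent clicking (from acoustic tag records)
  and the click rate while clicking (the reciprocal of the modal
  inter-click interval measured on the monitoring data itself);
* ``P_r`` -- probability that an individual is vocally active within a
  5-min bin, from the same tag records split cyclically into 300-s bins;
* ``o`` -- vocal-bout overlap between animals of a group, from acoustic
  tracking of multiple animals;
* ``P_v`` -- probability a group is vocally active in a 5-min bin,
  ``P_v = P_r (2 - o)`` for a nominal two-animal group, capped at unity;
* ``S`` -- mean group size from overlapping click-train counts.

Each estimate carries a CV for delta-method propagation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._stats import cochran_ratio, mean_se_cv

__all__ = [
    "DiveCycle",
    "TagRecord",
    "IciEstimate",
    "VocalActivity",
    "SynchronyEstimate",
    "GroupVocalProbability",
    "ClickRateEstimate",
    "GroupSizeEstimate",
    "ici_weekly_mode",
    "pooled_click_spacing_rate",
    "proportion_clicking_seconds",
    "proportion_clicking_bins",
    "click_rate",
    "synchrony_overlap",
    "group_vocal_probability",
    "group_size_stats",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiveCycle:
    """One deep dive plus its associated shallow dives.

    ``click_positive_seconds`` holds the integer second indices (within the
    cycle) that contained at least one click from the tagged animal.
    """
    duration: int
    click_positive_seconds: np.ndarray

    def __post_init__(self):
        sec = np.unique(np.asarray(self.click_positive_seconds, dtype=int))
        if sec.size and (sec.min() < 0 or sec.max() >= self.duration):
            raise ValueError("click-positive seconds must lie in [0, duration)")
        object.__setattr__(self, "click_positive_seconds", sec)

    @property
    def proportion(self) -> float:
        return self.click_positive_seconds.size / self.duration


@dataclass(frozen=True)
class TagRecord:
    cycles: tuple[DiveCycle, ...]

    def __init__(self, cycles):
        object.__setattr__(self, "cycles", tuple(cycles))


@dataclass(frozen=True)
class IciEstimate:
    weekly_modes: tuple[tuple[float, float], ...]  # (mode s, weight s)
    pooled_rate: float                              # clicks/s
    cv: float


@dataclass(frozen=True)
class VocalActivity:
    proportion_seconds: float
    cv_seconds: float
    proportion_bins: float
    cv_bins: float


@dataclass(frozen=True)
class SynchronyEstimate:
    overlap: float
    cv: float
    per_encounter: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")


@dataclass(frozen=True)
class GroupVocalProbability:
    p_v: float
    cv: float


@dataclass(frozen=True)
class ClickRateEstimate:
    rate: float
    cv: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("click rate must be positive")


@dataclass(frozen=True)
class GroupSizeEstimate:
    mean: float
    cv: float
    histogram: np.ndarray

    def __post_init__(self):
        if self.mean < 1:
            raise ValueError("mean group size must be at least 1")


# ---------------------------------------------------------------------------
# inter-click interval
# ---------------------------------------------------------------------------

def ici_weekly_mode(ici_values, min_count: int = 100, upper: float = 1.0,
                    grid_step: float = 0.001) -> float | None:
    """Modal inter-click interval for one week of detections.

    Interval measurements between detected clicks mix true single-animal
    ICIs with multi-animal interleavings and missed-click multiples, so the
    mode of the distribution is the robust location summary.  Values are
    restricted to (0, ``upper``) seconds; weeks with fewer than ``min_count``
    eligible values yield ``None``.  The density is a Gaussian kernel
    estimate (Silverman's bandwidth) evaluated on a 1-ms grid; ties break
    toward the smallest interval.
    """
    v = np.asarray(ici_values, dtype=float)
    v = v[(v > 0) & (v < upper)]
    if v.size < min_count:
        return None
    if np.ptp(v) == 0.0:
        return float(v[0])
    kde = gaussian_kde(v, bw_method="silverman")
    grid = np.arange(grid_step / 2, upper, grid_step)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def pooled_click_spacing_rate(modes, weights) -> IciEstimate:
    """Weight weekly modal ICIs into a pooled click rate (clicks/s).

    Weekly modes are converted to rates by reciprocal and combined as a
    weighted mean using the weekly bin length (seconds of effort) as the
    weight; the CV comes from Cochran's ratio-estimator variance.
    """
    modes = np.asarray(modes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if modes.size == 0:
        raise ValueError("need at least one weekly mode")
    if np.any(modes <= 0):
        raise ValueError("modal ICIs must be positive")
    rate, cv = cochran_ratio(1.0 / modes, weights)
    return IciEstimate(weekly_modes=tuple(zip(modes.tolist(), weights.tolist())),
                       pooled_rate=rate, cv=cv)


# ---------------------------------------------------------------------------
# proportion of time clicking
# ---------------------------------------------------------------------------

def _usable_cycles(tag: TagRecord, exclude_first: bool):
    cycles = tag.cycles[1:] if exclude_first else tag.cycles
    if not cycles:
        raise ValueError("no usable dive cycles after exclusion")
    return cycles


def proportion_clicking_seconds(tag: TagRecord, exclude_first: bool = True):
    """Dive-cycle-length-weighted mean proportion of click-positive seconds.

    The first cycle of a record is excluded by default (tagging effect).
    Returns ``(proportion, cv)`` with the CV from Cochran's ratio variance
    across cycles.
    """
    cycles = _usable_cycles(tag, exclude_first)
    props = np.array([c.proportion for c in cycles])
    durs = np.array([c.duration for c in cycles], dtype=float)
    return cochran_ratio(props, durs)


def proportion_clicking_bins(tag: TagRecord, bin_length: int = 300,
                             n_randomizations: int = 100,
                             seed=None, exclude_first: bool = True):
    """Proportion of 5-min bins of a dive cycle containing clicking.

    Each cycle is made cyclical, a uniform random integer start second is
    drawn, the cycle is cut into ``bin_length``-second bins from that start
    (the final incomplete bin is dropped) and the fraction of bins holding
    at least one click-positive second is recorded.  The per-cycle fraction
    is averaged over ``n_randomizations`` random starts, then combined
    across cycles as a cycle-length-weighted ratio with a Cochran CV.
    Cycles shorter than one bin are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    cycles = _usable_cycles(tag, exclude_first)
    props, durs = [], []
    skipped = 0
    for c in cycles:
        nbins = c.duration // bin_length
        if nbins == 0:
            skipped += 1
            continue
        starts = rng.integers(0, c.duration, size=n_randomizations)
        pos = c.click_positive_seconds
        if pos.size == 0:
            props.append(0.0)
            durs.append(float(c.duration))
            continue
        # bin index of each click-positive second for every random start
        idx = ((pos[None, :] - starts[:, None]) % c.duration) // bin_length
        fractions = np.array([
            np.unique(row[row < nbins]).size / nbins for row in idx
        ])
        props.append(float(fractions.mean()))
        durs.append(float(c.duration))
    if skipped:
        warnings.warn(f"skipped {skipped} dive cycles shorter than one bin",
                      stacklevel=2)
    if not props:
        raise ValueError("no dive cycle is at least one bin long")
    return cochran_ratio(np.array(props), np.array(durs))


def vocal_activity(tag: TagRecord, bin_length: int = 300,
                   n_randomizations: int = 100, seed=None,
                   exclude_first: bool = True) -> VocalActivity:
    """Bundle the per-second and per-bin clicking proportions of one record."""
    ps, cvs = proportion_clicking_seconds(tag, exclude_first)
    pb, cvb = proportion_clicking_bins(tag, bin_length, n_randomizations,
                                       seed, exclude_first)
    return VocalActivity(ps, cvs, pb, cvb)


def click_rate(proportion_seconds: float, cv_seconds: float,
               ici_rate: IciEstimate | ClickRateEstimate) -> ClickRateEstimate:
    """Cue production rate ``r``: clicking proportion times clicks-per-second.

    The CV combines the two independent components as a root sum of squares.
    """
    rate = getattr(ici_rate, "pooled_rate", None)
    if rate is None:
        rate = ici_rate.rate
    if proportion_seconds <= 0 or rate <= 0:
        raise ValueError("both the clicking proportion and the ICI rate must be positive")
    return ClickRateEstimate(rate=proportion_seconds * rate,
                             cv=float(np.hypot(cv_seconds, ici_rate.cv)))


# ---------------------------------------------------------------------------
# synchrony and group vocal activity
# ---------------------------------------------------------------------------

def _interval_union_length(iv: np.ndarray) -> float:
    if iv.size == 0:
        return 0.0
    iv = iv[np.argsort(iv[:, 0])]
    total, cur_lo, cur_hi = 0.0, iv[0, 0], iv[0, 1]
    for lo, hi in iv[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return float(total + (cur_hi - cur_lo))


def _multi_cover_length(intervals: list[np.ndarray], k: int = 2) -> float:
    """Length of time covered by at least ``k`` of the animals' bout sets."""
    events = []
    for iv in intervals:
        for lo, hi in iv:
            events.append((lo, 1))
            events.append((hi, -1))
    events.sort()
    total, active, prev = 0.0, 0, None
    for t, delta in events:
        if prev is not None and active >= k:
            total += t - prev
        active += delta
        prev = t
    return total


def synchrony_overlap(bouts: pd.DataFrame) -> SynchronyEstimate:
    """Vocal-bout overlap ``o`` from multi-animal tracking encounters.

    ``bouts`` has columns ``encounter_id, animal_id, start_s, end_s``.  For
    each encounter with two or more tracked animals, ``o`` is the period
    when at least two animals vocalise divided by the mean vocalisation
    period per animal; encounters are the sample units for the mean and CV.
    """
    required = {"encounter_id", "animal_id", "start_s", "end_s"}
    if not required.issubset(bouts.columns):
        raise ValueError(f"bout table must have columns {sorted(required)}")
    per_enc = []
    for _, enc in bouts.groupby("encounter_id"):
        animals = [g[["start_s", "end_s"]].to_numpy(dtype=float)
                   for _, g in enc.groupby("animal_id")]
        if len(animals) < 2:
            continue
        indiv = np.mean([_interval_union_length(iv) for iv in animals])
        if indiv == 0:
            continue
        per_enc.append(_multi_cover_length(animals, k=2) / indiv)
    if not per_enc:
        raise ValueError("synchrony requires at least one encounter with >= 2 animals")
    mean, _, cv = mean_se_cv(per_enc)
    return SynchronyEstimate(overlap=float(np.clip(mean, 0.0, 1.0)), cv=cv,
                             per_encounter=tuple(per_enc))


def group_vocal_probability(p_r: float, cv_r: float, o: float, cv_o: float,
                            group_size: int = 2) -> GroupVocalProbability:
    """Probability ``P_v`` that a two-animal group is vocal in a 5-min bin.

    With individual bin-activity probability ``P_r`` and bout overlap ``o``,
    ``P_v = P_r (2 - o)``: full asynchrony (o = 0) doubles the individual
    probability, full synchrony (o = 1) leaves it unchanged.  ``P_v`` is
    capped at unity.  The CV is the root sum of squares of the component
    CVs.  Only the nominal two-animal relation is supported.
    """
    if group_size != 2:
        raise ValueError("the vocal-synchrony relation is defined for a "
                         "nominal group size of 2")
    if not (0.0 <= p_r <= 1.0 and 0.0 <= o <= 1.0):
        raise ValueError("p_r and o must lie in [0, 1]")
    return GroupVocalProbability(p_v=min(1.0, p_r * (2.0 - o)),
                                 cv=float(np.hypot(cv_r, cv_o)))


def group_size_stats(samples) -> GroupSizeEstimate:
    """Mean group size, CV (= SE/mean) and histogram from encounter counts."""
    s = np.asarray(samples, dtype=int)
    if s.size == 0:
        raise ValueError("need at least one group-size sample")
    if np.any(s < 1):
        raise ValueError("group sizes must be at least 1")
    mean, _, cv = mean_se_cv(s)
    return GroupSizeEstimate(mean=mean, cv=cv, histogram=np.bincount(s)[1:])
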