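"""Click-detection log processing: encounters, 5-min bins, weekly counts.

A detection log is a time-ordered stream of individual echolocation-click
detections for one species at one site.  Three reductions are applied before
density estimation:

* encounters -- contiguous clicking periods (> 75 s of clicking, gaps of at
  most one hour), used for data screening and reporting;
* 5-min bins -- fixed UTC-aligned 300-s bins wholly inside recording effort;
  a bin "detects" a group when it holds at least 5 clicks;
* weekly counts -- Sunday-to-Saturday weeks holding the total click count,
  the number of detecting bins and the effort, the inputs ``n_kt`` and
  ``T_kt`` of both density estimators.

All times are seconds UTC (Unix epoch); weeks break at Sunday 00:00 UTC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Encounter",
    "FalseDetectionRate",
    "assemble_encounters",
    "bin_clicks",
    "weekly_aggregate",
    "estimate_false_rate",
    "SECONDS_PER_WEEK",
    "EPOCH_SUNDAY",
]

SECONDS_PER_WEEK = 7 * 86400
#: 1970-01-04 00:00 UTC, the first Sunday of the Unix epoch; weekly bins are
#: aligned to this anchor.
EPOCH_SUNDAY = 3 * 86400


@dataclass(frozen=True)
class Encounter:
    start: float
    end: float
    n_clicks: int
    species: str | None = None
    site: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class FalseDetectionRate:
    """Proportion of detections that are false, with its CV (``c_k``)."""
    proportion: float
    cv: float

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must lie in [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def assemble_encounters(click_times, max_gap: float = 3600.0,
                        min_duration: float = 75.0,
                        species: str | None = None,
                        site: str | None = None) -> list[Encounter]:
    """Split a sorted click-time stream into encounters.

    Successive clicks separated by more than ``max_gap`` seconds start a new
    encounter; encounters whose first-to-last-click span is not greater than
    ``min_duration`` are discarded.
    """
    t = np.asarray(click_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("click times must be sorted ascending")
    breaks = np.nonzero(np.diff(t) > max_gap)[0] + 1
    out = []
    for seg in np.split(t, breaks):
        if seg.size >= 2 and seg[-1] - seg[0] > min_duration:
            out.append(Encounter(start=float(seg[0]), end=float(seg[-1]),
                                 n_clicks=int(seg.size), species=species, site=site))
    return out


def _normalize_effort(effort) -> np.ndarray:
    """Effort as an (n, 2) float array of non-overlapping [start, end) periods."""
    if isinstance(effort, pd.DataFrame):
        arr = effort[["start", "end"]].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(effort, dtype=float))
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.shape[1] != 2:
        raise ValueError("effort must be (start, end) pairs")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("effort periods must have start < end")
    arr = arr[np.argsort(arr[:, 0])]
    if np.any(arr[1:, 0] < arr[:-1, 1]):
        raise ValueError("effort periods must not overlap")
    return arr


def bin_clicks(click_times, effort, bin_length: float = 300.0,
               min_clicks: int = 5) -> pd.DataFrame:
    """Count clicks in fixed 300-s bins lying wholly inside effort periods.

    The bin grid is anchored to absolute UTC multiples of ``bin_length``
    (the effort start rounded down to the grid); only bins fully covered by
    an effort period are emitted.  ``detected`` marks bins holding at least
    ``min_clicks`` clicks.  Clicks falling outside every emitted bin are
    excluded with a warning.
    """
    t = np.sort(np.asarray(click_times, dtype=float))
    periods = _normalize_effort(effort)
    starts, counts = [], []
    used = 0
    for p0, p1 in periods:
        b0 = np.ceil(p0 / bin_length) * bin_length
        nbin = int(np.floor((p1 - b0) / bin_length))
        if nbin <= 0:
            continue
        edges = b0 + bin_length * np.arange(nbin + 1)
        c, _ = np.histogram(t, bins=edges)
        # np.histogram closes the last bin on the right; drop a click sitting
        # exactly on the final edge to keep bins half-open
        if np.any(t == edges[-1]):
            c[-1] -= int(np.sum(t == edges[-1]))
        starts.append(edges[:-1])
        counts.append(c)
        used += int(c.sum())
    if starts:
        bin_start = np.concatenate(starts)
        n = np.concatenate(counts).astype(int)
    else:
        bin_start = np.empty(0)
        n = np.empty(0, dtype=int)
    excluded = t.size - used
    if excluded > 0:
        warnings.warn(f"{excluded} clicks fell outside whole effort bins and were "
                      "excluded from the bin series", stacklevel=2)
    return pd.DataFrame({"bin_start": bin_start, "n_clicks": n,
                         "detected": n >= min_clicks})


def week_start_of(t) -> np.ndarray:
    """Start (seconds UTC) of the Sunday-aligned week containing each time."""
    t = np.asarray(t, dtype=float)
    return EPOCH_SUNDAY + np.floor((t - EPOCH_SUNDAY) / SECONDS_PER_WEEK) * SECONDS_PER_WEEK


def weekly_aggregate(bins: pd.DataFrame, click_times, effort,
                     edge_min_days: float = 2.0,
                     site: str | None = None,
                     species: str | None = None) -> pd.DataFrame:
    """Aggregate bins, clicks and effort into Sunday-to-Saturday weeks.

    Clicks are counted over all effort (the >= 5-click bin filter applies
    only to the group stream, so ``n_clicks`` may include clicks from
    sub-threshold bins).  Edge weeks of the record with less than
    ``edge_min_days`` days of cumulative effort are merged into the adjacent
    week.  Weeks without effort yield no row; every effort second belongs to
    exactly one output row.
    """
    periods = _normalize_effort(effort)
    t = np.asarray(click_times, dtype=float)

    # effort seconds per week: intersect each period with the week grid
    effort_per_week: dict[float, float] = {}
    for p0, p1 in periods:
        w = week_start_of(p0)
        while w < p1:
            lo, hi = max(p0, w), min(p1, w + SECONDS_PER_WEEK)
            if hi > lo:
                effort_per_week[w] = effort_per_week.get(w, 0.0) + (hi - lo)
            w += SECONDS_PER_WEEK

    if not effort_per_week:
        return pd.DataFrame(columns=["week_start", "site", "species", "n_clicks",
                                     "n_bins_detected", "t_seconds", "t_bins"])

    weeks = np.array(sorted(effort_per_week))
    click_w = week_start_of(t) if t.size else np.empty(0)
    bin_w = week_start_of(bins["bin_start"].to_numpy()) if len(bins) else np.empty(0)
    det = bins["detected"].to_numpy() if len(bins) else np.empty(0, dtype=bool)

    rows = []
    for w in weeks:
        rows.append({
            "week_start": w,
            "n_clicks": int(np.sum(click_w == w)),
            "n_bins_detected": int(np.sum(det[bin_w == w])) if len(bins) else 0,
            "t_seconds": effort_per_week[w],
            "t_bins": int(np.sum(bin_w == w)) if len(bins) else 0,
        })

    min_effort = edge_min_days * 86400.0
    # merge a short leading week forward and a short trailing week backward;
    # interior low-effort weeks (mid-record gaps) stand on their own
    if len(rows) > 1 and rows[0]["t_seconds"] < min_effort:
        first = rows.pop(0)
        for key in ("n_clicks", "n_bins_detected", "t_seconds", "t_bins"):
            rows[0][key] += first[key]
    if len(rows) > 1 and rows[-1]["t_seconds"] < min_effort:
        last = rows.pop()
        for key in ("n_clicks", "n_bins_detected", "t_seconds", "t_bins"):
            rows[-1][key] += last[key]

    out = pd.DataFrame(rows)
    out.insert(1, "site", site)
    out.insert(2, "species", species)
    return out


def estimate_false_rate(is_false) -> FalseDetectionRate:
    """False-detection proportion and CV from a manually labelled subsample.

    ``is_false`` is a boolean array marking which sampled detections were
    judged false.  The CV is the binomial standard error divided by the
    proportion; a sample with no false detections has an undefined CV, which
    is reported as 0 with a warning.
    """
    lab = np.asarray(is_false, dtype=bool)
    if lab.size == 0:
        raise ValueError("labelled sample must be non-empty")
    n = lab.size
    k = int(lab.sum())
    p = k / n
    if k == 0:
        warnings.warn("no false detections in sample: CV undefined, reported as 0",
                      stacklevel=2)
        return FalseDetectionRate(0.0, 0.0)
    cv = float(np.sqrt(p * (1 - p) / n) / p)
    return FalseDetectionRate(p, cv)
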