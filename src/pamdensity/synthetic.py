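"""Ground-truth synthetic data for every input of the density pipeline.

The generator emulates a seafloor recorder monitoring a disc of radius
``w`` at a known true animal density.  Groups of echolocating animals appear
as a Poisson process in time, sit at a uniform random position in the disc
for one dive cycle, and click in regular trains (species-specific modal ICI
with small jitter) during vocal bouts that cover the configured proportion
of the dive cycle.  Received levels follow the same sonar-equation and
piston-beam model as the detection simulator; clicks below the detection
threshold never reach the log.  False detections arrive uniformly in time
at a configured rate.  Alongside the click log the module generates effort
tables, tag-style dive-cycle records, multi-animal bout tables and
group-size samples, plus a ledger holding the ground truth so parameter
recovery is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clicklog import EPOCH_SUNDAY, SECONDS_PER_WEEK
from .detection import AcousticScenario, GroupBehavior, _tables
from .multipliers import DiveCycle, TagRecord

__all__ = [
    "TruthScenario",
    "generate_effort",
    "generate_click_log",
    "generate_tag_records",
    "generate_synchrony_bouts",
]

#: A Sunday 00:00 UTC (2010-05-02), the default start of synthetic records.
DEFAULT_START = EPOCH_SUNDAY + 2104 * SECONDS_PER_WEEK


@dataclass
class TruthScenario:
    """Ground truth of a synthetic monitoring record.

    ``true_density`` is in animals per 1000 km^2.  ``group_size_probs``
    gives the probability of group sizes 1..len(probs).  The vocal cycle:
    each animal clicks during ``bouts_per_cycle`` vocal fragments totalling
    ``proportion_clicking_seconds`` of its dive cycle; members of a group
    offset their bouts so that pairwise bout overlap equals
    ``bout_overlap_o``.  Clicks are spaced at the modal ICI with lognormal-
    free multiplicative jitter of CV ``ici_jitter_cv``.
    """
    true_density: float
    acoustic: AcousticScenario
    group_size_probs: tuple[float, ...] = (0.20, 0.50, 0.20, 0.07, 0.03)
    modal_ici: float = 0.29
    ici_jitter_cv: float = 0.05
    proportion_clicking_seconds: float = 0.141
    bouts_per_cycle: int = 1
    bout_overlap_o: float = 0.67
    dive_cycle_length_range: tuple[float, float] = (6000.0, 8400.0)
    false_click_rate: float = 3.0e-4
    behavior: GroupBehavior = field(default_factory=GroupBehavior)
    species: str = "Synthetic"
    site: str = "SYN"
    weeks: int = 26

    def __post_init__(self):
        p = np.asarray(self.group_size_probs, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("group_size_probs must be a probability vector")
        for name in ("proportion_clicking_seconds", "bout_overlap_o"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.true_density < 0:
            raise ValueError("true_density must be non-negative")

    @property
    def mean_group_size(self) -> float:
        p = np.asarray(self.group_size_probs)
        return float(np.sum(p * np.arange(1, p.size + 1)))

    @property
    def click_rate_r(self) -> float:
        """Implied mean cue rate r = proportion clicking / modal ICI."""
        return self.proportion_clicking_seconds / self.modal_ici


def generate_effort(weeks: int, gap_schedule=None, seed=None,
                    start_s: float = DEFAULT_START,
                    site: str = "SYN") -> pd.DataFrame:
    """Continuous (or gapped) recording effort of the requested length.

    ``gap_schedule`` is an optional list of ``(offset_s, duration_s)`` gaps
    relative to the record start.  Returns a ``site, start, end`` table.
    """
    if weeks < 1:
        raise ValueError("need at least one week")
    end_s = start_s + weeks * SECONDS_PER_WEEK
    periods = [(start_s, end_s)]
    for off, dur in sorted(gap_schedule or []):
        g0, g1 = start_s + off, start_s + off + dur
        new = []
        for p0, p1 in periods:
            if g1 <= p0 or g0 >= p1:
                new.append((p0, p1))
                continue
            if g0 > p0:
                new.append((p0, g0))
            if g1 < p1:
                new.append((g1, p1))
        periods = new
    return pd.DataFrame(periods, columns=["start", "end"]).assign(site=site)[
        ["site", "start", "end"]]


def _bout_intervals(rng, duration: float, vocal_total: float, n_bouts: int):
    """Place ``n_bouts`` equal vocal fragments at random in a dive cycle."""
    if vocal_total <= 0:
        return np.empty((0, 2))
    n_bouts = max(1, int(n_bouts))
    frag = vocal_total / n_bouts
    free = duration - vocal_total
    if free <= 0:
        return np.array([[0.0, duration]])
    # gaps before each fragment and after the last one sum to the free time
    gaps = rng.dirichlet(np.ones(n_bouts + 1)) * free
    starts = np.cumsum(gaps[:-1]) + frag * np.arange(n_bouts)
    return np.column_stack([starts, starts + frag])


def _wrap_intervals(iv: np.ndarray, length: float) -> np.ndarray:
    """Wrap intervals cyclically into [0, length), splitting at the seam."""
    out = []
    for b0, b1 in iv:
        b0, b1 = b0 % length, b0 % length + (b1 - b0)
        if b1 <= length:
            out.append((b0, b1))
        else:
            out.append((b0, length))
            out.append((0.0, b1 - length))
    return np.asarray(out)


def _click_train(rng, bout0: float, bout1: float, ici: float, jitter_cv: float):
    """Regular click times covering one vocal bout."""
    n = max(int(np.ceil((bout1 - bout0) / ici)) + 2, 2)
    gaps = ici * np.maximum(1.0 + jitter_cv * rng.standard_normal(n), 0.1)
    t = bout0 + np.concatenate([[0.0], np.cumsum(gaps)])
    return t[t < bout1]


def generate_click_log(truth: TruthScenario, effort: pd.DataFrame, seed=None):
    """Simulate the click-detection log a seafloor recorder would produce.

    Returns ``(clicks, ledger)``: a ``time_s, received_level_dbpp, species,
    site`` table of detected clicks sorted by time, and a ledger dict with
    the true group arrivals (time, position, size), the per-click source
    index (-1 for false detections) and summary counts.
    """
    rng = np.random.default_rng(seed)
    sc = truth.acoustic
    tab = _tables(sc.beam_loss_floor)
    floor = sc.beam_loss_floor
    w_m = sc.monitoring_radius_w * 1000.0
    area_km2 = np.pi * sc.monitoring_radius_w**2

    eff = effort[["start", "end"]].to_numpy(dtype=float)
    t_lo, t_hi = eff.min(), eff.max()
    l_lo, l_hi = truth.dive_cycle_length_range
    mean_len = 0.5 * (l_lo + l_hi)

    # stationary group arrivals: expected groups present at any instant is
    # (animal density * disc area) / mean group size
    dens_km2 = truth.true_density / 1000.0
    groups_present = dens_km2 * area_km2 / truth.mean_group_size
    nu = groups_present / mean_len
    span0, span1 = t_lo - l_hi, t_hi
    n_groups = rng.poisson(nu * (span1 - span0)) if truth.true_density > 0 else 0

    def in_effort(times):
        ok = np.zeros(times.size, dtype=bool)
        for p0, p1 in eff:
            ok |= (times >= p0) & (times < p1)
        return ok

    sizes = np.arange(1, len(truth.group_size_probs) + 1)
    all_t, all_rl, all_src = [], [], []
    groups = []
    for g in range(n_groups):
        t0 = rng.uniform(span0, span1)
        length = rng.uniform(l_lo, l_hi)
        size = int(rng.choice(sizes, p=np.asarray(truth.group_size_probs)))
        r_h = w_m * np.sqrt(rng.random())
        groups.append({"t0": t0, "duration": length, "size": size, "r_m": r_h})
        if t0 + length < t_lo or t0 > t_hi:
            continue
        vocal = truth.proportion_clicking_seconds * length
        base = _bout_intervals(rng, length, vocal, truth.bouts_per_cycle)
        if not base.size:
            continue
        frag = base[0, 1] - base[0, 0]
        shift = (1.0 - truth.bout_overlap_o) * frag
        # the group travels together: one heading arc per dive cycle shared
        # by all members, matching the single swept cone of the group
        # detection simulation; orientation varies click to click within it
        heading0 = rng.uniform(-np.pi, np.pi)
        sweep = np.deg2rad(rng.uniform(*truth.behavior.azimuth_sweep_range))
        for member in range(size):
            iv = _wrap_intervals(base + member * shift, length)
            alt = rng.uniform(*sc.animal_altitude_range)
            dz = alt - sc.receiver_altitude
            slant = np.hypot(r_h, dz)
            eps = np.arctan2(-dz, r_h)
            pitch_sd = rng.uniform(*sc.pitch_sd_range)
            times = np.concatenate([
                _click_train(rng, b0, b1, truth.modal_ici, truth.ici_jitter_cv)
                for b0, b1 in iv
            ]) + t0
            if not times.size:
                continue
            k = times.size
            beta = heading0 + rng.uniform(-sweep / 2, sweep / 2, k)
            pitch = np.deg2rad(rng.standard_normal(k) * pitch_sd)
            cosd = (np.cos(pitch) * np.cos(eps) * np.cos(beta)
                    + np.sin(pitch) * np.sin(eps))
            theta = np.arccos(np.clip(cosd, -1.0, 1.0))
            ka = tab.ka_from_di(rng.uniform(*sc.directivity_index_range, k))
            x = ka * np.sin(np.minimum(theta, np.pi / 2))
            loss = np.minimum(np.where(theta > np.pi / 2, floor, tab.loss_at(x)),
                              floor)
            sl = rng.normal(sc.source_level_mean, sc.source_level_sd, k)
            rl = sl - 20.0 * np.log10(slant) - sc.absorption * slant / 1000.0 - loss
            keep = (rl >= sc.detection_threshold) & in_effort(times)
            if keep.any():
                all_t.append(times[keep])
                all_rl.append(rl[keep])
                all_src.append(np.full(int(keep.sum()), g))

    n_true = int(sum(a.size for a in all_t))
    # false detections: uniform in time over effort, levels echo the
    # detected-click level distribution
    total_effort = float(np.sum(eff[:, 1] - eff[:, 0]))
    n_false = rng.poisson(truth.false_click_rate * total_effort)
    if n_false:
        weights = (eff[:, 1] - eff[:, 0]) / total_effort
        which = rng.choice(len(eff), size=n_false, p=weights)
        ft = rng.uniform(eff[which, 0], eff[which, 1])
        pool = np.concatenate(all_rl) if all_rl else None
        frl = (rng.choice(pool, size=n_false) if pool is not None and pool.size
               else sc.detection_threshold + rng.exponential(3.0, n_false))
        all_t.append(ft)
        all_rl.append(frl)
        all_src.append(np.full(n_false, -1))

    if all_t:
        t = np.concatenate(all_t)
        rl = np.concatenate(all_rl)
        src = np.concatenate(all_src)
        order = np.argsort(t)
        t, rl, src = t[order], rl[order], src[order]
    else:
        t = rl = np.empty(0)
        src = np.empty(0, dtype=int)

    clicks = pd.DataFrame({"time_s": t, "received_level_dbpp": rl,
                           "species": truth.species, "site": truth.site})
    ledger = {
        "true_density": truth.true_density,
        "groups": groups,
        "click_source": src,
        "n_true_detected": n_true,
        "n_false": int(n_false),
        "false_proportion": float(n_false / max(n_true + n_false, 1)),
    }
    return clicks, ledger


def generate_tag_records(truth: TruthScenario, n_cycles: int, seed=None,
                         tagging_effect: bool = False) -> TagRecord:
    """Dive-cycle tag record with click-positive seconds.

    Each cycle's vocal time is placed in ``bouts_per_cycle`` contiguous
    fragments; with ``tagging_effect`` the first cycle's vocal time is
    halved, emulating a behavioural response to tagging.
    """
    if n_cycles < 2:
        raise ValueError("need at least two dive cycles")
    rng = np.random.default_rng(seed)
    cycles = []
    for i in range(n_cycles):
        dur = int(rng.uniform(*truth.dive_cycle_length_range))
        vocal = truth.proportion_clicking_seconds * dur
        if tagging_effect and i == 0:
            vocal *= 0.5
        iv = _bout_intervals(rng, dur, vocal, truth.bouts_per_cycle)
        secs = [np.arange(int(np.floor(b0)), int(np.ceil(b1))) for b0, b1 in iv]
        pos = np.concatenate(secs) if secs else np.empty(0, dtype=int)
        cycles.append(DiveCycle(duration=dur,
                                click_positive_seconds=np.clip(pos, 0, dur - 1)))
    return TagRecord(cycles)


def generate_synchrony_bouts(o_target: float, n_encounters: int, seed=None,
                             duration_range=(600.0, 1800.0),
                             jitter: float = 0.05) -> pd.DataFrame:
    """Two-animal bout tables whose expected overlap statistic is ``o_target``.

    Each encounter holds one bout per animal of equal length ``m``; the
    second bout lags the first by ``(1 - o) m`` so the measured overlap is
    exactly ``o`` per encounter, with multiplicative jitter across
    encounters.
    """
    if not 0.0 <= o_target <= 1.0:
        raise ValueError("o_target must lie in [0, 1]")
    if n_encounters < 1:
        raise ValueError("need at least one encounter")
    rng = np.random.default_rng(seed)
    rows = []
    for enc in range(n_encounters):
        m = rng.uniform(*duration_range)
        # the degenerate targets (fully synchronous / fully disjoint bouts)
        # are constructed exactly; interior targets carry encounter-level
        # jitter so the overlap statistic has a non-zero CV
        if jitter > 0 and 0.0 < o_target < 1.0:
            o = float(np.clip(o_target * (1.0 + jitter * rng.standard_normal()),
                              0.0, 1.0))
        else:
            o = o_target
        lag = (1.0 - o) * m
        rows.append((enc, "A", 0.0, m))
        rows.append((enc, "B", lag, lag + m))
    return pd.DataFrame(rows, columns=["encounter_id", "animal_id",
                                       "start_s", "end_s"])
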