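"""Click-log reduction: encounters, 5-min bins, weekly counts, false rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamdensity.clicklog import (SECONDS_PER_WEEK, assemble_encounters,
                                 bin_clicks, estimate_false_rate,
                                 weekly_aggregate)
from pamdensity.synthetic import DEFAULT_START

WEEK0 = DEFAULT_START  # a Sunday 00:00 UTC


def brute_force_encounters(times, max_gap=3600.0, min_duration=75.0):
    """Independent reference: explicit pairwise gap scan."""
    segments = []
    cur = []
    for t in times:
        if cur and t - cur[-1] > max_gap:
            segments.append(cur)
            cur = []
        cur.append(t)
    if cur:
        segments.append(cur)
    return [(seg[0], seg[-1], len(seg)) for seg in segments
            if len(seg) >= 2 and seg[-1] - seg[0] > min_duration]


class TestEncounters:
    def test_single_click_yields_nothing(self):
        assert assemble_encounters([100.0]) == []

    def test_empty_input(self):
        assert assemble_encounters([]) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            assemble_encounters([10.0, 5.0])

    def test_sub_hour_gap_bridged(self):
        # clicking 0..80 s, 30 min silence, clicking 1880..1960 s: the gap is
        # below one hour so a single encounter spans the whole period
        t = np.concatenate([np.arange(0, 80.5, 0.5), np.arange(1880, 1960.5, 0.5)])
        enc = assemble_encounters(t)
        assert len(enc) == 1
        assert enc[0].start == 0.0 and enc[0].end == 1960.0
        assert enc[0].n_clicks == t.size

    def test_two_hour_gap_splits(self):
        burst = np.arange(0, 80.5, 0.5)
        t = np.concatenate([burst, burst + 80.0 + 7200.0])
        enc = assemble_encounters(t)
        assert len(enc) == 2

    def test_short_encounters_discarded(self):
        # 60 s of clicking is below the 75 s minimum
        assert assemble_encounters(np.arange(0, 61.0, 1.0)) == []

    def test_matches_brute_force_on_large_log(self, rng):
        # clustered arrivals with heavy-tailed gaps exercise both rules
        gaps = rng.exponential(200.0, 10_000)
        t = np.cumsum(gaps)
        enc = assemble_encounters(t)
        ref = brute_force_encounters(t)
        assert [(e.start, e.end, e.n_clicks) for e in enc] == ref

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1e5, allow_nan=False),
                    min_size=0, max_size=60))
    def test_matches_brute_force_property(self, times):
        t = np.sort(np.asarray(times))
        enc = assemble_encounters(t, max_gap=500.0, min_duration=75.0)
        ref = brute_force_encounters(t, max_gap=500.0, min_duration=75.0)
        assert [(e.start, e.end, e.n_clicks) for e in enc] == ref

    def test_idempotent_under_reapplication(self, rng):
        t = np.cumsum(rng.exponential(300.0, 2000))
        enc = assemble_encounters(t)
        for e in enc:
            sub = t[(t >= e.start) & (t <= e.end)]
            again = assemble_encounters(sub)
            assert len(again) == 1
            assert again[0].start == e.start and again[0].end == e.end


class TestBinClicks:
    def test_empty_hour_gives_twelve_undetected_bins(self):
        bins = bin_clicks([], [(0.0, 3600.0)])
        assert len(bins) == 12
        assert not bins["detected"].any()

    def test_detection_threshold_is_five_clicks(self):
        four = bin_clicks(np.linspace(10, 200, 4), [(0.0, 300.0)])
        five = bin_clicks(np.linspace(10, 200, 5), [(0.0, 300.0)])
        assert not four["detected"].iloc[0]
        assert five["detected"].iloc[0]

    def test_counts_equal_histogram_oracle(self, rng):
        t = np.sort(rng.uniform(0, 7200.0, 3000))
        bins = bin_clicks(t, [(0.0, 7200.0)])
        oracle, _ = np.histogram(t, bins=np.arange(0, 7201.0, 300.0))
        assert np.array_equal(bins["n_clicks"].to_numpy(), oracle)

    def test_partial_bins_not_emitted_and_clicks_warned(self):
        # effort 0..450 s holds one whole bin; a click at 400 s sits in the
        # partial remainder
        with pytest.warns(UserWarning, match="outside"):
            bins = bin_clicks([10.0, 400.0], [(0.0, 450.0)])
        assert len(bins) == 1
        assert bins["n_clicks"].iloc[0] == 1

    def test_grid_is_absolute(self):
        # effort starting off-grid: first whole bin starts at the next
        # 300-s boundary
        bins = bin_clicks([], [(150.0, 900.0)])
        assert bins["bin_start"].tolist() == [300.0, 600.0]


class TestWeeklyAggregate:
    def _aggregate(self, effort, clicks=()):
        clicks = np.asarray(clicks, dtype=float)
        bins = bin_clicks(clicks, effort)
        return weekly_aggregate(bins, clicks, effort)

    def test_full_week_has_2016_bins(self):
        out = self._aggregate([(WEEK0, WEEK0 + SECONDS_PER_WEEK)])
        assert len(out) == 1
        assert out["t_bins"].iloc[0] == 2016
        assert out["t_seconds"].iloc[0] == SECONDS_PER_WEEK

    def test_no_effort_no_rows(self):
        out = weekly_aggregate(pd.DataFrame(columns=["bin_start", "n_clicks", "detected"]),
                               [], np.empty((0, 2)))
        assert len(out) == 0

    def test_friday_start_keeps_standalone_edge_week(self):
        # two full days of effort before the Sunday boundary stand alone
        friday = WEEK0 + SECONDS_PER_WEEK - 2 * 86400
        out = self._aggregate([(friday, WEEK0 + 2 * SECONDS_PER_WEEK)])
        assert len(out) == 2
        assert out["t_seconds"].iloc[0] == 2 * 86400
        assert out["week_start"].iloc[0] == WEEK0

    def test_saturday_start_merges_into_next_week(self):
        saturday = WEEK0 + SECONDS_PER_WEEK - 86400
        out = self._aggregate([(saturday, WEEK0 + 2 * SECONDS_PER_WEEK)])
        # merged row is labelled with the full week's start and carries the
        # extra day of effort
        assert len(out) == 1
        assert out["week_start"].iloc[0] == WEEK0 + SECONDS_PER_WEEK
        assert out["t_seconds"].iloc[0] == SECONDS_PER_WEEK + 86400

    def test_every_effort_second_in_exactly_one_row(self, rng):
        # gapped effort across five weeks, trailing short edge
        periods = [(WEEK0 + 1 * 86400, WEEK0 + 9 * 86400),
                   (WEEK0 + 10 * 86400, WEEK0 + 23 * 86400),
                   (WEEK0 + 28 * 86400, WEEK0 + 29 * 86400)]
        total = sum(p1 - p0 for p0, p1 in periods)
        clicks = np.sort(rng.uniform(WEEK0, WEEK0 + 29 * 86400, 500))
        keep = np.zeros(clicks.size, dtype=bool)
        for p0, p1 in periods:
            keep |= (clicks >= p0) & (clicks < p1)
        clicks = clicks[keep]
        bins = bin_clicks(clicks, periods)
        out = weekly_aggregate(bins, clicks, periods)
        assert out["t_seconds"].sum() == total
        assert out["t_bins"].sum() == len(bins)
        assert out["n_clicks"].sum() == clicks.size

    def test_weekly_clicks_include_subthreshold_bins(self):
        # 3 clicks in one bin: below the 5-click bin filter but still counted
        # in the weekly click stream
        clicks = [WEEK0 + 10.0, WEEK0 + 20.0, WEEK0 + 30.0]
        out = self._aggregate([(WEEK0, WEEK0 + SECONDS_PER_WEEK)], clicks)
        assert out["n_clicks"].iloc[0] == 3
        assert out["n_bins_detected"].iloc[0] == 0


class TestFalseRate:
    def test_ratio(self):
        fr = estimate_false_rate([True] * 59 + [False] * 941)
        assert fr.proportion == pytest.approx(0.059)
        assert fr.cv == pytest.approx(np.sqrt(0.059 * 0.941 / 1000) / 0.059)

    def test_zero_false_warns(self):
        with pytest.warns(UserWarning, match="CV undefined"):
            fr = estimate_false_rate([False] * 100)
        assert fr.proportion == 0.0 and fr.cv == 0.0

    def test_bin_level_rate(self):
        fr = estimate_false_rate([True] * 30 + [False] * 5970)
        assert fr.proportion == pytest.approx(0.005)
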