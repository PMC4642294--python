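"""Behavioural multipliers: ICI mode, clicking proportions, synchrony, P_v."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamdensity.multipliers import (DiveCycle, TagRecord, click_rate,
                                    group_size_stats, group_vocal_probability,
                                    ici_weekly_mode, pooled_click_spacing_rate,
                                    proportion_clicking_bins,
                                    proportion_clicking_seconds,
                                    synchrony_overlap)


class TestIciMode:
    def test_degenerate_distribution(self):
        assert ici_weekly_mode([0.29] * 200) == pytest.approx(0.29)

    def test_too_few_values_yields_none(self):
        assert ici_weekly_mode([0.29] * 99) is None

    def test_values_at_or_above_one_second_excluded(self):
        assert ici_weekly_mode([1.0] * 500) is None

    def test_mixture_mode_matches_histogram_oracle(self, rng):
        # 80% true ICIs near 0.5 s plus 20% missed-click doubles near 1.0 s
        # (truncated below 1 s): the mode must sit at the main component
        main = rng.normal(0.50, 0.01, 800)
        doubles = rng.normal(1.0, 0.02, 200)
        values = np.concatenate([main, doubles])
        mode = ici_weekly_mode(values)
        edges = np.arange(0.0, 1.0 + 0.005, 0.005)
        hist, _ = np.histogram(values[(values > 0) & (values < 1)], bins=edges)
        oracle = edges[np.argmax(hist)] + 0.0025
        assert mode == pytest.approx(oracle, abs=0.01)
        assert mode == pytest.approx(0.50, abs=0.01)

    def test_gervais_like_train(self, rng):
        values = rng.normal(0.29, 0.29 * 0.02, 500)
        assert ici_weekly_mode(values) == pytest.approx(0.29, abs=0.005)


class TestPooledRate:
    def test_equal_modes(self):
        est = pooled_click_spacing_rate([0.5, 0.5], [1.0, 1.0])
        assert est.pooled_rate == pytest.approx(2.0)
        assert est.cv == 0.0

    def test_hand_computed_weighted_mean(self):
        # rates 2 and 4 with weights 1 and 3: (2 + 12) / 4 = 3.5
        est = pooled_click_spacing_rate([0.5, 0.25], [1.0, 3.0])
        assert est.pooled_rate == pytest.approx(3.5)

    def test_single_week_warns_cv_zero(self):
        with pytest.warns(UserWarning, match="single"):
            est = pooled_click_spacing_rate([0.5], [1.0])
        assert est.cv == 0.0

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0.1, max_value=0.99), min_size=2, max_size=10))
    def test_equal_weights_reduce_to_simple_mean(self, modes):
        est = pooled_click_spacing_rate(modes, np.ones(len(modes)))
        assert est.pooled_rate == pytest.approx(np.mean(1.0 / np.asarray(modes)))

    def test_cuviers_like_rate(self):
        est = pooled_click_spacing_rate([0.50, 0.52, 0.53], [1.0, 1.0, 1.0])
        assert 1.85 <= est.pooled_rate <= 2.05


def _tag(cycles):
    return TagRecord([DiveCycle(d, np.asarray(p, dtype=int)) for d, p in cycles])


class TestClickingProportions:
    def test_fully_vocal_cycles(self):
        tag = _tag([(600, range(600)), (600, range(600))])
        p, cv = proportion_clicking_seconds(tag, exclude_first=False)
        assert p == 1.0
        pb, _ = proportion_clicking_bins(tag, exclude_first=False, seed=0)
        assert pb == 1.0

    def test_weighted_mean_arithmetic(self):
        tag = _tag([(3600, range(900)), (1800, range(180))])
        p, _ = proportion_clicking_seconds(tag, exclude_first=False)
        assert p == pytest.approx((900 + 180) / (3600 + 1800))

    def test_first_cycle_excluded_by_default(self):
        tag = _tag([(1000, []), (1000, range(500))])
        p, _ = proportion_clicking_seconds(tag)
        assert p == pytest.approx(0.5)

    def test_binned_proportion_matches_exhaustive_start_oracle(self):
        # one 600 s cycle, clicking only in [0, 60): enumerate every integer
        # start to get the exact expectation over random starts
        dur, bin_len = 600, 300
        pos = np.arange(60)
        occupied = []
        for start in range(dur):
            idx = ((pos - start) % dur) // bin_len
            occupied.append(np.unique(idx[idx < dur // bin_len]).size / (dur // bin_len))
        oracle = np.mean(occupied)
        tag = _tag([(dur, pos)])
        pb, _ = proportion_clicking_bins(tag, exclude_first=False,
                                         n_randomizations=4000, seed=42)
        assert pb == pytest.approx(oracle, abs=0.02)

    def test_binning_inflates_occupancy(self, rng):
        # scattered click-positive seconds: a bin is occupied by a single
        # second, so the bin proportion can only exceed the second proportion
        cycles = []
        for _ in range(5):
            dur = int(rng.integers(1200, 3600))
            pos = rng.choice(dur, size=int(0.2 * dur), replace=False)
            cycles.append((dur, pos))
        tag = _tag(cycles)
        ps, _ = proportion_clicking_seconds(tag, exclude_first=False)
        pb, _ = proportion_clicking_bins(tag, exclude_first=False, seed=3)
        assert pb >= ps

    def test_short_cycle_skipped_with_warning(self):
        tag = _tag([(200, range(10)), (600, range(60))])
        with pytest.warns(UserWarning, match="skipped"):
            pb, _ = proportion_clicking_bins(tag, exclude_first=False, seed=0)
        assert 0 <= pb <= 1


class TestClickRate:
    def test_product(self):
        from pamdensity.multipliers import ClickRateEstimate
        est = click_rate(0.5, 0.0, ClickRateEstimate(2.0, 0.0))
        assert est.rate == pytest.approx(1.0)

    def test_cv_root_sum_square(self):
        from pamdensity.multipliers import ClickRateEstimate
        est = click_rate(0.243, 0.171, ClickRateEstimate(1.0 / 0.51, 0.0))
        assert est.rate == pytest.approx(0.476, abs=0.002)
        assert est.cv == pytest.approx(0.171)


class TestSynchrony:
    @staticmethod
    def _bouts(rows):
        return pd.DataFrame(rows, columns=["encounter_id", "animal_id",
                                           "start_s", "end_s"])

    def test_identical_intervals(self):
        b = self._bouts([(0, "A", 0.0, 100.0), (0, "B", 0.0, 100.0)])
        assert synchrony_overlap(b).overlap == pytest.approx(1.0)

    def test_disjoint_intervals(self):
        b = self._bouts([(0, "A", 0.0, 100.0), (0, "B", 200.0, 300.0)])
        assert synchrony_overlap(b).overlap == pytest.approx(0.0)

    def test_half_overlap(self):
        # A=[0,100], B=[50,150]: joint period 50, mean individual period 100
        b = self._bouts([(0, "A", 0.0, 100.0), (0, "B", 50.0, 150.0)])
        assert synchrony_overlap(b).overlap == pytest.approx(0.5)

    def test_single_animal_rejected(self):
        b = self._bouts([(0, "A", 0.0, 100.0)])
        with pytest.raises(ValueError, match="2 animals"):
            synchrony_overlap(b)


class TestGroupVocalProbability:
    def test_cuviers_anchor(self):
        est = group_vocal_probability(0.354, 0.08, 0.67, 0.03)
        assert round(est.p_v, 3) == 0.471
        assert round(est.cv, 2) == 0.09

    def test_gervais_anchor(self):
        est = group_vocal_probability(0.191, 0.171, 0.67, 0.03)
        assert round(est.p_v, 3) == 0.254

    def test_capped_at_unity(self):
        assert group_vocal_probability(0.6, 0.0, 0.0, 0.0).p_v == 1.0

    def test_only_pairs_supported(self):
        with pytest.raises(ValueError):
            group_vocal_probability(0.3, 0.0, 0.5, 0.0, group_size=3)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_bounds_and_monotonicity(self, p_r, o):
        pv = group_vocal_probability(p_r, 0.0, o, 0.0).p_v
        assert p_r <= pv + 1e-12
        assert pv <= min(1.0, 2.0 * p_r) + 1e-12
        # monotone decreasing in overlap
        pv_more_sync = group_vocal_probability(p_r, 0.0, min(1.0, o + 0.1), 0.0).p_v
        assert pv_more_sync <= pv + 1e-12


class TestGroupSize:
    def test_constant_sample(self):
        est = group_size_stats([2, 2, 2])
        assert est.mean == 2.0 and est.cv == 0.0
        assert est.histogram.tolist() == [0, 3]

    def test_se_of_mean(self):
        est = group_size_stats([1, 2, 3])
        se = np.std([1, 2, 3], ddof=1) / np.sqrt(3)
        assert est.mean == pytest.approx(2.0)
        assert est.cv == pytest.approx(se / 2.0)
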