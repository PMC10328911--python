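"""Cloud filtering, gap filling and maximum-value compositing contracts."""

import numpy as np
import pytest

from maizemap import (compute_indices, drop_cloudy_scenes, flatten_features,
                      max_value_composite, replace_cloudy_bands,
                      unflatten_features)
from maizemap.calendar import DEFAULT_PERIODS
from maizemap.compositing import append_indices

from conftest import make_stack, random_toy_stack


def stack_with_fractions(fractions):
    """One scene per listed cloud fraction on a 1x10 grid, each period covered."""
    dates = np.linspace(91, 334, len(fractions)).astype(int).tolist()
    t = len(dates)
    data = np.random.default_rng(0).random((t, 6, 1, 10)).astype(np.float32)
    cloud = np.zeros((t, 6, 1, 10), bool)
    for ti, frac in enumerate(fractions):
        cloud[ti, :, 0, :int(round(frac * 10))] = True
    return make_stack(dates, data, cloud)


class TestDropCloudyScenes:
    def test_threshold_one_is_identity(self):
        stack = stack_with_fractions([0.0, 0.3, 0.9, 0.2])
        out = drop_cloudy_scenes(stack, 1.0)
        assert out.dates == stack.dates
        np.testing.assert_array_equal(out.data, stack.data)

    def test_counts_scenes_below_threshold(self):
        # survivors are the first five dates, all inside Apr–May..Jun–Jul
        fractions = [i / 10 for i in range(10)]
        out = drop_cloudy_scenes(stack_with_fractions(fractions), 0.45,
                                 periods=[DEFAULT_PERIODS[0]])
        assert out.n_scenes == 5

    def test_zero_threshold_keeps_only_clean(self):
        stack = stack_with_fractions([0.5, 0.0, 0.5, 0.0, 0.5, 0.0, 0.2, 0.0])
        out = drop_cloudy_scenes(stack, 0.0)
        assert out.n_scenes == 4 and not out.cloud.any()

    def test_error_when_a_period_is_emptied(self):
        # all Apr–May scenes too cloudy
        dates = [100, 160, 230, 300]
        cloud = np.zeros((4, 6, 1, 1), bool)
        cloud[0] = True
        stack = make_stack(dates, np.zeros((4, 6, 1, 1)), cloud)
        with pytest.raises(ValueError, match=r"period \[91, 151\]"):
            drop_cloudy_scenes(stack, 0.5)


class TestReplaceCloudyBands:
    def test_clean_stack_unchanged(self):
        stack = make_stack([100, 200, 300], np.random.default_rng(1).random((3, 6, 2, 2)))
        out = replace_cloudy_bands(stack)
        np.testing.assert_array_equal(out.data, stack.data)
        assert not out.cloud.any()

    def test_tie_breaks_to_earlier_date(self):
        data = np.zeros((3, 6, 1, 1), np.float32)
        data[0, 3] = 0.30   # day 134
        data[1, 3] = 0.99   # day 150, flagged
        data[2, 3] = 0.32   # day 166
        cloud = np.zeros((3, 6, 1, 1), bool)
        cloud[1, 3] = True
        out = replace_cloudy_bands(make_stack([134, 150, 166], data, cloud))
        assert out.data[1, 3, 0, 0] == np.float32(0.30)
        assert not out.cloud.any()

    def test_nearest_in_time_wins(self):
        data = np.zeros((3, 6, 1, 1), np.float32)
        data[0, 0], data[2, 0] = 0.1, 0.2
        cloud = np.zeros((3, 6, 1, 1), bool)
        cloud[1, 0] = True
        out = replace_cloudy_bands(make_stack([91, 200, 210], data, cloud))
        assert out.data[1, 0, 0, 0] == np.float32(0.2)  # 210 closer than 91

    def test_always_cloudy_pixel_stays_invalid_and_period_falls_back(self):
        # band 0 of pixel (0,0) cloudy at every date -> irreplaceable
        dates = [100, 140, 170, 230, 300]
        data = np.full((5, 6, 1, 2), 0.5, np.float32)
        cloud = np.zeros((5, 6, 1, 2), bool)
        cloud[:, 0, 0, 0] = True
        out = replace_cloudy_bands(make_stack(dates, data, cloud))
        assert out.cloud[:, 0, 0, 0].all()
        comp = max_value_composite(out)
        assert not comp.valid[:, 0, 0].any()      # every period lacks band 0
        assert comp.valid[:, 0, 1].all()          # neighbour pixel unaffected


class TestMaxValueComposite:
    def test_single_scene_per_period_is_identity(self):
        dates = [120, 180, 240, 300]
        data = np.random.default_rng(2).random((4, 6, 3, 3)).astype(np.float32)
        comp = max_value_composite(make_stack(dates, data))
        np.testing.assert_array_equal(comp.values, data)
        assert comp.valid.all()

    def test_max_of_listed_nir_values(self):
        dates = [155, 170, 200]                    # all Jun–Jul
        data = np.zeros((3, 6, 1, 1), np.float32)
        data[:, 3, 0, 0] = [0.12, 0.30, 0.25]
        comp = max_value_composite(make_stack(dates, data),
                                   periods=[DEFAULT_PERIODS[1]])
        assert comp.values[0, 3, 0, 0] == np.float32(0.30)

    def test_unhandled_cloud_corrupts_naive_max(self):
        """A flagged bright-Blue observation must be excluded: the naive max
        keeps 0.95, the pipeline keeps the clean 0.18."""
        dates = [160, 176]
        data = np.full((2, 6, 1, 1), 0.18, np.float32)
        data[1, 0] = 0.95
        cloud = np.zeros((2, 6, 1, 1), bool)
        cloud[1, 0] = True
        naive = max_value_composite(make_stack(dates, data),
                                    periods=[DEFAULT_PERIODS[1]])
        # pretending every observation is valid keeps the cloud value
        dirty = max_value_composite(make_stack(dates, data, None),
                                    periods=[DEFAULT_PERIODS[1]])
        assert dirty.values[0, 0, 0, 0] == np.float32(0.95)
        assert naive.values[0, 0, 0, 0] == np.float32(0.95)
        clean = max_value_composite(make_stack(dates, data, cloud),
                                    periods=[DEFAULT_PERIODS[1]])
        assert clean.values[0, 0, 0, 0] == np.float32(0.18)

    def test_empty_period_window_raises(self):
        stack = make_stack([100], np.zeros((1, 6, 1, 1)))
        with pytest.raises(ValueError, match="no scenes"):
            max_value_composite(stack)

    def test_monotonicity_adding_observation_never_decreases(self):
        rng = np.random.default_rng(3)
        stack = random_toy_stack(rng)
        base = max_value_composite(stack)
        # append one extra valid scene inside Jun–Jul
        extra_date = 175
        while extra_date in stack.dates:
            extra_date += 1
        data = np.concatenate([stack.data,
                               rng.random((1, 6, *stack.grid_shape), np.float32)
                               .astype(np.float32)])
        cloud = np.concatenate([stack.cloud,
                                np.zeros((1, 6, *stack.grid_shape), bool)])
        order = np.argsort(stack.dates + [extra_date])
        grown = make_stack(sorted(stack.dates + [extra_date]),
                           data[order], cloud[order])
        out = max_value_composite(grown)
        both = np.isfinite(base.values) & np.isfinite(out.values)
        assert (out.values[both] >= base.values[both]).all()

    def test_idempotent_on_one_scene_per_period(self):
        dates = [120, 180, 240, 300]
        data = np.random.default_rng(4).random((4, 6, 2, 2)).astype(np.float32)
        comp1 = max_value_composite(make_stack(dates, data))
        comp2 = max_value_composite(make_stack(dates, comp1.values))
        np.testing.assert_array_equal(comp1.values, comp2.values)

    def test_cloud_robustness_recovers_clean_composite(self, profiles):
        """Where a clean donor exists, the cloud-handled composite equals the
        composite of the uncontaminated stack."""
        from maizemap import SimScenario, simulate_scene_stack
        sc = SimScenario(grid_shape=(16, 16), cloud_prob=0.15, seed=9)
        stack, *_ = simulate_scene_stack(sc, profiles)
        clean_sc = SimScenario(grid_shape=(16, 16), cloud_prob=0.0, seed=9)
        clean_stack, *_ = simulate_scene_stack(clean_sc, profiles)
        # same seed -> same surfaces; clouds only overwrite flagged cells
        np.testing.assert_array_equal(stack.data[~stack.cloud],
                                      clean_stack.data[~stack.cloud])
        comp = max_value_composite(replace_cloudy_bands(stack))
        ref = max_value_composite(clean_stack)
        # composites agree exactly wherever a pixel/band had no flagged date
        # inside the period (replacement can only touch flagged cells); a
        # donor drawn from a *different* period may legitimately shift the
        # remaining cells, but at 16-day cadence the nearest donor is almost
        # always in-period, so recovery is near-total overall
        dates = np.asarray(stack.dates)
        for pi, (lo, hi) in enumerate(comp.periods):
            in_win = (dates >= lo) & (dates <= hi)
            unflagged = ~stack.cloud[in_win].any(axis=0)      # (6, H, W)
            np.testing.assert_array_equal(comp.values[pi][unflagged],
                                          ref.values[pi][unflagged])
        # flagged cells lose at most the flagged date's own clean value, so
        # errors stay within the noise scale — while skipping cloud handling
        # lets the bright signature corrupt the maxima outright
        naive = max_value_composite(
            make_stack(stack.dates, stack.data, np.zeros_like(stack.cloud)))
        err_pipeline = np.abs(comp.values - ref.values).mean()
        err_naive = np.abs(naive.values - ref.values).mean()
        assert err_pipeline < 0.01
        assert err_naive > 5 * err_pipeline


class TestFlatten:
    def test_ordering_contract_period_major(self):
        dates = [120, 180, 240, 300]
        data = np.zeros((4, 6, 1, 1), np.float32)
        data[1, 3] = 0.7                    # period 2, NIR
        comp = max_value_composite(make_stack(dates, data))
        flat = flatten_features(comp)
        assert flat.shape == (1, 1, 24)
        assert flat[0, 0, 9] == np.float32(0.7)   # (2-1)*6 + 4 = index 10, 1-based

    def test_round_trip(self):
        rng = np.random.default_rng(5)
        comp = max_value_composite(make_stack([120, 180, 240, 300],
                                              rng.random((4, 6, 3, 2))))
        back = unflatten_features(flatten_features(comp))
        np.testing.assert_array_equal(back.values, comp.values)
        np.testing.assert_array_equal(back.valid, comp.valid)

    def test_zero_composite_flattens_to_zero_vector(self):
        comp = max_value_composite(make_stack([120, 180, 240, 300],
                                              np.zeros((4, 6, 1, 1))))
        assert flatten_features(comp).tolist() == [[[0.0] * 24]]


class TestIndices:
    def test_hand_values(self):
        ndvi, evi, ndwi = compute_indices(blue=0.04, green=0.1, red=0.1, nir=0.5)
        assert ndvi == pytest.approx(0.6667, abs=1e-4)
        assert evi == pytest.approx(2.5 * 0.4 / (0.5 + 0.6 - 0.3 + 1), abs=1e-9)
        assert evi == pytest.approx(0.5556, abs=1e-4)

    def test_symmetry_zeros(self):
        ndvi, _, ndwi = compute_indices(blue=0.1, green=0.3, red=0.3, nir=0.3)
        assert ndvi == 0.0 and ndwi == 0.0

    def test_zero_denominator_gives_nan_not_exception(self):
        ndvi, evi, ndwi = compute_indices(blue=1.0 / 7.5, green=0.0, red=0.0, nir=0.0)
        assert np.isnan(ndvi) and np.isnan(evi) and np.isnan(ndwi)

    def test_append_indices_shapes_and_values(self):
        rng = np.random.default_rng(6)
        comp = max_value_composite(make_stack([120, 180, 240, 300],
                                              rng.uniform(0.05, 0.6, (4, 6, 2, 2))))
        aug = append_indices(comp)
        assert aug.values.shape == (4, 9, 2, 2)
        np.testing.assert_array_equal(aug.values[:, :6], comp.values)
        b = comp.values
        expect_ndvi = (b[:, 3] - b[:, 2]) / (b[:, 3] + b[:, 2])
        np.testing.assert_allclose(aug.values[:, 6], expect_ndvi, rtol=1e-6)
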