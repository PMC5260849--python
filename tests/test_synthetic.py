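import numpy as np
import pandas as pd
import pytest

import forestcloud as fc
from forestcloud.containers import FOREST
from forestcloud.timeutils import JJA


class TestBuildLandcover:
    def test_forest_pixel_count(self):
        lc = fc.build_landcover(200, 200, forest_rect=(50, 160, 50, 160))
        assert int(lc.mask(FOREST).sum()) == 12_100

    def test_forest_rect_out_of_bounds(self):
        with pytest.raises(ValueError, match="outside"):
            fc.build_landcover(100, 100, forest_rect=(50, 160, 50, 160))

    def test_damage_rect_must_be_inside_forest(self):
        with pytest.raises(ValueError, match="not inside"):
            fc.build_landcover(
                200, 200, forest_rect=(50, 160, 50, 160), damage_rect=(40, 60, 50, 70)
            )

    def test_named_boxes_registered(self):
        lc = fc.demo_landcover(80, 80)
        assert set(lc.boxes) == {"forest", "nonforest_1", "nonforest_2"}
        assert (lc.classes[lc.boxes["forest"].slices()] == FOREST).all()
        assert not (lc.classes[lc.boxes["nonforest_1"].slices()] == FOREST).any()

    def test_box_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="box"):
            fc.build_landcover(50, 50, forest_rect=(10, 40, 10, 40),
                               boxes={"bad": (0, 60, 0, 10)})


class TestSimulateTruth:
    def test_same_seed_bit_identical(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), seed=77)
        a = fc.simulate_truth(small_landcover, cfg)
        b = fc.simulate_truth(small_landcover, cfg)
        assert np.array_equal(a.true_cloud, b.true_cloud)
        assert np.array_equal(a.clearsky_counts, b.clearsky_counts)
        pd.testing.assert_frame_equal(a.wind, b.wind)
        c = fc.render_counts(a)
        d = fc.render_counts(b)
        assert np.array_equal(c.counts, d.counts)

    def test_different_seed_differs(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), seed=77)
        a = fc.simulate_truth(small_landcover, cfg)
        b = fc.simulate_truth(small_landcover, fc.with_seed(cfg, 78))
        assert not np.array_equal(a.true_cloud, b.true_cloud)

    def test_null_landscape_is_exchangeable(self, null_scene, small_landcover):
        masks = null_scene.cloud_mask_stack()
        fmap = fc.frequency_map(masks, season=JJA)
        p_f = fmap.box_mean(small_landcover.boxes["forest"])
        p_n = fmap.box_mean(small_landcover.boxes["nonforest_1"])
        n = fmap.n_valid[small_landcover.boxes["forest"].slices()].sum()
        se = np.sqrt(2 * 0.3 * 0.7 / n)
        assert abs(p_f - p_n) < 3 * se

    def test_jja_enhancement_within_binomial_error(self, jja_scene, small_landcover):
        masks = jja_scene.cloud_mask_stack()
        fmap = fc.frequency_map(masks, season=JJA)
        boxes = small_landcover.boxes
        p_f = fmap.box_mean(boxes["forest"])
        p_n = 0.5 * (fmap.box_mean(boxes["nonforest_1"]) + fmap.box_mean(boxes["nonforest_2"]))
        n = fmap.n_valid[boxes["forest"].slices()].sum()
        se = np.sqrt(p_f * (1 - p_f) / n + 0.5 * p_n * (1 - p_n) / n)
        assert abs((p_f - p_n) - jja_scene.config.delta_forest_jja) < 3 * se

    def test_no_enhancement_outside_summer(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(1,), seed=5)  # January only
        truth = fc.simulate_truth(small_landcover, cfg)
        masks = truth.cloud_mask_stack()
        fmap = fc.frequency_map(masks)
        p_f = fmap.box_mean(small_landcover.boxes["forest"])
        p_n = fmap.box_mean(small_landcover.boxes["nonforest_1"])
        n = fmap.n_valid[small_landcover.boxes["forest"].slices()].sum()
        assert abs(p_f - p_n) < 3 * np.sqrt(2 * 0.3 * 0.7 / n)

    def test_klaus_step_reduces_damage_zone_enhancement(self):
        lc = fc.demo_landcover(40, 40, damage=True)
        cfg = fc.SimConfig(
            start=pd.Timestamp("2008-01-01").date(), years=2, months=JJA,
            klaus_date=pd.Timestamp("2009-01-24").date(), seed=21,
            wind_displacement_km_per_ms=0.0,
        )
        truth = fc.simulate_truth(lc, cfg)
        masks = truth.cloud_mask_stack()
        dz = lc.damage_zone.slices()
        pre = fc.frequency_map(
            fc.CloudMaskStack(masks.times[masks.times.year == 2008],
                              masks.flags[masks.times.year == 2008])
        ).values[dz].mean()
        post = fc.frequency_map(
            fc.CloudMaskStack(masks.times[masks.times.year == 2009],
                              masks.flags[masks.times.year == 2009])
        ).values[dz].mean()
        # enhancement drops from 0.10 to 0.020 inside the damage zone
        assert pre - post == pytest.approx(0.08, abs=0.02)

    def test_missing_wind_day_rejected(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), seed=1)
        wind = pd.DataFrame({"u10": [0.0], "v10": [0.0]},
                            index=pd.to_datetime(["2004-06-01"]))
        with pytest.raises(ValueError, match="wind series missing"):
            fc.simulate_truth(small_landcover, cfg, wind=wind)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            fc.SimConfig(p_cloud_base=1.2)
        with pytest.raises(ValueError):
            fc.SimConfig(p_cloud_base=0.95, delta_forest_jja=0.10)
        with pytest.raises(ValueError):
            fc.SimConfig(years=0)


class TestRenderCounts:
    def test_noiseless_cloudfree_counts_equal_clearsky(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), p_cloud_base=0.0, delta_forest_jja=0.0,
                           noise_sd=0.0, seed=2)
        truth = fc.simulate_truth(small_landcover, cfg)
        counts = fc.render_counts(truth)
        h0, _ = cfg.daylight_window
        from forestcloud.timeutils import dekad_of

        dk = dekad_of(truth.times) - 1
        hr = truth.times.hour.to_numpy() - h0
        expected = truth.clearsky_counts[dk, hr]
        assert np.array_equal(counts.counts, expected.astype(np.int16))

    def test_cloud_boost_is_additive(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), p_cloud_base=1.0,
                           delta_forest_jja=0.0, noise_sd=0.0, seed=2)
        truth = fc.simulate_truth(small_landcover, cfg)
        counts = fc.render_counts(truth)
        from forestcloud.timeutils import dekad_of

        dk = dekad_of(truth.times) - 1
        hr = truth.times.hour.to_numpy() - cfg.daylight_window[0]
        expected = truth.clearsky_counts[dk, hr] + 50
        assert np.array_equal(counts.counts, expected.astype(np.int16))

    def test_counts_clipped_to_ten_bits(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), clear_base_counts=9000.0,
                           p_cloud_base=1.0, delta_forest_jja=0.0, seed=2)
        truth = fc.simulate_truth(small_landcover, cfg)
        counts = fc.render_counts(truth)
        assert counts.counts.max() == 1023

    def test_weak_boost_warns(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), cloud_boost_counts=8.0, seed=2)
        truth = fc.simulate_truth(small_landcover, cfg)
        with pytest.warns(UserWarning, match="undetectable"):
            fc.render_counts(truth)

    def test_missing_rate_injects_fill(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), missing_rate=0.1, seed=2)
        truth = fc.simulate_truth(small_landcover, cfg)
        counts = fc.render_counts(truth)
        frac = (counts.counts == -1).mean()
        assert frac == pytest.approx(0.1, abs=0.01)


def test_diurnal_lead_shifts_enhancement_early(small_landcover):
    cfg = fc.SimConfig(years=1, months=JJA, diurnal_lead_hours=2.0, seed=31,
                       wind_displacement_km_per_ms=0.0)
    truth = fc.simulate_truth(small_landcover, cfg)
    masks = truth.cloud_mask_stack()
    f = fc.diurnal_cycle(masks, small_landcover.boxes["forest"])
    n = fc.diurnal_cycle(masks, small_landcover.boxes["nonforest_1"])
    diff = f["value"] - n["value"]
    assert (diff.loc[6:9] > 0).all()  # positive early-morning contrast
    assert diff.loc[6:9].mean() > diff.loc[14:17].mean()  # and larger than evening


def test_dekadal_difference_seasonal_switch(small_landcover):
    cfg = fc.SimConfig(years=1, seed=13, wind_displacement_km_per_ms=0.0)
    truth = fc.simulate_truth(small_landcover, cfg)
    masks = truth.cloud_mask_stack()
    boxes = small_landcover.boxes
    diff = fc.dekadal_difference_series(
        masks, boxes["forest"], [boxes["nonforest_1"], boxes["nonforest_2"]]
    )
    month = diff.index.month
    summer = diff["value"][np.isin(month, JJA)]
    winter = diff["value"][np.isin(month, (1, 2, 12))]
    assert summer.mean() == pytest.approx(0.10, abs=0.02)
    assert abs(winter.mean()) < 0.02
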