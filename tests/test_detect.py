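import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forestcloud as fc
from forestcloud.detect import (
    BinScheme,
    InsufficientDataError,
    OutOfWindowError,
    ecdf_steepest,
    time_bin,
)


def ecdf_steepest_oracle(samples, w):
    """Naive reference: evaluate the ECDF rise over every integer candidate.

    ECDF(v + w/2) − ECDF(v − w/2) is n_window / n, so comparing the raw
    window occupancies (exact integers) ranks candidates identically.
    """
    s = np.asarray(samples, dtype=float)
    best_v, best_rise = None, -1
    for v in range(int(s.min()), int(s.max()) + 1):
        rise = int(np.sum(s <= v + w / 2)) - int(np.sum(s <= v - w / 2))
        if rise > best_rise:  # strict: ties keep the smallest v
            best_v, best_rise = v, rise
    return best_v


class TestTimeBin:
    def test_examples(self):
        assert time_bin(pd.Timestamp("2005-01-01 06:10")) == (1, 6)
        assert time_bin(pd.Timestamp("2005-12-31 17:45")) == (36, 17)

    def test_outside_daylight_rejected(self):
        with pytest.raises(OutOfWindowError):
            time_bin(pd.Timestamp("2005-06-01 05:59"))
        with pytest.raises(OutOfWindowError):
            time_bin(pd.Timestamp("2005-06-01 18:00"))


class TestEcdfSteepest:
    def test_constant_sample(self):
        assert ecdf_steepest([7, 7, 7], window_w=1) == 7

    def test_small_example(self):
        assert ecdf_steepest([5, 5, 6, 9], window_w=1) == 5

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            ecdf_steepest([])

    def test_bimodal_picks_dark_dense_mode(self):
        rng = np.random.default_rng(0)
        clear = np.rint(rng.normal(80, 2, 100)).astype(int)
        cloudy = np.rint(rng.normal(200, 5, 30)).astype(int)
        v = ecdf_steepest(np.concatenate([clear, cloudy]), window_w=3)
        assert 77 <= v <= 83

    def test_tie_breaks_to_smallest(self):
        assert ecdf_steepest([3, 3, 10, 10], window_w=1) == 3

    @settings(max_examples=150, deadline=None)
    @given(
        samples=st.lists(st.integers(0, 300), min_size=1, max_size=400),
        w=st.integers(1, 5),
    )
    def test_matches_exhaustive_oracle(self, samples, w):
        assert ecdf_steepest(samples, window_w=w) == ecdf_steepest_oracle(samples, w)


def _tiny_stack(count_value, nt=30, ny=2, nx=2, start="2004-01-01 06:00"):
    times = pd.date_range(start, periods=nt, freq="15min")
    counts = np.full((nt, ny, nx), count_value, dtype=np.int16)
    return fc.CountStack(times, counts)


class TestClimatology:
    def test_noiseless_cloudfree_matches_truth_exactly(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(6,), p_cloud_base=0.0, delta_forest_jja=0.0,
                           noise_sd=0.0, seed=3)
        truth = fc.simulate_truth(small_landcover, cfg)
        counts = fc.render_counts(truth)
        clim = fc.build_clearsky_climatology(counts, min_samples=10)
        valid = np.isfinite(clim.values)
        assert valid.any()
        assert np.array_equal(clim.values[valid], truth.clearsky_counts[valid])

    def test_contaminated_matches_truth_within_window(self, jja_scene, small_landcover):
        """30% cloud contamination leaves the clear-sky estimate within the
        search window almost everywhere; at 40% (enhanced forest pixels in
        a summer-only record) occasional bins lock onto the cloudy mode."""
        counts = fc.render_counts(jja_scene)
        clim = fc.build_clearsky_climatology(counts, window_w=3, min_samples=20)
        err = np.abs(clim.values - jja_scene.clearsky_counts)
        valid = np.isfinite(clim.values)
        forest = small_landcover.mask(1)
        assert (err[..., ~forest][valid[..., ~forest]] <= 3).mean() > 0.995
        assert (err[..., forest][valid[..., forest]] <= 3).mean() > 0.85
        assert (err[valid] <= 3).mean() > 0.95

    def test_sparse_bin_marked_invalid(self):
        stack = _tiny_stack(100, nt=8)  # 8 slots in (dekad 1, hour 6/7)
        clim = fc.build_clearsky_climatology(stack, min_samples=20)
        assert not np.isfinite(clim.values).any()
        assert clim.sample_count.sum() == 8 * 4

    def test_all_missing_bin_invalid(self):
        stack = _tiny_stack(100, nt=48)
        stack.counts[:4] = -1  # hour 6 of dekad 1 entirely missing
        clim = fc.build_clearsky_climatology(stack, min_samples=4)
        assert not np.isfinite(clim.values[0, 0]).any()
        assert np.isfinite(clim.values[0, 1]).all()


def _manual_clim(value, ny=1, nx=1):
    scheme = BinScheme()
    values = np.full((36, scheme.n_hours, ny, nx), float(value), dtype=np.float32)
    nsamp = np.full_like(values, 100, dtype=np.int32)
    return fc.ClearSkyClimatology(values, nsamp, scheme, window_w=3, min_samples=20)


class TestDetect:
    def test_strict_exceedance_convention(self):
        clim = _manual_clim(80, ny=2, nx=2)
        counts = np.array([[[91, 90], [80, 0]]], dtype=np.int16)
        stack = fc.CountStack(pd.to_datetime(["2004-01-01 06:00"]), counts)
        masks = fc.detect_clouds(stack, clim, threshold=10)
        assert masks.flags[0, 0, 0] == fc.CLOUD  # 91 > 90
        assert masks.flags[0, 0, 1] == fc.CLEAR  # 90 is not > 90
        assert masks.flags[0, 1, 0] == fc.CLEAR

    def test_missing_count_and_invalid_bin_propagate(self):
        clim = _manual_clim(80, ny=1, nx=2)
        clim.values[0, 0, 0, 1] = np.nan  # invalid bin for pixel 1 at (dekad 1, hour 6)
        counts = np.array([[[-1, 200]]], dtype=np.int16)
        stack = fc.CountStack(pd.to_datetime(["2004-01-01 06:00"]), counts)
        masks = fc.detect_clouds(stack, clim)
        assert masks.flags[0, 0, 0] == fc.MISSING
        assert masks.flags[0, 0, 1] == fc.MISSING

    def test_cloud_frequency_monotone_in_threshold(self, jja_scene):
        counts = fc.render_counts(jja_scene)
        clim = fc.build_clearsky_climatology(counts, min_samples=20)
        prev = None
        for tau in (5, 10, 20, 60):
            masks = fc.detect_clouds(counts, clim, threshold=tau)
            freq = fc.frequency_map(masks).values
            if prev is not None:
                assert np.all(freq <= prev + 1e-12)
            prev = freq

    def test_zero_cloud_noiseless_limit(self, small_landcover):
        cfg = fc.SimConfig(years=1, months=(7,), p_cloud_base=0.0, delta_forest_jja=0.0,
                           noise_sd=0.0, seed=9)
        truth = fc.simulate_truth(small_landcover, cfg)
        counts = fc.render_counts(truth)
        clim = fc.build_clearsky_climatology(counts, min_samples=10)
        masks = fc.detect_clouds(counts, clim)
        assert (masks.flags == fc.CLEAR).all()

    def test_detection_confusion_vs_truth(self, jja_scene):
        counts = fc.render_counts(jja_scene)
        clim = fc.build_clearsky_climatology(counts, min_samples=20)
        masks = fc.detect_clouds(counts, clim)
        cloud = masks.flags == fc.CLOUD
        hit = (cloud & jja_scene.true_cloud).sum() / jja_scene.true_cloud.sum()
        fa = (cloud & ~jja_scene.true_cloud).sum() / (~jja_scene.true_cloud).sum()
        assert hit > 0.95
        assert fa < 0.01
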