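"""Front extraction, smoothing and the normalized invasion extent."""

import numpy as np
import pytest

from ansia import front_quant as fq
from ansia import synthetic_data as sd
from ansia.errors import ConfigError, DataError
from ansia.io_formats import ImageStack, RoiPolygon

from conftest import smooth_oracle


class TestMaskFromStack:
    def test_noiseless_band_recovers_ground_truth(self):
        cfg = sd.FrontSimConfig(width=96, height=96, interface_row=32,
                                n_frames=3, fork_rate=0.0, noise_sigma=0.0)
        res = sd.simulate_front_stack(cfg)
        masks = fq.mask_from_stack(res.stack)
        np.testing.assert_array_equal(masks, res.true_masks)

    def test_default_noise_agreement_above_99pct(self):
        cfg = sd.FrontSimConfig(width=128, height=128, interface_row=48,
                                n_frames=4, fork_rate=0.2, seed=7)
        res = sd.simulate_front_stack(cfg)
        masks = fq.mask_from_stack(res.stack)
        agreement = (masks == res.true_masks).mean()
        assert agreement >= 0.99

    def test_uniform_frame_is_degenerate(self):
        stack = ImageStack(np.full((2, 16, 16), 7.0))
        with pytest.raises(DataError, match="degenerate"):
            fq.mask_from_stack(stack)


class TestExtractFront:
    def test_uniform_advance(self, band_mask):
        mask = band_mask(64, 40, 30)  # front at row 30, interface at 20
        profile = fq.extract_front(mask, interface_row=20)
        np.testing.assert_array_equal(profile.depth, np.full(40, 10.0))
        assert profile.interface_length == 40

    def test_tongue_matches_bruteforce_column_scan(self, band_mask):
        front = np.full(60, 25)
        front[10:15] = 50  # 5-px-wide tongue, 30 px beyond interface row 20
        mask = band_mask(80, 60, front)
        profile = fq.extract_front(mask, interface_row=20)
        # oracle: direct per-column scan of the ground-truth mask
        expected = np.array(
            [np.max(np.nonzero(mask[20:, x])[0]) for x in range(60)],
            dtype=float,
        )
        np.testing.assert_array_equal(profile.depth, expected)
        assert (profile.depth[10:15] == 30).all()
        assert (profile.depth[:10] == 5).all()

    def test_mask_not_reaching_interface_is_all_invalid(self, band_mask):
        mask = band_mask(64, 30, 10)  # band stops above interface row 40
        with pytest.warns(UserWarning, match="does not reach"):
            profile = fq.extract_front(mask, interface_row=40)
        assert not profile.valid.any()

    def test_detached_cluster_excluded_from_depth(self, band_mask):
        mask = band_mask(64, 30, 25)
        mask[50:55, 4:8] = True  # detached cells ahead of the front
        profile = fq.extract_front(mask, interface_row=20)
        assert (profile.depth == 5).all()

    def test_empty_mask_errors(self):
        with pytest.raises(DataError, match="empty mask"):
            fq.extract_front(np.zeros((8, 8), bool), 4)


class TestSmoothProfile:
    def test_constant_profile_is_fixed_point(self):
        p = fq.FrontProfile(np.full(100, 3.5))
        out = fq.smooth_profile(p, window=20)
        np.testing.assert_allclose(out.depth, 3.5, rtol=1e-12)

    def test_unit_impulse_matches_direct_summation(self):
        d = np.zeros(200)
        d[100] = 1.0
        out = fq.smooth_profile(fq.FrontProfile(d), window=20)
        np.testing.assert_allclose(out.depth, smooth_oracle(d, 20),
                                   rtol=0, atol=1e-12)
        covered = np.flatnonzero(out.depth > 0)
        assert covered.size == 20 and 100 in covered
        np.testing.assert_allclose(out.depth[covered], 1 / 20)

    def test_window_one_is_identity(self, rng):
        d = rng.normal(size=50)
        out = fq.smooth_profile(fq.FrontProfile(d), window=1)
        np.testing.assert_array_equal(out.depth, d)

    def test_window_larger_than_profile_errors(self):
        with pytest.raises(ConfigError, match="larger than profile"):
            fq.smooth_profile(fq.FrontProfile(np.zeros(10)), window=11)

    @pytest.mark.parametrize("window", [2, 5, 20, 33])
    def test_matches_bruteforce_with_invalid_positions(self, rng, window):
        d = rng.normal(10, 4, 150)
        d[rng.random(150) < 0.15] = np.nan
        out = fq.smooth_profile(fq.FrontProfile(d), window=window)
        np.testing.assert_allclose(out.depth, smooth_oracle(d, window),
                                   rtol=0, atol=1e-9, equal_nan=True)

    def test_preserves_interior_mean_and_bounds(self, rng):
        d = rng.uniform(0, 30, 400)
        out = fq.smooth_profile(fq.FrontProfile(d), window=20)
        # interior positions have fully contained windows
        interior = slice(10, 390)
        # mean of a moving average over the interior equals the mean of the
        # underlying values it touches, to numerical precision
        assert np.isfinite(out.depth).all()
        assert out.depth.min() >= d.min() - 1e-9
        assert out.depth.max() <= d.max() + 1e-9
        direct = smooth_oracle(d, 20)
        np.testing.assert_allclose(out.depth[interior], direct[interior],
                                   atol=1e-9)


class TestNormalizedExtent:
    def _mask_stack(self, band_mask, fronts, height=80, width=50):
        return np.stack([band_mask(height, width, f) for f in fronts])

    def test_uniform_advance_analytic(self, band_mask):
        masks = self._mask_stack(band_mask, [20, 25, 30])
        s = fq.normalized_extent(masks, interface_row=20)
        np.testing.assert_allclose(s.extent[0], [0.0, 5.0, 10.0])
        assert s.interface_length == 50

    def test_triangular_advance_half_depth(self, band_mask):
        # rasterizing the ramp biases the pixel count by ~half a pixel,
        # so the depth is chosen large enough for the 2% tolerance
        w, d = 200, 80
        ramp = 20 + np.linspace(0, d, w)
        masks = self._mask_stack(band_mask, [np.full(w, 20), ramp],
                                 height=120, width=w)
        s = fq.normalized_extent(masks, interface_row=20)
        assert s.extent[0, 1] == pytest.approx(d / 2, rel=0.02)

    def test_no_movement_zero(self, band_mask):
        masks = self._mask_stack(band_mask, [20, 20])
        s = fq.normalized_extent(masks, interface_row=20)
        np.testing.assert_array_equal(s.extent[0], [0.0, 0.0])

    def test_translation_and_padding_invariance(self, band_mask):
        front = np.full(60, 20)
        front[10:20] = 45
        masks = self._mask_stack(band_mask, [np.full(60, 20), front],
                                 height=90, width=60)
        base = fq.normalized_extent(masks, 20).extent[0]
        rolled = np.stack([np.roll(m, 17, axis=1) for m in masks])
        np.testing.assert_allclose(
            fq.normalized_extent(rolled, 20).extent[0], base
        )
        padded = np.pad(masks, ((0, 0), (0, 25), (0, 0)))  # stroma-only rows
        np.testing.assert_allclose(
            fq.normalized_extent(padded, 20).extent[0], base
        )

    def test_depth_sum_equals_area_for_single_valued_front(self, band_mask):
        rng = np.random.default_rng(5)
        front = 20 + rng.integers(0, 30, size=70)
        mask0 = band_mask(90, 70, 20)
        mask1 = band_mask(90, 70, front)
        s = fq.normalized_extent(np.stack([mask0, mask1]), 20)
        profile = fq.extract_front(mask1, 20)
        assert s.extent[0, 1] == pytest.approx(profile.depth.sum() / 70)

    def test_roi_polygon_route(self):
        # invaded region: rectangle W x d beyond the interface
        roi0 = RoiPolygon(np.array([[0, 0], [50, 0], [50, 0.0], [0, 0.0]]),
                          0, closed=True)
        roi1 = RoiPolygon(np.array([[0, 0], [50, 0], [50, 8.0], [0, 8.0]]),
                          1, closed=True)
        s = fq.normalized_extent_from_rois([roi1, roi0], interface_length=50)
        np.testing.assert_allclose(s.extent[0], [0.0, 8.0])


class TestFoldChange:
    def _summary(self, finals, cond=""):
        ext = np.column_stack([np.zeros(len(finals)), np.asarray(finals)])
        return fq.InvasionSummary(ext, condition=cond)

    def test_identical_replicates_fold_one(self):
        a = self._summary([10.0, 11.0, 9.0])
        res = fq.fold_change(a, self._summary([10.0, 11.0, 9.0]))
        assert res.fold_change == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == "n.s."

    def test_doubled_advance_rate_recovers_twofold(self):
        finals_v, finals_2v = [], []
        for seed in range(4):
            for rate, sink in ((2.0, finals_v), (4.0, finals_2v)):
                cfg = sd.FrontSimConfig(width=256, height=256,
                                        interface_row=96, n_frames=12,
                                        advance_rate=rate, fork_rate=0.2,
                                        seed=seed)
                res = sd.simulate_front_stack(cfg)
                masks = fq.mask_from_stack(res.stack)
                s = fq.normalized_extent(masks, cfg.interface_row)
                sink.append(s.extent[0, -1])
        res = fq.fold_change(self._summary(finals_2v), self._summary(finals_v))
        assert res.fold_change == pytest.approx(2.0, rel=0.15)

    def test_zero_control_errors(self):
        with pytest.raises(DataError, match="control mean"):
            fq.fold_change(self._summary([1.0, 2.0]),
                           self._summary([0.0, 0.0]))

    def test_advance_rate_recovered_from_extent_slope(self):
        cfg = sd.FrontSimConfig(width=256, height=256, interface_row=96,
                                n_frames=10, advance_rate=2.0, fork_rate=0.0,
                                seed=11)
        res = sd.simulate_front_stack(cfg)
        masks = fq.mask_from_stack(res.stack)
        s = fq.normalized_extent(masks, cfg.interface_row)
        slope = np.polyfit(np.arange(s.n_frames), s.extent[0], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.05)
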