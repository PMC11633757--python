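"""Preprocessing: stitching geometry, percentile normalization, shading
estimation/correction and mask coregistration."""

import numpy as np
import pytest
from scipy import ndimage

from endoseg.images import AcquisitionSpec, AnnotationMask, MultimodalImage
from endoseg.preprocess import (
    PercentileNormalizer,
    RegistrationError,
    RegistrationTransform,
    ShadingCorrector,
    ShadingModel,
    correct_shading,
    estimate_shading,
    percentile_normalize,
    register_from_landmarks,
    register_mask,
    stitch_tiles,
)
from endoseg.synthetic import decompose_into_tiles, vignette_profile


class TestStitchTiles:
    def test_mosaic_size_3x3_1200px(self):
        """3x3 grid of 1200-px tiles at 10% overlap stitches to 3240 px."""
        rng = np.random.default_rng(0)
        img = MultimodalImage(rng.random((3, 3360, 3360)))
        acq = AcquisitionSpec(tile_px=1200, overlap_frac=0.10, grid=(3, 3))
        stack = decompose_into_tiles(img, acq, seed=0)
        mosaic = stitch_tiles(stack, crop_frac=0.05)
        assert mosaic.shape == (3240, 3240)

    def test_single_tile_is_center_crop(self, mosaic):
        acq = AcquisitionSpec(tile_px=120, overlap_frac=0.10, grid=(1, 1))
        stack = decompose_into_tiles(mosaic, acq, seed=0)
        out = stitch_tiles(stack, crop_frac=0.05)
        assert np.array_equal(out.data, mosaic.data[:, 6:114, 6:114])

    def test_round_trip_is_pixel_exact(self, mosaic):
        """decompose (no vignette/noise) then stitch reproduces the central
        region of the source exactly — values are conserved, not blended."""
        acq = AcquisitionSpec(tile_px=120, overlap_frac=0.10, grid=(2, 2))
        stack = decompose_into_tiles(mosaic, acq, seed=0)
        out = stitch_tiles(stack, crop_frac=0.05)
        crop = 6
        expected = mosaic.data[:, crop : crop + out.shape[0], crop : crop + out.shape[1]]
        assert np.array_equal(out.data, expected)

    def test_inconsistent_geometry_states_expected_crop(self, mosaic):
        acq = AcquisitionSpec(tile_px=120, overlap_frac=0.10, grid=(2, 2))
        stack = decompose_into_tiles(mosaic, acq, seed=0)
        with pytest.raises(ValueError, match="0.05"):
            stitch_tiles(stack, crop_frac=0.08)


class TestPercentileNormalize:
    def test_constant_channel_zeroed_with_warning(self):
        img = MultimodalImage(np.full((3, 32, 32), 0.7))
        with pytest.warns(UserWarning, match="degenerate"):
            out = percentile_normalize(img)
        assert np.all(out.data == 0.0)

    def test_ramp_spans_unit_interval(self):
        ramp = np.linspace(0, 1, 64 * 64).reshape(64, 64)
        img = MultimodalImage(np.stack([ramp] * 3))
        out = percentile_normalize(img)
        assert out.data.min() == 0.0
        assert out.data.max() == 1.0

    def test_clip_fractions_match_percentiles(self):
        rng = np.random.default_rng(4)
        img = MultimodalImage(rng.random((3, 256, 256)))
        out = percentile_normalize(img, p_lo=1.5, p_hi=99.0)
        n = 256 * 256
        for ch in range(3):
            at_zero = np.mean(out.data[ch] == 0.0)
            at_one = np.mean(out.data[ch] == 1.0)
            # binomial tolerance around the nominal clip fractions
            assert at_zero <= 0.015 + 3 * np.sqrt(0.015 / n)
            assert at_one <= 0.01 + 3 * np.sqrt(0.01 / n)

    def test_monotone_per_channel(self):
        rng = np.random.default_rng(5)
        img = MultimodalImage(rng.random((3, 64, 64)))
        out = percentile_normalize(img)
        for ch in range(3):
            order = np.argsort(img.data[ch].ravel())
            vals = out.data[ch].ravel()[order]
            assert np.all(np.diff(vals) >= 0)

    def test_idempotent_on_normalized_ramp(self):
        ramp = np.linspace(0, 1, 200 * 200).reshape(200, 200)
        img = MultimodalImage(np.stack([ramp] * 3))
        once = percentile_normalize(img)
        twice = percentile_normalize(once)
        # up to clipping, renormalizing an already-normalized ramp is stable
        assert np.allclose(once.data, twice.data, atol=0.02)

    def test_estimator_interface(self):
        rng = np.random.default_rng(6)
        img = MultimodalImage(rng.random((3, 32, 32)))
        est = PercentileNormalizer(p_lo=2.0, p_hi=98.0)
        assert est.get_params()["p_lo"] == 2.0
        out = est.fit(img).transform(img)
        assert out.data.shape == img.data.shape
        assert hasattr(est, "lo_") and hasattr(est, "hi_")


@pytest.fixture(scope="module")
def vignetted_flat_stack():
    flat = MultimodalImage(np.full((3, 512, 512), 0.5))
    acq = AcquisitionSpec(
        tile_px=96, overlap_frac=0.10, vignette_strength=0.4, grid=(4, 4), noise_sd=0.01
    )
    return decompose_into_tiles(flat, acq, seed=0)


class TestShading:
    def test_flatfield_correlates_with_true_vignette(self, vignetted_flat_stack):
        model = estimate_shading(vignetted_flat_stack)
        true_v = vignette_profile(96, 0.4)
        for ch in range(3):
            r = np.corrcoef(model.flatfield[ch].ravel(), true_v.ravel())[0, 1]
            assert r > 0.95

    def test_identical_flat_tiles_give_unit_flatfield(self):
        flat = MultimodalImage(np.full((3, 512, 512), 0.5))
        acq = AcquisitionSpec(tile_px=96, overlap_frac=0.10, grid=(3, 3))
        stack = decompose_into_tiles(flat, acq, seed=0)
        model = estimate_shading(stack)
        assert np.allclose(model.flatfield, 1.0, atol=1e-9)

    def test_correction_halves_cv_on_flat_phantom(self, vignetted_flat_stack):
        corrected = ShadingCorrector().fit(vignetted_flat_stack).transform(vignetted_flat_stack)
        cv_before = vignetted_flat_stack.tiles.std() / vignetted_flat_stack.tiles.mean()
        cv_after = corrected.tiles.std() / corrected.tiles.mean()
        assert cv_after <= 0.5 * cv_before

    def test_residual_edge_center_ratio_near_one(self, vignetted_flat_stack):
        model = estimate_shading(vignetted_flat_stack)
        corrected = correct_shading(vignetted_flat_stack, model)
        tile = corrected.tiles.mean(axis=0)[0]
        edge = tile[0, :].mean()
        center = tile[40:56, 40:56].mean()
        assert edge / center == pytest.approx(1.0, abs=0.05)

    def test_identity_model_is_noop_and_clipping(self, vignetted_flat_stack):
        t = vignetted_flat_stack.spec.tile_px
        identity = ShadingModel(flatfield=np.ones((3, t, t)))
        out = correct_shading(vignetted_flat_stack, identity)
        assert np.allclose(out.tiles, np.clip(vignetted_flat_stack.tiles, 0, None))
        # negative values after dark-field subtraction clip to zero
        dark = ShadingModel(flatfield=np.ones((3, t, t)), darkfield=np.full((3, t, t), 10.0))
        assert np.all(correct_shading(vignetted_flat_stack, dark).tiles == 0.0)

    def test_shape_mismatch_and_empty_stack_raise(self, vignetted_flat_stack):
        with pytest.raises(ValueError, match="match"):
            correct_shading(vignetted_flat_stack, ShadingModel(flatfield=np.ones((3, 8, 8))))

    def test_flatfield_invariants(self):
        with pytest.raises(ValueError, match="positive"):
            ShadingModel(flatfield=np.zeros((3, 4, 4)))
        with pytest.raises(ValueError, match="unit mean"):
            ShadingModel(flatfield=np.full((3, 4, 4), 2.0))


class TestRegistration:
    def test_translation_recovery(self, label_map, mosaic):
        shifted = AnnotationMask(
            ndimage.shift(label_map.labels, (12, -7), order=0, mode="nearest"), level=6
        )
        tf, aligned = register_mask(shifted, mosaic, kind="translation")
        assert tf.dy == pytest.approx(12, abs=0.5)
        assert tf.dx == pytest.approx(-7, abs=0.5)
        # central region realigned to the original annotations
        core = np.s_[40:-40, 40:-40]
        agreement = np.mean(aligned.labels[core] == label_map.labels[core])
        assert agreement > 0.95

    def test_identity_gives_zero_transform(self, label_map, mosaic):
        tf, _ = register_mask(label_map, mosaic, kind="translation")
        assert abs(tf.dx) <= 0.5 and abs(tf.dy) <= 0.5

    def test_rigid_recovers_rotation(self, label_map, mosaic):
        rotated = ndimage.rotate(label_map.labels, 2.0, reshape=False, order=0, mode="nearest")
        moved = ndimage.shift(rotated, (5, -3), order=0, mode="nearest")
        tf, _ = register_mask(AnnotationMask(moved, level=6), mosaic, kind="rigid")
        assert tf.theta == pytest.approx(2.0, abs=0.5)
        assert tf.dy == pytest.approx(5, abs=1.0)
        assert tf.dx == pytest.approx(-3, abs=1.0)

    def test_no_new_labels_after_resampling(self, label_map, mosaic):
        shifted = AnnotationMask(
            ndimage.shift(label_map.labels, (9, 4), order=0, mode="nearest"), level=6
        )
        _, aligned = register_mask(shifted, mosaic, kind="translation")
        assert set(np.unique(aligned.labels)) <= set(np.unique(shifted.labels))

    def test_uncorrelated_content_flags_failure(self, mosaic):
        rng = np.random.default_rng(0)
        noise = AnnotationMask(rng.integers(0, 6, mosaic.data.shape[1:]), level=6)
        with pytest.raises(RegistrationError, match="failed"):
            register_mask(noise, mosaic, kind="translation", min_correlation=0.5)

    def test_landmark_fallback(self):
        fixed_pts = np.array([[10.0, 10.0], [10.0, 50.0], [40.0, 30.0]])
        moving_pts = fixed_pts + [3.0, -2.0]
        tf = register_from_landmarks(moving_pts, fixed_pts, kind="translation")
        assert (tf.dy, tf.dx) == (3.0, -2.0)
        theta = np.radians(4.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated = (fixed_pts - fixed_pts.mean(0)) @ rot.T + fixed_pts.mean(0)
        tf2 = register_from_landmarks(rotated, fixed_pts, kind="rigid")
        assert tf2.theta == pytest.approx(4.0, abs=0.2)

    def test_transform_invariants(self):
        with pytest.raises(ValueError):
            RegistrationTransform(dx=np.nan, dy=0.0)
        with pytest.raises(ValueError):
            RegistrationTransform(dx=0, dy=0, theta=3.0, kind="translation")
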