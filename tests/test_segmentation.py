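"""Biomarker segmentation: brute-force morphology oracles, detection of
planted lesions, pseudolabels and U-net refinement."""

import numpy as np
import pytest

from angiograde.frames import AngioFrame, Grade, Phase, Provenance, RetinaGeometry
from angiograde.gan import DifferenceImage, difference_image
from angiograde.segmentation import (
    SegParams,
    leakage_mask,
    local_min_map,
    moderate_baseline,
    perfused_baseline,
    pseudo_nonperfusion,
    segment_nonperfusion,
    suspected_nonperfusion,
    train_np_unet,
)
from angiograde.synth import SceneParams, generate_dataset, generate_eye, params_for_grade


def _frame(img, phase=Phase.EARLY):
    return AngioFrame(image=np.asarray(img, dtype=np.float32), phase=phase)


def _brute_min(img, k):
    h, w = img.shape
    r = k // 2
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            i0, i1 = max(0, i - r), min(h, i + r + 1)
            j0, j1 = max(0, j - r), min(w, j + r + 1)
            # edge replication: clipping the window equals replicate-padding
            out[i, j] = img[i0:i1, j0:j1].min()
    return out


def _brute_max(img, k):
    return -_brute_min(-img, k)


def _iou(a, b):
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


class TestMorphologyOracles:
    def test_min_map_constant(self):
        img = np.full((8, 8), 0.5)
        np.testing.assert_array_equal(local_min_map(_frame(img), 3), img)

    def test_min_map_spreads_single_zero(self):
        img = np.full((9, 9), 100.0, dtype=np.float32)
        img[4, 4] = 0.0
        out = local_min_map(_frame(img), 3)
        assert (out[3:6, 3:6] == 0).all()
        assert (out[np.abs(np.arange(9) - 4) > 1][:, np.abs(np.arange(9) - 4) > 1] == 100).all()

    @pytest.mark.parametrize("size", [3, 5])
    def test_min_map_matches_brute_force(self, rng, size):
        for _ in range(25):
            img = rng.random((8, 8)).astype(np.float32)
            np.testing.assert_array_equal(
                local_min_map(_frame(img), size), _brute_min(img, size)
            )

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            local_min_map(_frame(np.zeros((4, 4))), 4)
        with pytest.raises(ValueError):
            moderate_baseline(_frame(np.zeros((4, 4))), -1)

    def test_opening_constant_identity(self):
        img = np.full((10, 10), 0.3)
        np.testing.assert_allclose(moderate_baseline(_frame(img), 5), img)

    def test_opening_removes_thin_bright_line(self):
        img = np.full((12, 12), 0.2, dtype=np.float32)
        img[6, :] = 0.9
        out = moderate_baseline(_frame(img), 5)
        np.testing.assert_allclose(out[6, :], 0.2)

    @pytest.mark.parametrize("size", [3, 5])
    def test_opening_matches_brute_force(self, rng, size):
        for _ in range(25):
            img = rng.random((10, 10)).astype(np.float32)
            expect = _brute_max(_brute_min(img, size), size)
            np.testing.assert_array_equal(moderate_baseline(_frame(img), size), expect)

    def test_min_map_below_image_opening_anti_extensive(self, rng):
        img = rng.random((12, 12)).astype(np.float32)
        assert (local_min_map(_frame(img), 5) <= img).all()
        assert (moderate_baseline(_frame(img), 5) <= img + 1e-7).all()


class TestSuspectedNonperfusion:
    def test_constant_inside_footprint_empty(self):
        img = np.full((32, 32), 0.5, dtype=np.float32)
        fp = np.zeros((32, 32), dtype=bool)
        fp[4:28, 4:28] = True
        geom = RetinaGeometry(footprint=fp, disc_xy=(10, 16), macula_xy=(16, 16))
        mask = suspected_nonperfusion(_frame(img), geom, SegParams())
        assert not mask.any()

    def test_planted_dark_patch_iou(self):
        """A 0.3x-background dark patch is recovered at IoU >= 0.6."""
        eye = generate_eye(
            SceneParams(grade=Grade.NPDR, image_size=128, seed=3,
                        np_area_fraction=0.06, lk_area_fraction=0.0, ma_count=0)
        )
        mask = suspected_nonperfusion(eye.early, eye.geometry, SegParams(dark_ratio=0.7))
        assert _iou(mask, eye.truth_masks.nonperfusion) >= 0.6

    def test_never_outside_footprint(self, pdr_eye):
        mask = suspected_nonperfusion(pdr_eye.early, pdr_eye.geometry, SegParams())
        assert not (mask & ~pdr_eye.geometry.footprint).any()

    def test_monotone_in_lesion_contrast(self):
        """Deepening a dark patch never shrinks the suspected mask."""
        base_eye = generate_eye(
            SceneParams(grade=Grade.NPDR, image_size=96, seed=8,
                        np_area_fraction=0.08, lk_area_fraction=0.0, ma_count=0)
        )
        geom = base_eye.geometry
        npm = base_eye.truth_masks.nonperfusion
        clean = base_eye.early_clean.image
        prev = None
        for mult in (0.6, 0.4, 0.2):
            img = np.where(npm, clean * mult, clean)
            mask = suspected_nonperfusion(_frame(img), geom, SegParams())
            if prev is not None:
                assert (prev & ~mask).sum() == 0  # no shrinkage
            prev = mask

    def test_perfused_baseline_tracks_background_inside_lesion(self, pdr_eye):
        base = perfused_baseline(pdr_eye.early, pdr_eye.geometry, SegParams())
        npm = pdr_eye.truth_masks.nonperfusion
        # reference stays near the perfused brightness even inside lesions
        assert np.median(base[npm]) > 2.0 * np.median(pdr_eye.early.image[npm])


class TestPseudoNonperfusion:
    def test_identical_frames_idempotent(self, pdr_eye):
        p = SegParams()
        alone = suspected_nonperfusion(pdr_eye.early, pdr_eye.geometry, p)
        both = pseudo_nonperfusion(pdr_eye.early, pdr_eye.early, pdr_eye.geometry, p)
        np.testing.assert_array_equal(alone, both)

    def test_subset_of_each(self, pdr_eye):
        p = SegParams()
        pm = pseudo_nonperfusion(pdr_eye.early, pdr_eye.early_clean, pdr_eye.geometry, p)
        a = suspected_nonperfusion(pdr_eye.early, pdr_eye.geometry, p)
        b = suspected_nonperfusion(pdr_eye.early_clean, pdr_eye.geometry, p)
        assert not (pm & ~a).any()
        assert not (pm & ~b).any()

    def test_shape_mismatch(self, pdr_eye):
        with pytest.raises(ValueError):
            pseudo_nonperfusion(
                pdr_eye.early, _frame(np.zeros((16, 16))), pdr_eye.geometry, SegParams()
            )


class TestLeakageMask:
    def test_all_zero_difference_empty(self, pdr_eye):
        d = DifferenceImage(values=np.zeros_like(pdr_eye.late.image), phase=Phase.LATE)
        assert not leakage_mask(d, pdr_eye.geometry, SegParams()).any()

    @pytest.mark.parametrize("mode", ["robust", "zscore", "otsu"])
    def test_planted_blob_recovered(self, mode):
        """Oracle-twin difference thresholding finds the planted leakage."""
        eye = generate_eye(
            SceneParams(grade=Grade.NPDR, image_size=128, seed=21,
                        np_area_fraction=0.0, lk_area_fraction=0.04, ma_count=0)
        )
        d = difference_image(eye.late, eye.late_clean)
        mask = leakage_mask(d, eye.geometry, SegParams(leak_threshold_mode=mode))
        assert _iou(mask, eye.truth_masks.leakage) >= 0.5

    def test_subset_of_footprint(self, pdr_eye):
        d = difference_image(pdr_eye.late, pdr_eye.late_clean)
        mask = leakage_mask(d, pdr_eye.geometry, SegParams())
        assert not (mask & ~pdr_eye.geometry.footprint).any()


class TestSegParams:
    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            SegParams(min_filter_size=6)
        with pytest.raises(ValueError):
            SegParams(min_filter_size=15, opening_size=7)
        with pytest.raises(ValueError):
            SegParams(label_smoothing_eps=0.5)

    def test_scaled_keeps_odd_ordering(self):
        p = SegParams().scaled(64)
        assert p.min_filter_size % 2 == 1
        assert p.min_filter_size < p.opening_size


class TestUnet:
    def test_smoothed_targets_values(self):
        eps = 0.1
        t = np.where(np.array([[True, False]]), 1 - eps, eps)
        assert set(np.unique(t)) == {eps, 1 - eps}

    def test_background_only_label_fits_background(self):
        img = np.random.default_rng(0).random((32, 32)).astype(np.float32)
        frame = _frame(img)
        label = np.zeros((32, 32), dtype=bool)
        params = SegParams(label_smoothing_eps=0.0, unet_epochs=30, unet_base=4,
                           unet_ensemble=1, min_filter_size=3, opening_size=5)
        model = train_np_unet([frame] * 4, [label] * 4, params, seed=0)
        proba = model.predict_proba(frame)
        assert (proba > 0.5).mean() < 0.05

    def test_training_determinism(self):
        eyes = generate_dataset(0, 3, 3, seed=13, image_size=64)
        frames = [e.early for e in eyes]
        params = SegParams(unet_epochs=3, unet_ensemble=1).scaled(64)
        labels = [suspected_nonperfusion(e.early, e.geometry, params) for e in eyes]
        m1 = train_np_unet(frames, labels, params, seed=4)
        m2 = train_np_unet(frames, labels, params, seed=4)
        assert m1.loss_trace == m2.loss_trace

    def test_refinement_tracks_rule_based_masks(self):
        """Pseudo-supervised refinement stays in the quality regime of its
        rule-based teacher on held-out eyes (the tiny U-net cannot match the
        near-perfect teacher exactly)."""
        eyes = generate_dataset(5, 5, 5, seed=13, image_size=128)
        params = SegParams(unet_ensemble=1)
        frames = [e.early for e in eyes]
        labels = [suspected_nonperfusion(e.early, e.geometry, params) for e in eyes]
        model = train_np_unet(frames, labels, params, seed=5)
        held = generate_dataset(2, 2, 2, seed=99, image_size=128)
        iou_ref, iou_rule = [], []
        for e in held:
            refined = segment_nonperfusion(model, e.early, e.geometry)
            assert refined.provenance is Provenance.REFINED
            assert not (refined.nonperfusion & ~e.geometry.footprint).any()
            rule = suspected_nonperfusion(e.early, e.geometry, params)
            iou_ref.append(_iou(refined.nonperfusion, e.truth_masks.nonperfusion))
            iou_rule.append(_iou(rule, e.truth_masks.nonperfusion))
        assert np.mean(iou_ref) >= 0.75
        assert np.mean(iou_ref) >= np.mean(iou_rule) - 0.25

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_np_unet([], [], SegParams(), seed=0)
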