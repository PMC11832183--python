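"""Filter bank, random-forest voxel classification and threshold baseline."""

import numpy as np
import pytest

import netquant3d as nq
from netquant3d.segmentation import (
    FeatureBankSpec,
    PixelClassifier,
    ThresholdResult,
    apply_classifier,
    compute_features,
    fixed_threshold_area,
    train_classifier,
)


def _stack(arr, spacing=(1.0, 1.0, 1.0)):
    return nq.CalibratedStack(np.asarray(arr, dtype=np.uint8), spacing=spacing)


class TestFeatureBank:
    def test_constant_image_features(self):
        stack = _stack(np.full((8, 8, 8), 57))
        bank = FeatureBankSpec(
            sigmas_um=(1.0, 2.0),
            features=("gaussian", "difference_of_gaussians", "gradient_magnitude",
                      "laplacian"),
        )
        feats, names = compute_features(stack, bank)
        for j, name in enumerate(names):
            col = feats[:, j]
            if name.startswith("gaussian"):
                np.testing.assert_allclose(col, 57.0, atol=1e-3)
            else:
                np.testing.assert_allclose(col, 0.0, atol=1e-3)

    def test_identity_feature_equals_raw(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 256, size=(6, 10, 10), dtype=np.uint8)
        stack = _stack(arr)
        feats, names = compute_features(
            stack, FeatureBankSpec(sigmas_um=(1.0,), features=("identity", "gaussian"))
        )
        assert names[0] == "identity"
        np.testing.assert_array_equal(feats[:, 0], arr.ravel().astype(np.float32))

    def test_gaussian_semigroup(self):
        """Smoothing at s1 then s2 approximates one pass at sqrt(s1^2+s2^2)."""
        rng = np.random.default_rng(7)
        arr = rng.integers(0, 256, size=(32, 32, 32), dtype=np.uint8)
        s1, s2 = 2.0, 3.0
        stack = _stack(arr)
        bank1 = FeatureBankSpec(sigmas_um=(s1,), features=("gaussian",))
        f1, _ = compute_features(stack, bank1)
        inner = nq.CalibratedStack(
            f1[:, 0].reshape(arr.shape), spacing=(1, 1, 1), bit_depth=16
        )
        bank2 = FeatureBankSpec(sigmas_um=(s2,), features=("gaussian",))
        f12, _ = compute_features(inner, bank2)
        bank12 = FeatureBankSpec(
            sigmas_um=(np.hypot(s1, s2),), features=("gaussian",)
        )
        fdirect, _ = compute_features(stack, bank12)
        # compare away from the borders (boundary conditions differ slightly)
        core = np.zeros(arr.shape, dtype=bool)
        core[8:-8, 8:-8, 8:-8] = True
        a = f12[:, 0].reshape(arr.shape)[core]
        b = fdirect[:, 0].reshape(arr.shape)[core]
        assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-3

    def test_sigma_below_half_voxel_rejected(self):
        stack = _stack(np.zeros((4, 8, 8)), spacing=(15.0, 1.0, 1.0))
        bank = FeatureBankSpec(sigmas_um=(2.0,), features=("gaussian",))
        with pytest.raises(ValueError, match="axis z"):
            compute_features(stack, bank)
        # the per-slice 2D bank ignores the z spacing
        bank2d = FeatureBankSpec(sigmas_um=(2.0,), features=("gaussian",), use_3d=False)
        feats, _ = compute_features(stack, bank2d)
        assert feats.shape[0] == stack.voxels.size

    @pytest.mark.parametrize(
        "bad", [{"sigmas_um": (2.0, 1.0)}, {"sigmas_um": (0.0,)}, {"features": ()}]
    )
    def test_invalid_bank_rejected(self, bad):
        with pytest.raises(ValueError):
            FeatureBankSpec(**bad)


class TestTrainApply:
    def test_separable_fixture_heldout_accuracy(self, separable_fixture):
        stack, _, train_ann, held_out = separable_fixture
        clf = train_classifier(stack, train_ann, seed=42)
        assert clf.training_accuracy >= 0.9
        mask = apply_classifier(stack, clf)
        pred = mask.voxels[tuple(held_out.coordinates.T)]
        acc = float((pred == held_out.labels).mean())
        assert acc > 0.95

    def test_self_consistency_on_training_voxels(self, separable_fixture):
        stack, _, train_ann, _ = separable_fixture
        clf = train_classifier(stack, train_ann, seed=42)
        mask = apply_classifier(stack, clf)
        pred = mask.voxels[tuple(train_ann.coordinates.T)]
        assert float((pred == train_ann.labels).mean()) >= 0.9

    def test_more_correct_labels_never_hurt_much(self, separable_fixture):
        """Held-out accuracy with richer annotation stays within 0.05 of the
        minimal 2-labels-per-class baseline."""
        stack, _, train_ann, held_out = separable_fixture

        def heldout_acc(n_per_class):
            fg_idx = np.flatnonzero(train_ann.labels == 1)[:n_per_class]
            bg_idx = np.flatnonzero(train_ann.labels == 0)[:n_per_class]
            sel = np.concatenate([fg_idx, bg_idx])
            ann = nq.TrainingAnnotation(
                coordinates=train_ann.coordinates[sel], labels=train_ann.labels[sel]
            )
            clf = train_classifier(stack, ann, seed=42)
            mask = apply_classifier(stack, clf)
            pred = mask.voxels[tuple(held_out.coordinates.T)]
            return float((pred == held_out.labels).mean())

        baseline = heldout_acc(2)
        for n in (20, 200):
            assert heldout_acc(n) >= baseline - 0.05

    def test_conflicting_labels_posterior_near_half(self):
        stack = _stack(np.full((4, 8, 8), 100))
        coords = np.argwhere(np.ones((4, 8, 8), dtype=bool))[:100]
        labels = np.array([1, 0] * 50)
        ann = nq.TrainingAnnotation(coordinates=coords, labels=labels)
        clf = train_classifier(
            stack, ann,
            bank=FeatureBankSpec(sigmas_um=(1.0,), features=("identity",)),
            seed=0,
        )
        from netquant3d.segmentation import predict_proba

        proba = predict_proba(stack, clf)
        assert abs(float(proba.mean()) - 0.5) < 0.1

    def test_single_class_annotation_rejected(self, separable_fixture):
        stack, _, train_ann, _ = separable_fixture
        fg_only = np.flatnonzero(train_ann.labels == 1)
        ann = nq.TrainingAnnotation(
            coordinates=train_ann.coordinates[fg_only],
            labels=train_ann.labels[fg_only],
        )
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(stack, ann)

    def test_save_load_identical_predictions(self, separable_fixture, tmp_path):
        stack, _, train_ann, _ = separable_fixture
        clf = train_classifier(stack, train_ann, seed=42)
        before = apply_classifier(stack, clf).voxels
        path = clf.save(tmp_path / "clf.joblib")
        loaded = PixelClassifier.load(path)
        after = apply_classifier(stack, loaded).voxels
        assert np.array_equal(before, after)

    def test_load_with_mismatched_bank_rejected(self, separable_fixture, tmp_path):
        stack, _, train_ann, _ = separable_fixture
        clf = train_classifier(stack, train_ann, seed=42)
        path = clf.save(tmp_path / "clf.joblib")
        other = FeatureBankSpec(sigmas_um=(9.0,), features=("gaussian",))
        with pytest.raises(ValueError, match="bank"):
            PixelClassifier.load(path, expected_bank=other)

    def test_acceleration_toggle_identical_mask(self, separable_fixture):
        stack, _, train_ann, _ = separable_fixture
        clf = train_classifier(stack, train_ann, seed=42)
        plain = apply_classifier(stack, clf, acceleration=False).voxels
        fast = apply_classifier(stack, clf, acceleration=True).voxels
        assert np.array_equal(plain, fast)

    def test_mask_binary_and_aligned(self, separable_fixture):
        stack, _, train_ann, _ = separable_fixture
        clf = train_classifier(stack, train_ann, seed=42)
        mask = apply_classifier(stack, clf)
        assert mask.voxels.shape == stack.grid_shape
        assert set(np.unique(mask.voxels)) <= {0, 1}


class TestPhantomSegmentation:
    def test_tube_phantom_dice_overlap(self, small_phantom):
        spec, truth, stack, mask = small_phantom
        from netquant3d.phantoms import annotation_from_truth

        ann = annotation_from_truth(mask, spec.radius_um, seed=1)
        clf = train_classifier(stack, ann, seed=42)
        pred = apply_classifier(stack, clf)
        inter = int((pred.binary & mask.binary).sum())
        dice = 2 * inter / (int(pred.binary.sum()) + int(mask.binary.sum()))
        assert dice > 0.8

    def test_background_only_phantom_near_empty(self, small_phantom):
        spec, truth, stack, mask = small_phantom
        from netquant3d.phantoms import annotation_from_truth

        ann = annotation_from_truth(mask, spec.radius_um, seed=1)
        clf = train_classifier(stack, ann, seed=42)
        blank_spec = nq.PhantomSpec(
            shape=spec.shape, spacing=spec.spacing, n_tubes=0, seed=7
        )
        blank_truth = nq.grow_network(blank_spec)
        blank, _ = nq.rasterize(blank_truth, blank_spec)
        pred = apply_classifier(blank, clf)
        assert float(pred.binary.mean()) < 0.01


class TestFixedThreshold:
    def test_strictly_greater_at_threshold(self):
        stack = _stack(np.full((4, 8, 8), 170))
        assert fixed_threshold_area(stack, 170).count == 0

    def test_all_above(self):
        stack = _stack(np.full((4, 8, 8), 171), spacing=(2.0, 1.5, 1.5))
        res = fixed_threshold_area(stack, 170)
        assert res.count == 4 * 8 * 8
        assert res.area_um2 == pytest.approx(res.count * 1.5 * 1.5)
        assert res.volume_um3 == pytest.approx(res.count * 2.0 * 1.5 * 1.5)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 256, size=(16, 16, 16), dtype=np.uint8)
        stack = _stack(arr)
        threshold = 170
        expected = 0
        for v in arr.ravel():
            if v > threshold:
                expected += 1
        assert fixed_threshold_area(stack, threshold).count == expected

    def test_threshold_out_of_range_rejected(self):
        stack = _stack(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            fixed_threshold_area(stack, 300)
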