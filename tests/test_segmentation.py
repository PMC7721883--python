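"""Projection, features, pixel classifier, hysteresis, post-processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptscape.core_io import Image2D, SHGImageStack
from cryptscape.segmentation import (
    LABEL_COLLAGEN,
    LABEL_CRYPT,
    PixelClassifier,
    ProbabilityMap,
    _Stage,
    compute_features,
    hysteresis_segment,
    max_project,
    postprocess_labels,
    predict_probability,
    train_pixel_classifier,
)
from tests.conftest import sparse_training_labels


def hysteresis_oracle(probs, low, high):
    """Flood fill from every seed (> high) through > low, 8-connected."""
    selected = np.zeros(probs.shape, dtype=bool)
    passable = probs > low
    stack = list(zip(*np.nonzero(probs > high)))
    while stack:
        r, c = stack.pop()
        if selected[r, c]:
            continue
        selected[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < probs.shape[0]
                    and 0 <= cc < probs.shape[1]
                    and passable[rr, cc]
                    and not selected[rr, cc]
                ):
                    stack.append((rr, cc))
    return selected


class TestMaxProject:
    def test_single_slice_is_identity(self):
        stack = SHGImageStack(
            voxels=np.arange(16, dtype=float).reshape(1, 4, 4),
            pixel_size_um=0.5,
        )
        out = max_project(stack)
        assert np.array_equal(out.pixels, stack.voxels[0])
        assert out.pixel_size_um == 0.5

    def test_small_example(self):
        stack = SHGImageStack(
            voxels=np.array([[[1.0, 5.0]], [[3.0, 2.0]]]), pixel_size_um=1.0
        )
        assert np.array_equal(max_project(stack).pixels, [[3.0, 5.0]])

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        vox = rng.random((3, 4, 4))
        out = max_project(SHGImageStack(voxels=vox, pixel_size_um=1.0))
        for r in range(4):
            for c in range(4):
                assert out.pixels[r, c] == max(vox[z, r, c] for z in range(3))


class TestFeatures:
    def test_constant_image(self):
        img = Image2D(pixels=np.full((16, 16), 7.0), pixel_size_um=1.0)
        feats = compute_features(img, scales=(1.0, 2.0))
        smooth = feats[..., [0, 3]]
        grad = feats[..., [1, 4]]
        var = feats[..., [2, 5]]
        assert np.allclose(smooth, 7.0)
        assert np.allclose(grad, 0.0)
        assert np.allclose(var, 0.0, atol=1e-9)

    def test_tiny_scale_approximates_raw_intensity(self):
        rng = np.random.default_rng(1)
        img = Image2D(pixels=rng.random((12, 12)), pixel_size_um=1.0)
        feats = compute_features(img, scales=(0.05,))
        assert np.allclose(feats[..., 0], img.pixels, atol=1e-3)

    def test_gradient_peaks_at_step_edge(self):
        pixels = np.zeros((16, 16))
        pixels[:, 8:] = 100.0
        img = Image2D(pixels=pixels, pixel_size_um=1.0)
        grad = compute_features(img, scales=(1.0,))[..., 1]
        # finite-difference oracle: the raw |d/dcol| peaks between cols 7/8
        assert grad[8].argmax() in (7, 8)

    def test_empty_scales_rejected(self):
        img = Image2D(pixels=np.zeros((4, 4)), pixel_size_um=1.0)
        with pytest.raises(ValueError):
            compute_features(img, scales=())


class TestClassifier:
    def test_linearly_separable_training_is_perfect(self):
        # two flat intensity plateaus: trivially separable by the
        # smoothed-intensity feature
        pixels = np.full((20, 20), 30.0)
        pixels[:, 10:] = 200.0
        img = Image2D(pixels=pixels, pixel_size_um=1.0)
        masks = np.zeros((20, 20), dtype=int)
        masks[:, :4] = LABEL_CRYPT
        masks[:, 16:] = LABEL_COLLAGEN
        clf = train_pixel_classifier([img], [masks], n_stages=1)
        probs = predict_probability(clf, img).probs
        assert (probs[:, :4] > 0.5).all()
        assert (probs[:, 16:] < 0.5).all()

    def test_one_class_only_is_an_error(self):
        img = Image2D(pixels=np.zeros((8, 8)), pixel_size_um=1.0)
        masks = np.zeros((8, 8), dtype=int)
        masks[0, 0] = LABEL_CRYPT
        with pytest.raises(ValueError, match="one class"):
            train_pixel_classifier([img], [masks])

    def test_empty_masks_are_an_error(self):
        img = Image2D(pixels=np.zeros((8, 8)), pixel_size_um=1.0)
        with pytest.raises(ValueError, match="empty"):
            train_pixel_classifier([img], [np.zeros((8, 8), dtype=int)])

    def test_heldout_accuracy_on_noisy_mosaic(self, small_mosaic, trained_classifier):
        img, truth = small_mosaic
        probs = predict_probability(trained_classifier, img).probs
        lumen = truth.label_map.labels > 0
        accuracy = ((probs > 0.5) == lumen).mean()
        assert accuracy >= 0.95

    def test_autocontext_stage_does_not_hurt(self, small_mosaic):
        img, truth = small_mosaic
        rng = np.random.default_rng(13)
        masks = sparse_training_labels(truth.label_map.labels, rng)
        lumen = truth.label_map.labels > 0
        accs = {}
        for n_stages in (1, 2):
            clf = train_pixel_classifier(
                [img], [masks], n_stages=n_stages, seed=0
            )
            probs = predict_probability(clf, img).probs
            accs[n_stages] = ((probs > 0.5) == lumen).mean()
        assert accs[2] >= accs[1] - 0.002  # context must not degrade

    def test_zero_weight_classifier_gives_uniform_half(self):
        clf = PixelClassifier(scales=(1.0,))
        clf.stages.append(
            _Stage(
                weights=np.zeros(3),
                bias=0.0,
                feat_mean=np.zeros(3),
                feat_std=np.ones(3),
            )
        )
        img = Image2D(pixels=np.random.default_rng(0).random((6, 6)), pixel_size_um=1.0)
        assert np.allclose(predict_probability(clf, img).probs, 0.5)

    def test_prediction_matches_sigmoid_formula(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=3)
        b = 0.3
        clf = PixelClassifier(scales=(1.0,))
        clf.stages.append(
            _Stage(weights=w, bias=b, feat_mean=np.zeros(3), feat_std=np.ones(3))
        )
        img = Image2D(pixels=rng.random((8, 8)), pixel_size_um=1.0)
        feats = compute_features(img, scales=(1.0,))
        expected = 1.0 / (1.0 + np.exp(-(feats @ w + b)))
        assert np.allclose(predict_probability(clf, img).probs, expected)

    def test_json_serialization_roundtrip(self, trained_classifier, tmp_path, small_mosaic):
        img, _ = small_mosaic
        path = tmp_path / "clf.json"
        trained_classifier.to_json(path)
        back = PixelClassifier.from_json(path)
        p1 = predict_probability(trained_classifier, img).probs
        p2 = predict_probability(back, img).probs
        assert np.allclose(p1, p2)


class TestHysteresis:
    def test_all_above_high_selects_everything(self):
        probs = np.full((5, 5), 0.9)
        assert hysteresis_segment(probs, 0.5, 0.8).all()

    def test_no_seed_selects_nothing(self):
        probs = np.full((5, 5), 0.7)
        assert not hysteresis_segment(probs, 0.5, 0.8).any()

    def test_row_example_two_components(self):
        probs = np.array([[0.9, 0.6, 0.4, 0.6, 0.9]])
        mask = hysteresis_segment(probs, 0.5, 0.8)
        assert mask.tolist() == [[True, True, False, True, True]]

    def test_diagonal_connectivity_is_eight(self):
        probs = np.array([[0.9, 0.0], [0.0, 0.6]])
        assert hysteresis_segment(probs, 0.5, 0.8)[1, 1]
        assert not hysteresis_segment(probs, 0.5, 0.8, connectivity=4)[1, 1]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random((32, 32))
        low, high = sorted(rng.uniform(0.1, 0.9, size=2))
        mask = hysteresis_segment(probs, low, high)
        assert np.array_equal(mask, hysteresis_oracle(probs, low, high))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_sandwich_and_seed_invariants(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random((24, 24))
        low, high = sorted(rng.uniform(0.0, 1.0, size=2))
        mask = hysteresis_segment(probs, low, high)
        assert not (mask & ~(probs > low)).any()  # output within low mask
        assert ((probs > high) & ~mask).sum() == 0  # contains all seeds
        # every component of the output holds at least one seed
        from scipy import ndimage as ndi

        comp, n = ndi.label(mask, structure=np.ones((3, 3)))
        for k in range(1, n + 1):
            assert (probs[comp == k] > high).any()


class TestPostprocess:
    def test_size_filter_boundary_at_300_um2(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[2:19, 2:19] = True  # 17x17 = 289 um^2 at 1 um/px
        mask[25:43, 25:43] = True  # 18x18 = 324 um^2
        out = postprocess_labels(mask, pixel_size_um=1.0, min_area_um2=300.0)
        assert out.n_labels == 1
        assert (out.labels[25:43, 25:43] == 1).all()
        assert not out.labels[2:19, 2:19].any()

    def test_ring_hole_filled_before_size_test(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        mask[10:20, 10:20] = False  # 20x20 ring with 10x10 hole
        out = postprocess_labels(mask, pixel_size_um=1.0)
        assert out.n_labels == 1
        assert (out.labels == 1).sum() == 400  # hole counted as filled

    def test_hole_bounded_by_two_labels_stays_open(self):
        from cryptscape.segmentation import fill_single_object_holes

        labels = np.array(
            [
                [1, 1, 1, 1],
                [1, 0, 0, 1],
                [2, 0, 0, 2],
                [2, 2, 2, 2],
            ],
            dtype=np.int32,
        )
        assert np.array_equal(fill_single_object_holes(labels), labels)

    def test_border_object_flagged(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[0:18, 5:23] = True
        out = postprocess_labels(mask, pixel_size_um=1.0)
        assert out.border_flags[1]

    def test_labels_ordered_by_descending_area(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[2:20, 2:20] = True  # 324
        mask[30:55, 30:55] = True  # 625
        out = postprocess_labels(mask, pixel_size_um=1.0)
        assert (out.labels[30:55, 30:55] == 1).all()
        assert (out.labels[2:20, 2:20] == 2).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotent_on_its_own_output(self, seed):
        rng = np.random.default_rng(seed)
        probs = np.random.default_rng(seed).random((48, 48))
        mask = hysteresis_segment(probs, 0.4, 0.7)
        first = postprocess_labels(mask, pixel_size_um=3.0, min_area_um2=50.0)
        again = postprocess_labels(
            first.labels > 0, pixel_size_um=3.0, min_area_um2=50.0
        )
        assert np.array_equal(first.labels, again.labels)
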