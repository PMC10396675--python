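import numpy as np
import pytest

from focalseg.errors import ShapeError, ValidationError
from focalseg.segmentation import (
    SegNetConfig,
    TrainConfig,
    build_network,
    compute_seg_metrics,
    extract_nodule_regions,
    predict_mask,
    train,
)
from focalseg.segmentation.layers import softmax_channels
from focalseg.segmentation.train import nodule_iou, split_slices
from focalseg.synthetic_data import PhantomSpec, generate_slice

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def oracle_convolution(image, kernel):
    """Literal double-loop 2-D convolution (kernel flipped), zero padding."""
    h, w = image.shape
    kh, kw = kernel.shape
    out = np.zeros((h, w))
    for m in range(h):
        for n in range(w):
            acc = 0.0
            for j in range(kh):
                for k in range(kw):
                    r, c = m - (j - kh // 2), n - (k - kw // 2)
                    if 0 <= r < h and 0 <= c < w:
                        acc += kernel[j, k] * image[r, c]
            out[m, n] = acc
    return out


def oracle_pixel_metrics(pred, truth):
    """Per-pixel enumeration of the four pixel metrics over both classes."""
    counts = {c: {"tp": 0, "fp": 0, "fn": 0} for c in (0, 1)}
    correct = 0
    total = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        total += 1
        if p == t:
            correct += 1
        for c in (0, 1):
            if p == c and t == c:
                counts[c]["tp"] += 1
            elif p == c and t != c:
                counts[c]["fp"] += 1
            elif p != c and t == c:
                counts[c]["fn"] += 1
    recalls, ious, freqs = [], [], []
    for c in (0, 1):
        tp, fp, fn = counts[c]["tp"], counts[c]["fp"], counts[c]["fn"]
        if tp + fn > 0:
            recalls.append(tp / (tp + fn))
        if tp + fp + fn > 0:
            ious.append(tp / (tp + fp + fn))
            freqs.append(tp + fn)
    weighted = sum(f * i for f, i in zip(freqs, ious)) / sum(freqs) if sum(freqs) else 0.0
    return {
        "global_accuracy": correct / total,
        "mean_accuracy": float(np.mean(recalls)),
        "mean_iou": float(np.mean(ious)),
        "weighted_iou": weighted,
    }


def oracle_bf_score(pred, truth, tol):
    """Brute-force boundary F1: pairwise distances between boundary sets."""

    def boundary(mask):
        pts = []
        h, w = mask.shape
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc]:
                        pts.append((r, c))
                        break
        return pts

    scores = []
    for cls in (0, 1):
        pb = boundary(pred == cls)
        tb = boundary(truth == cls)
        if not pb and not tb:
            scores.append(1.0)
            continue
        if not pb or not tb:
            scores.append(0.0)
            continue
        prec = np.mean(
            [min(np.hypot(p[0] - t[0], p[1] - t[1]) for t in tb) <= tol for p in pb]
        )
        rec = np.mean(
            [min(np.hypot(p[0] - t[0], p[1] - t[1]) for p in pb) <= tol for t in tb]
        )
        scores.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# network contracts
# ---------------------------------------------------------------------------


class TestNetwork:
    def test_output_shape_and_softmax(self):
        net = build_network(SegNetConfig(input_size=(32, 32, 3), seed=0))
        probs = net.predict_proba(np.zeros((32, 32, 3), dtype=np.uint8))
        assert probs.shape == (1, 32, 32, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("size", [16, 32, 48])
    def test_shape_preserved_any_even_size(self, size, rng):
        net = build_network(SegNetConfig(input_size=(size, size, 3), seed=0))
        x = rng.integers(0, 256, (size, size, 3)).astype(np.uint8)
        logits = net.forward(x)
        assert logits.shape == (1, 2, size, size)

    def test_odd_size_rejected(self):
        with pytest.raises(ShapeError):
            SegNetConfig(input_size=(33, 33, 3))

    def test_untrained_determinism(self, rng):
        x = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        a = build_network(SegNetConfig(input_size=(16, 16, 3), seed=4)).forward(x)
        b = build_network(SegNetConfig(input_size=(16, 16, 3), seed=4)).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_first_conv_matches_convolution_oracle(self, rng):
        """A hand-loaded 3x3 kernel reproduces the double-loop convolution."""
        net = build_network(SegNetConfig(input_size=(4, 4, 3), seed=0))
        image = rng.uniform(-1, 1, (4, 4)).astype(np.float32)
        kernel = rng.uniform(-1, 1, (3, 3)).astype(np.float32)

        conv1 = net.layers[1]
        conv1.w.value[:] = 0.0
        conv1.b.value[:] = 0.0
        # convolution == correlation with the flipped kernel
        conv1.w.value[0, 0] = kernel[::-1, ::-1]
        net.zero_center.set_mean(np.zeros(3))
        net.zero_center.scale = np.float32(1.0)

        x = np.repeat(image[:, :, None], 3, axis=2)
        out = net.layers[1].forward(net.layers[0].forward(net._check_input(x)))
        expected = oracle_convolution(image.astype(float), kernel.astype(float))
        np.testing.assert_allclose(out[0, 0], expected, rtol=1e-4, atol=1e-5)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        from focalseg.segmentation import SegNet

        net = build_network(SegNetConfig(input_size=(16, 16, 3), seed=9))
        net.zero_center.set_mean(np.array([10.0, 10.0, 10.0]))
        net.save(tmp_path / "net.npz")
        loaded = SegNet.load(tmp_path / "net.npz")
        x = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        np.testing.assert_array_equal(net.forward(x), loaded.forward(x))


class TestPredictMask:
    def test_values_binary(self, rng):
        net = build_network(SegNetConfig(input_size=(16, 16, 3), seed=1))
        mask = predict_mask(net, rng.integers(0, 256, (16, 16, 3)).astype(np.uint8))
        assert set(np.unique(mask)) <= {0, 1}

    def test_argmax_and_tie_rule(self):
        probs = np.array([[[0.6, 0.4], [0.5, 0.5]]])  # (1, 2, K)
        labels = probs.argmax(axis=-1)
        assert labels[0, 0] == 0  # higher background prob
        assert labels[0, 1] == 0  # exact tie -> lower index

    def test_softmax_tie_from_equal_logits(self):
        logits = np.zeros((1, 2, 2, 2), dtype=np.float32)
        probs = softmax_channels(logits)
        np.testing.assert_allclose(probs, 0.5)
        assert probs[0].argmax(axis=0).max() == 0


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


class TestSegMetrics:
    def test_perfect_prediction(self, rng):
        truth = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        m = compute_seg_metrics(truth, truth)
        assert m.global_accuracy == m.mean_accuracy == m.mean_iou == 1.0
        assert m.weighted_iou == m.mean_bf_score == 1.0

    def test_complement_prediction(self, rng):
        truth = (rng.random((16, 16)) < 0.5).astype(np.uint8)
        assert truth.any() and not truth.all()
        m = compute_seg_metrics(1 - truth, truth)
        assert m.global_accuracy == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            pred = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            truth = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            m = compute_seg_metrics(pred, truth)
            o = oracle_pixel_metrics(pred, truth)
            assert m.global_accuracy == pytest.approx(o["global_accuracy"])
            assert m.mean_accuracy == pytest.approx(o["mean_accuracy"])
            assert m.mean_iou == pytest.approx(o["mean_iou"])
            assert m.weighted_iou == pytest.approx(o["weighted_iou"])

    def test_bf_score_matches_brute_force(self, rng):
        for _ in range(10):
            pred = (rng.random((12, 12)) < 0.4).astype(np.uint8)
            truth = (rng.random((12, 12)) < 0.4).astype(np.uint8)
            tol = 2.0
            m = compute_seg_metrics(pred, truth, bf_tolerance=tol)
            assert m.mean_bf_score == pytest.approx(oracle_bf_score(pred, truth, tol))

    def test_weighted_iou_bounds(self, rng):
        from focalseg.segmentation.metrics import per_class_iou

        for _ in range(50):
            pred = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            truth = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            m = compute_seg_metrics(pred, truth)
            ious = [v for v in per_class_iou(pred, truth).values() if not np.isnan(v)]
            assert min(ious) - 1e-12 <= m.weighted_iou <= max(ious) + 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            compute_seg_metrics(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_non_binary_rejected(self):
        with pytest.raises(ShapeError):
            compute_seg_metrics(np.full((4, 4), 2), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------


class TestExtractRegions:
    @staticmethod
    def _disc_mask(size, center, radius):
        rr, cc = np.mgrid[0:size, 0:size]
        return (np.hypot(rr - center[0], cc - center[1]) <= radius).astype(np.uint8)

    def test_two_discs_two_regions(self):
        mask = self._disc_mask(64, (16, 16), 5) | self._disc_mask(64, (48, 48), 5)
        image = (mask * 200).astype(np.uint8)
        regions = extract_nodule_regions(image, mask)
        assert len(regions) == 2

    def test_empty_mask_empty_list(self):
        assert extract_nodule_regions(np.zeros((32, 32), np.uint8), np.zeros((32, 32), np.uint8)) == []

    def test_disc_bounding_box_extent(self):
        mask = self._disc_mask(64, (32, 32), 10)
        regions = extract_nodule_regions((mask * 255).astype(np.uint8), mask, pad=0)
        assert len(regions) == 1
        r0, c0, r1, c1 = regions[0].bounding_box
        assert 20 <= r1 - r0 <= 22
        assert 20 <= c1 - c0 <= 22

    def test_min_area_filter(self):
        mask = np.zeros((32, 32), np.uint8)
        mask[4, 4] = 1  # below min_area
        mask[16:22, 16:22] = 1
        regions = extract_nodule_regions((mask * 255).astype(np.uint8), mask, min_area=9)
        assert len(regions) == 1

    def test_output_size_and_binary_mask(self, one_slice):
        regions = extract_nodule_regions(one_slice.image, one_slice.mask, out_size=48)
        for r in regions:
            assert r.crop.shape == (48, 48)
            assert r.crop_mask.shape == (48, 48)
            assert set(np.unique(r.crop_mask)) <= {0, 1}


# ---------------------------------------------------------------------------
# training harness
# ---------------------------------------------------------------------------


def _easy_slices(n, size=48, seed=2):
    spec = PhantomSpec(
        image_size=size,
        n_slices=n,
        nodule_diameter_range_benign=(5.0, 8.0),
        nodule_diameter_range_malignant=(10.0, 16.0),
        benign_fraction=0.6,
        vessel_count=0,
        noise_sigma=0.0,
        seed=seed,
    )
    return [generate_slice(spec, i) for i in range(n)]


class TestTrain:
    def test_split_exact_7_3(self):
        slices = _easy_slices(10)
        tr, te = split_slices(slices, 0.7, seed=0)
        assert len(tr) == 7 and len(te) == 3
        assert sorted(tr + te) == list(range(10))

    def test_split_determinism(self):
        slices = _easy_slices(10)
        assert split_slices(slices, 0.7, seed=3) == split_slices(slices, 0.7, seed=3)

    def test_split_stratified_on_malignant(self):
        slices = _easy_slices(20)
        has_mal = [any(n.label == "malignant" for n in s.nodules) for s in slices]
        tr, te = split_slices(slices, 0.7, seed=1)
        n_mal = sum(has_mal)
        n_mal_train = sum(has_mal[i] for i in tr)
        assert abs(n_mal_train - 0.7 * n_mal) <= 1

    def test_class_absent_error(self):
        slices = _easy_slices(4)
        for s in slices:
            s.mask[:] = 0
        net = build_network(SegNetConfig(input_size=(48, 48, 3), seed=0))
        with pytest.raises(ValidationError, match="nodule"):
            train(net, slices, TrainConfig(epochs=1, seed=0))

    def test_too_few_slices(self):
        net = build_network(SegNetConfig(input_size=(48, 48, 3), seed=0))
        with pytest.raises(ValidationError):
            train(net, _easy_slices(1), TrainConfig(epochs=1))

    def test_learning_improves_iou(self):
        """Held-out nodule IoU strictly increases from the untrained baseline."""
        slices = _easy_slices(12)
        cfg = TrainConfig(epochs=3, learning_rate=0.05, batch_size=4, seed=7)
        net = build_network(SegNetConfig(input_size=(48, 48, 3), seed=7))
        _, te = split_slices(slices, cfg.train_fraction, cfg.seed)
        baseline = nodule_iou(net, [slices[i] for i in te])
        result = train(net, slices, cfg)
        trained = nodule_iou(net, [slices[i] for i in te])
        assert trained > baseline
        assert len(result.history) == 3
        assert result.val_metrics is not None

    def test_train_fraction_validation(self):
        with pytest.raises(ValidationError):
            TrainConfig(train_fraction=1.3)
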