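import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfdiff.fixtures import FiberModel, ShapeSpec, make_fibers, make_shape, \
    render_micrograph, SyntheticPair
from sfdiff.segmentation import (
    AugmentConfig,
    SegTrainConfig,
    augment,
    dilate_for_eval,
    seg_metrics,
    segment,
    train_segmenter,
)


def _brute_dilate(b, k):
    h, w = b.shape
    out = np.zeros_like(b)
    lo, hi = k // 2, k - k // 2 - 1
    for y in range(h):
        for x in range(w):
            y0, y1 = max(y - lo, 0), min(y + hi, h - 1)
            x0, x1 = max(x - lo, 0), min(x + hi, w - 1)
            if b[y0:y1 + 1, x0:x1 + 1].any():
                out[y0:y1 + 1, x0:x1 + 1] = True
    return out


def _toy_labelled_set(n=8, side=64, seed=0):
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n):
        cell = make_shape(ShapeSpec(kind="ellipse",
                                    aspect_ratio=1 + 2 * rng.random(),
                                    area=1800.0, resolution=side,
                                    pixel_size=2.2, seed=i,
                                    orientation=rng.uniform(0, np.pi)))
        img, segs = make_fibers(cell, FiberModel(n_fibers=8, seed=i,
                                                 length_range=(8, 20)))
        raw = render_micrograph(SyntheticPair(cell, img, segs), seed=i)
        images.append(np.asarray(raw.data))
        labels.append((np.asarray(img.data) >= 128).astype(np.uint8))
    return images, labels


class TestAugment:
    def test_output_count_scales_variants(self):
        images, labels = _toy_labelled_set(n=5)
        cfg = AugmentConfig(variants_per_image=8, seed=0)
        out_i, out_l = augment(images, labels, cfg)
        assert len(out_i) == len(out_l) == 40

    def test_default_expansion_ratio_is_forty(self):
        # 50 originals at the default config expand to 2000
        assert AugmentConfig().variants_per_image * 50 == 2000

    def test_identity_mosaic(self):
        images, labels = _toy_labelled_set(n=3)
        cfg = AugmentConfig(variants_per_image=1, blur_prob=0,
                            mean_filter_prob=0, noise_prob=0, jitter_prob=0,
                            rotations=(0,), flip=False, shuffle_pieces=False)
        out_i, out_l = augment(images, labels, cfg)
        for src, rec in zip(images, out_i):
            assert np.allclose(src, rec)
        for src, rec in zip(labels, out_l):
            assert np.allclose(src, rec)

    def test_seeded_determinism(self):
        images, labels = _toy_labelled_set(n=4)
        cfg = AugmentConfig(variants_per_image=3, seed=9)
        a = augment(images, labels, cfg)
        b = augment(images, labels, cfg)
        for x, y in zip(a[0], b[0]):
            assert np.array_equal(x, y)

    def test_geometric_transforms_preserve_metrics(self):
        """Rotating/flipping prediction and truth together leaves the pixel
        metrics unchanged."""
        rng = np.random.default_rng(0)
        pred = rng.random((32, 32)) > 0.8
        truth = rng.random((32, 32)) > 0.8
        base = seg_metrics(pred, truth)
        for k in (1, 2, 3):
            m = seg_metrics(np.rot90(pred, k), np.rot90(truth, k))
            assert (m.tp, m.fp, m.tn, m.fn) == (base.tp, base.fp,
                                                base.tn, base.fn)
        m = seg_metrics(pred[:, ::-1], truth[:, ::-1])
        assert m.accuracy == base.accuracy

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment([np.zeros((8, 8))], [np.zeros((6, 6))])


@pytest.fixture(scope="module")
def trained():
    images, labels = _toy_labelled_set(n=14)
    cfg = SegTrainConfig(epochs=6, batch_size=4, learning_rate=3e-3,
                         pixels_per_image=512, seed=0)
    model = train_segmenter((images[:12], labels[:12]), cfg)
    return model, images, labels, cfg


class TestTrainSegmenter:

    def test_loss_decreases(self, trained):
        model, *_ = trained
        assert model.loss_history[-1] < model.loss_history[0]

    def test_heldout_pixel_accuracy(self, trained):
        model, images, labels, _ = trained
        accs = []
        for img, lab in zip(images[12:], labels[12:]):
            binary = segment(img, model).data
            accs.append(np.mean(binary == lab.astype(bool)))
        assert np.mean(accs) >= 0.85

    def test_seeded_loss_trajectory_reproducible(self, trained):
        model, images, labels, cfg = trained
        again = train_segmenter((images[:12], labels[:12]), cfg)
        assert np.allclose(model.loss_history, again.loss_history)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter(([np.zeros((16, 16))],
                             [np.full((16, 16), 0.5)]),
                            SegTrainConfig(epochs=1))


class TestSegmentOperation:
    class _Const:
        def __init__(self, value):
            self.value = value
            self.resolution = None

        def predict_gray(self, image):
            return np.full(np.asarray(image).shape, self.value, np.uint8)

    def test_constant_zero_gives_empty_mask(self):
        out = segment(np.zeros((32, 32)), self._Const(0))
        assert not out.data.any()

    def test_threshold_boundary_is_inclusive(self):
        # grayscale exactly 128 counts as foreground (>= threshold)
        out = segment(np.zeros((16, 16)), self._Const(128))
        assert out.data.all()


class TestDilateForEval:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        b = rng.random((40, 40)) > 0.97
        for k in (5, 8):
            assert np.array_equal(dilate_for_eval(b, k).data,
                                  _brute_dilate(b, k))

    def test_isolated_pixel_becomes_15_square(self):
        b = np.zeros((41, 41), bool)
        b[20, 20] = True
        out = dilate_for_eval(b, 8).data
        ys, xs = np.nonzero(out)
        assert (np.ptp(ys) + 1, np.ptp(xs) + 1) == (15, 15)
        assert out.sum() == 15 * 15

    def test_thin_line_becomes_band(self):
        b = np.zeros((40, 60), bool)
        b[20, 5:55] = True
        out = dilate_for_eval(b, 8).data
        widths = out[:, 30].sum()
        assert widths == 15  # (2k-1) support of the sliding 8x8 window
        assert np.array_equal(out, _brute_dilate(b, 8))

    def test_empty_extensive_monotone(self):
        empty = np.zeros((20, 20), bool)
        assert not dilate_for_eval(empty).data.any()
        rng = np.random.default_rng(0)
        a = rng.random((30, 30)) > 0.9
        b = a | (rng.random((30, 30)) > 0.9)
        da = dilate_for_eval(a).data
        db = dilate_for_eval(b).data
        assert np.all(da >= a)          # extensive
        assert np.all(db >= da)         # monotone


class TestSegMetrics:
    def test_perfect_and_inverted(self):
        rng = np.random.default_rng(0)
        t = rng.random((16, 16)) > 0.5
        m = seg_metrics(t, t)
        assert (m.accuracy, m.fnr, m.fpr) == (1.0, 0.0, 0.0)
        m = seg_metrics(~t, t)
        assert (m.accuracy, m.fnr, m.fpr) == (0.0, 1.0, 1.0)

    def test_hand_enumerated_grid(self):
        # 4x4 with TP=3, FN=1, FP=2, TN=10
        truth = np.zeros((4, 4), bool)
        pred = np.zeros((4, 4), bool)
        truth[0, :4] = True               # 4 positives
        pred[0, :3] = True                # 3 of them hit -> TP=3, FN=1
        pred[1, :2] = True                # 2 false alarms
        m = seg_metrics(pred, truth)
        assert (m.tp, m.fn, m.fp, m.tn) == (3, 1, 2, 10)
        assert m.accuracy == pytest.approx(13 / 16)
        assert m.fnr == pytest.approx(0.25)
        assert m.fpr == pytest.approx(1 / 6)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_counts_partition_pixels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((12, 12)) > rng.random()
        t = rng.random((12, 12)) > rng.random()
        m = seg_metrics(p, t)
        assert m.tp + m.fp + m.tn + m.fn == 144

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg_metrics(np.zeros((4, 4)), np.zeros((5, 5)))
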