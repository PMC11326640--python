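"""Stress-fiber segmentation: mosaic augmentation, a trainable per-pixel
segmenter, kernel-dilated evaluation and pixel metrics.

Hand-labelled SF images are scarce, so the augmentation stage cuts each
labelled image into four quarters and recombines random quarters into new
mosaics, applying photometric jitter (blur/mean filter, additive noise,
contrast/brightness) to image pieces only and geometric transforms
(right-angle rotations, flips) to image and label jointly.

Evaluation follows the kernel protocol: both prediction and truth are
converted from thin lines to typical fiber width with a sliding k x k
window (any SF pixel in the window sets the whole covered window), then
compared pixel-wise via accuracy, FNR = FN/(TP+FN) and FPR = FP/(FP+TN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter, uniform_filter
from skimage.transform import resize

from .core import ImageGrid, as_array
from .nn import MLP, Adam, patch_offsets, sample_patches

__all__ = [
    "AugmentConfig",
    "SegTrainConfig",
    "SegMetrics",
    "SegmenterModel",
    "augment",
    "train_segmenter",
    "segment",
    "dilate_for_eval",
    "seg_metrics",
]


@dataclass
class AugmentConfig:
    pieces_per_image: int = 4
    variants_per_image: int = 40
    blur_prob: float = 0.3
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    mean_filter_prob: float = 0.2
    mean_filter_size: int = 3
    noise_prob: float = 0.5
    noise_sigma_range: tuple[float, float] = (0.0, 10.0)
    jitter_prob: float = 0.5
    contrast_range: tuple[float, float] = (0.8, 1.2)
    brightness_range: tuple[float, float] = (-20.0, 20.0)
    rotations: tuple[int, ...] = (0, 90, 180, 270)
    flip: bool = True
    shuffle_pieces: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.blur_prob, self.mean_filter_prob, self.noise_prob,
                  self.jitter_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pieces_per_image != 4:
            raise ValueError("mosaic augmentation uses quarter pieces (4)")


@dataclass
class SegTrainConfig:
    epochs: int = 50
    batch_size: int = 4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    learning_rate: float = 2.0e-4
    input_resolution: int = 512
    patch_size: int = 9
    hidden: tuple[int, ...] = (48, 48)
    pixels_per_image: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.input_resolution,
               self.patch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("training parameters must be positive")


@dataclass
class SegMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.tn + self.fp + self.fn, 1)

    @property
    def fnr(self) -> float:
        return self.fn / max(self.tp + self.fn, 1)

    @property
    def fpr(self) -> float:
        return self.fp / max(self.fp + self.tn, 1)


# ---------------------------------------------------------------------------
# augmentation


def _quarters(img: np.ndarray) -> list[np.ndarray]:
    h, w = img.shape
    h2, w2 = h // 2, w // 2
    return [img[:h2, :w2], img[:h2, w2 : 2 * w2],
            img[h2 : 2 * h2, :w2], img[h2 : 2 * h2, w2 : 2 * w2]]


def _assemble(pieces: list[np.ndarray]) -> np.ndarray:
    top = np.hstack([pieces[0], pieces[1]])
    bot = np.hstack([pieces[2], pieces[3]])
    return np.vstack([top, bot])


def augment(images, labels, cfg: AugmentConfig | None = None):
    """Mosaic augmentation; returns (aug_images, aug_labels) lists.

    Output count is ``len(images) * variants_per_image`` (50 inputs at the
    default 40 variants yield 2000).  Labels receive only the geometric
    transforms.
    """
    cfg = cfg or AugmentConfig()
    images = [as_array(im).astype(float) for im in images]
    labels = [as_array(lb).astype(float) for lb in labels]
    if len(images) != len(labels) or not images:
        raise ValueError("images and labels must be aligned and non-empty")
    for im, lb in zip(images, labels):
        if im.shape != lb.shape:
            raise ValueError("image/label size mismatch")
        if im.shape != images[0].shape:
            raise ValueError("all inputs must share one shape")
    rng = np.random.default_rng(cfg.seed)
    img_quarters = [_quarters(im) for im in images]
    lab_quarters = [_quarters(lb) for lb in labels]
    n = len(images)
    out_images, out_labels = [], []
    for src in range(n):
        for _ in range(cfg.variants_per_image):
            im_pieces, lb_pieces = [], []
            for q in range(4):
                if cfg.shuffle_pieces:
                    i, j = int(rng.integers(n)), int(rng.integers(4))
                else:
                    i, j = src, q
                piece = img_quarters[i][j].copy()
                lab = lab_quarters[i][j].copy()
                # (i) defocus
                if rng.random() < cfg.blur_prob:
                    piece = gaussian_filter(piece, rng.uniform(*cfg.blur_sigma_range))
                if rng.random() < cfg.mean_filter_prob:
                    piece = uniform_filter(piece, cfg.mean_filter_size)
                # (ii) sensor noise
                if rng.random() < cfg.noise_prob:
                    piece = piece + rng.normal(
                        0.0, rng.uniform(*cfg.noise_sigma_range), piece.shape
                    )
                # (iii) exposure jitter
                if rng.random() < cfg.jitter_prob:
                    piece = piece * rng.uniform(*cfg.contrast_range) + rng.uniform(
                        *cfg.brightness_range
                    )
                piece = np.clip(piece, 0.0, 255.0)
                # (iv) geometric, applied jointly
                k = int(rng.choice(cfg.rotations)) // 90
                piece, lab = np.rot90(piece, k), np.rot90(lab, k)
                if cfg.flip and rng.random() < 0.5:
                    piece, lab = piece[:, ::-1], lab[:, ::-1]
                if cfg.flip and rng.random() < 0.5:
                    piece, lab = piece[::-1], lab[::-1]
                im_pieces.append(piece)
                lb_pieces.append(lab)
            out_images.append(_assemble(im_pieces))
            out_labels.append(_assemble(lb_pieces))
    return out_images, out_labels


# ---------------------------------------------------------------------------
# segmenter


@dataclass
class SegmenterModel:
    """Per-pixel fiber classifier over local patches."""

    mlp: MLP
    patch_size: int
    resolution: int | None
    loss_history: list[float] = field(default_factory=list)
    seed: int = 0

    def predict_proba(self, image) -> np.ndarray:
        img = as_array(image).astype(float) / 255.0
        h, w = img.shape
        ys, xs = np.mgrid[0:h, 0:w]
        centers = np.column_stack([ys.ravel(), xs.ravel()]).astype(float)
        feats = sample_patches(img, centers, patch_offsets(self.patch_size))
        return self.mlp.forward(feats).reshape(h, w)

    def predict_gray(self, image) -> np.ndarray:
        """8-bit grayscale output map (0..255)."""
        return np.clip(np.round(self.predict_proba(image) * 255), 0, 255).astype(
            np.uint8
        )


def _check_binary(label: np.ndarray) -> np.ndarray:
    vals = np.unique(label)
    if np.all(np.isin(vals, (0, 1))):
        return label.astype(float)
    if np.all(np.isin(vals, (0, 255))):
        return (label > 0).astype(float)
    raise ValueError("labels must be binary (0/1 or 0/255)")


def train_segmenter(dataset, cfg: SegTrainConfig | None = None) -> SegmenterModel:
    """Train the per-pixel segmenter with binary cross-entropy and Adam.

    ``dataset`` is a (images, labels) pair of aligned lists.  The loss
    trajectory (per-epoch mean BCE) is logged on the returned model and is
    deterministic for a fixed seed and dataset.
    """
    cfg = cfg or SegTrainConfig()
    images, labels = dataset
    if len(images) == 0:
        raise ValueError("empty dataset")
    imgs = [as_array(im).astype(float) / 255.0 for im in images]
    labs = [_check_binary(as_array(lb)) for lb in labels]
    rng = np.random.default_rng(cfg.seed)
    k = cfg.patch_size
    sizes = [k * k, *cfg.hidden, 1]
    mlp = MLP(sizes, rng, out="sigmoid")
    opt = Adam(mlp.params, lr=cfg.learning_rate, beta1=cfg.adam_beta1,
               beta2=cfg.adam_beta2)
    offs = patch_offsets(k)
    model = SegmenterModel(mlp=mlp, patch_size=k, resolution=None, seed=cfg.seed)
    n = len(imgs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            X_list, t_list = [], []
            for idx in order[start : start + cfg.batch_size]:
                img, lab = imgs[idx], labs[idx]
                h, w = img.shape
                ys = rng.integers(0, h, cfg.pixels_per_image)
                xs = rng.integers(0, w, cfg.pixels_per_image)
                centers = np.column_stack([ys, xs]).astype(float)
                X_list.append(sample_patches(img, centers, offs))
                t_list.append(lab[ys, xs])
            X = np.vstack(X_list)
            t = np.concatenate(t_list)[:, None]
            cache: list = []
            p = mlp.forward(X, cache)
            eps = 1e-7
            losses.append(
                float(-np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))
            )
            grads = mlp.backward(cache, (p - t) / X.shape[0])
            opt.step(grads)
        model.loss_history.append(float(np.mean(losses)))
    return model


def segment(image, model, threshold: int = 128) -> ImageGrid:
    """Binary SF raster at the input resolution.

    If the model was trained at a fixed resolution the input is resized to
    it bilinearly and the grayscale output mapped back with nearest
    neighbour.  Foreground is ``grayscale >= threshold`` on the 8-bit map.
    """
    img = as_array(image)
    native = img.shape
    work = img
    res = getattr(model, "resolution", None)
    if res is not None and native != (res, res):
        work = resize(img.astype(float), (res, res), order=1,
                      anti_aliasing=True, preserve_range=True)
    gray = model.predict_gray(work)
    if gray.shape != native:
        gray = resize(gray, native, order=0, preserve_range=True).astype(np.uint8)
    binary = gray >= threshold
    px = image.pixel_size if isinstance(image, ImageGrid) else ImageGrid(img).pixel_size
    return ImageGrid(binary, pixel_size=px, vrange=(0, 1))


# ---------------------------------------------------------------------------
# evaluation


def dilate_for_eval(binary, kernel: int = 8) -> ImageGrid:
    """Sliding-window widening of thin fiber masks before pixel metrics.

    A k x k window slides across the raster; whenever any SF pixel falls
    inside the window, every pixel covered by that window placement becomes
    foreground.  The union over placements equals a dilation by the
    (2k-1) x (2k-1) support, so an isolated pixel becomes a (2k-1)-square.
    Extensive and monotone; not idempotent (each application widens further).
    """
    b = as_array(binary)
    b = b > (127 if b.max() > 1 else 0)
    # stage 1: window placements that saw a fiber pixel (window [-k//2, ...])
    hit = maximum_filter(b, size=kernel)
    # stage 2: union of all windows that hit, i.e. filter with the
    # reflected window (for even sizes the reflection shifts the anchor)
    out = maximum_filter(hit, size=kernel, origin=-1 if kernel % 2 == 0 else 0)
    return ImageGrid(out, vrange=(0, 1))


def seg_metrics(pred_dilated, truth_dilated) -> SegMetrics:
    """Pixel confusion counts and rates between binary rasters."""
    p = as_array(pred_dilated)
    t = as_array(truth_dilated)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    p = p > (127 if p.max() > 1 else 0)
    t = t > (127 if t.max() > 1 else 0)
    return SegMetrics(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )
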