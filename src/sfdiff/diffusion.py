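"""Conditional denoising diffusion for shape-to-fiber translation.

Forward process: ``x_t = sqrt(abar_t) x_0 + sqrt(1 - abar_t) eps`` with
``abar_t`` the cumulative product of per-step alphas following the
squared-cosine schedule.  A noise-prediction network ``mu_theta(x_t, c, t)``
is trained on the simplified objective ``L_t = ||eps - mu_theta(...)||^2``
(mean over pixels).  Generation runs the deterministic accelerated reverse
update over an increasing sub-sequence tau of [1..T]:

    x0_hat  = (x_tau - sqrt(1 - abar_tau) mu_theta) / sqrt(abar_tau)
    x_prev  = sqrt(abar_prev) x0_hat + sqrt(1 - abar_prev) mu_theta

so that with the true noise supplied as the prediction the trajectory
inverts the forward process exactly.

The denoiser is a per-pixel patch network: the noisy field and the cell
mask are sampled on a receptive field rotated into the cell's major-axis
frame, concatenated with per-pixel shape descriptors (edge distance,
elliptic radial coordinate, centroid-frame coordinates, aspect ratio) and a
timestep embedding.  Conditioning therefore enters the network exactly as
``mu_theta(x_t, c, t)``, with the contour raster c pre-encoded into
geometric channels rather than fed as a bare image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .core import CellMask, ImageGrid, as_array
from .geometry import cell_morphometrics
from .nn import MLP, Adam, BilinearSampler, patch_offsets, sample_patches

__all__ = [
    "NoiseSchedule",
    "SubSequence",
    "DiffTrainConfig",
    "PROFILES",
    "cosine_schedule",
    "forward_diffuse",
    "training_loss",
    "make_subsequence",
    "ddim_step",
    "sample",
    "condition_features",
    "ConditionFeatures",
    "PatchDenoiser",
    "ConditionalDiffusion",
    "train_diffusion",
    "cycle_splits",
    "to_model_range",
    "from_model_range",
]


# ---------------------------------------------------------------------------
# schedule


@dataclass
class NoiseSchedule:
    """Per-step alphas and their cumulative products abar, 1-indexed in t."""

    alphas: np.ndarray
    alpha_bar: np.ndarray
    kind: str = "cosine"

    @property
    def T(self) -> int:
        return len(self.alphas)

    def alpha_bar_at(self, t) -> np.ndarray | float:
        """abar_t for t in [0..T]; abar_0 = 1 by construction."""
        t = np.asarray(t)
        if np.any(t < 0) or np.any(t > self.T):
            raise ValueError("timestep out of range")
        padded = np.concatenate([[1.0], self.alpha_bar])
        out = padded[t]
        return float(out) if out.ndim == 0 else out


def cosine_schedule(T: int = 800, offset: float = 0.008) -> NoiseSchedule:
    """Squared-cosine variance schedule.

    ``abar_t = f(t/T) / f(0)`` with ``f(u) = cos^2((u + s) / (1 + s) * pi/2)``;
    per-step alphas are the successive ratios, clipped to [0.001, 0.999],
    and abar is their cumulative product (so schedule invariants hold
    exactly after clipping).
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    t = np.arange(T + 1)
    f = np.cos((t / T + offset) / (1 + offset) * np.pi / 2) ** 2
    abar = f / f[0]
    alphas = np.clip(abar[1:] / abar[:-1], 0.001, 0.999)
    return NoiseSchedule(alphas=alphas, alpha_bar=np.cumprod(alphas))


@dataclass
class SubSequence:
    """Increasing sub-sequence tau of [1..T] used by the accelerated sampler."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=int)
        if len(self.tau) == 0 or np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing and non-empty")

    def __len__(self) -> int:
        return len(self.tau)


def make_subsequence(schedule: NoiseSchedule | int, length_S: int = 80) -> SubSequence:
    """Uniform-stride sub-sequence tau_i = round(i * T / S), ending at T.

    When T is not divisible by S the rounded values are de-duplicated and
    the final element forced to T, so the result may be shorter than S.
    """
    T = schedule if isinstance(schedule, int) else schedule.T
    if length_S < 1 or length_S > T:
        raise ValueError("length_S must lie in [1, T]")
    tau = np.unique(np.round(np.arange(1, length_S + 1) * T / length_S).astype(int))
    tau = tau[tau >= 1]
    tau[-1] = T
    return SubSequence(np.unique(tau))


# ---------------------------------------------------------------------------
# forward / reverse primitives


def forward_diffuse(x0, eps, t: int, schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form forward corruption to timestep t (t in [1..T])."""
    x0 = as_array(x0)
    eps = as_array(eps)
    if x0.shape != eps.shape:
        raise ValueError("x0 and eps must share shape")
    if not 1 <= t <= schedule.T:
        raise ValueError("t out of range")
    ab = schedule.alpha_bar_at(t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def training_loss(model, x0, condition_c, t: int, eps,
                  schedule: NoiseSchedule) -> float:
    """Simplified diffusion objective: mean-square noise-prediction error.

    The reduction is the mean over pixels, so a model emitting zeros scores
    ~1 against standard-normal noise.
    """
    x0 = as_array(x0)
    eps = as_array(eps)
    x_t = forward_diffuse(x0, eps, t, schedule)
    pred = model.predict_noise(x_t, condition_c, t)
    if pred.shape != eps.shape:
        raise ValueError("model output shape mismatch")
    return float(np.mean((eps - pred) ** 2))


def ddim_step(x, eps_hat, schedule: NoiseSchedule, t_cur: int,
              t_prev: int, clip_x0: bool = False) -> np.ndarray:
    """Deterministic reverse update from timestep t_cur down to t_prev.

    ``clip_x0`` bounds the implied clean image to the model range [-1, 1]
    before re-noising.  Near t = T the update divides by sqrt(abar_t) ~ 1e-4,
    so unclipped noise-prediction errors are amplified enormously; clipping
    is the standard stabilisation during generation.  It is off by default
    so that the algebraic forward/reverse inversion identity holds for
    arbitrary fields.
    """
    x = as_array(x)
    eps_hat = as_array(eps_hat)
    ab_c = schedule.alpha_bar_at(t_cur)
    ab_p = schedule.alpha_bar_at(t_prev)
    x0_hat = (x - np.sqrt(1.0 - ab_c) * eps_hat) / np.sqrt(ab_c)
    if clip_x0:
        x0_hat = np.clip(x0_hat, -1.0, 1.0)
        eps_hat = (x - np.sqrt(ab_c) * x0_hat) / np.sqrt(1.0 - ab_c)
    return np.sqrt(ab_p) * x0_hat + np.sqrt(1.0 - ab_p) * eps_hat


def to_model_range(img) -> np.ndarray:
    """8-bit image to the model's [-1, 1] range."""
    return as_array(img).astype(float) / 127.5 - 1.0


def from_model_range(x: np.ndarray) -> np.ndarray:
    """[-1, 1] field back to clipped 8-bit grayscale."""
    return np.clip(np.round((x + 1.0) * 127.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# conditioning


@dataclass
class ConditionFeatures:
    """Per-pixel geometric encoding of a cell shape condition."""

    mask: np.ndarray          # 0/1 float
    edge_dist: np.ndarray     # in-cell distance to the contour, / max
    radial: np.ndarray        # elliptic radius, ~1 at the contour
    coord_u: np.ndarray       # centroid-frame coordinate along the major axis
    coord_v: np.ndarray       # ... along the minor axis
    aspect_ratio: float
    psi: float                # major-axis angle used to rotate receptive fields
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def scalars(self) -> np.ndarray:
        """Stack of per-pixel scalar channels fed beside the patches."""
        ar_map = np.full_like(self.mask, min(self.aspect_ratio, 6.0) / 6.0)
        return np.stack(
            [self.mask, self.edge_dist, self.radial, self.coord_u,
             self.coord_v, ar_map]
        )


def condition_features(cell: CellMask) -> ConditionFeatures:
    mask = cell.mask.astype(float)
    m = cell_morphometrics(cell)
    dt = distance_transform_edt(cell.mask)
    edge = dt / max(dt.max(), 1.0)
    h, w = mask.shape
    ys, xs = np.mgrid[0:h, 0:w]
    cx, cy = m.centroid
    psi = 0.0 if m.isotropic else m.cell_direction_psi
    c, s = np.cos(psi), np.sin(psi)
    u = (xs - cx) * c + (ys - cy) * s
    v = -(xs - cx) * s + (ys - cy) * c
    a = max(m.major_axis_px, 1.0)
    b = max(m.minor_axis_px, 1.0)
    radial = np.clip(np.hypot(u / a, v / b), 0.0, 2.0)
    return ConditionFeatures(
        mask=mask,
        edge_dist=edge,
        radial=radial,
        coord_u=np.clip(u / a, -2.0, 2.0),
        coord_v=np.clip(v / b, -2.0, 2.0),
        aspect_ratio=m.aspect_ratio,
        psi=psi,
    )


def _time_embedding(t: int, T: int, schedule: NoiseSchedule) -> np.ndarray:
    ab = schedule.alpha_bar_at(t)
    return np.array(
        [np.sqrt(ab), np.sqrt(1.0 - ab), t / T, np.cos(np.pi * t / T)]
    )


# ---------------------------------------------------------------------------
# denoiser


class PatchDenoiser:
    """Noise-prediction network over rotated local patches.

    Input per pixel: the x_t patch and the mask patch sampled on an offset
    grid rotated by the cell direction, the condition scalars at the pixel,
    the learned condition-prior value (when a prior encoder is attached)
    and the timestep embedding.

    The prior encoder is a small network regressing the clean image value
    on the shape descriptors alone, i.e. a learned map of where fibers tend
    to sit in a given shape.  Supervising it directly (rather than only
    through the noise-prediction objective, where the spatial prior is a
    small component of a high-variance target) makes the conditional
    structure of the generator much more reliable at this model scale.
    The denoiser is residual around it: one input block is the noise that
    the current field would imply if the clean image equalled the prior
    map, so reproducing that block verbatim already generates the prior and
    the network only has to model deviations from it.
    """

    N_TIME = 4

    def __init__(self, patch_size: int, hidden: tuple[int, ...],
                 schedule: NoiseSchedule, seed: int = 0,
                 prior: MLP | None = None):
        self.patch_size = patch_size
        self.schedule = schedule
        self.prior = prior
        k2 = patch_size * patch_size
        self.n_scalars = 6 + (1 if prior is not None else 0)
        # x_t at two scales (dilated receptive field), mask, and the
        # prior-residual block
        self.n_patches = 4 if prior is not None else 3
        sizes = [self.n_patches * k2 + self.n_scalars + self.N_TIME,
                 *hidden, 1]
        self.mlp = MLP(sizes, np.random.default_rng(seed), out="linear")
        if prior is not None:
            # start as a small correction around the prior-implied skip
            self.mlp.W[-1] *= 0.1

    def _static_features(self, cond: ConditionFeatures,
                         centers: np.ndarray):
        """(mask patches, prior patches or None, scalar block); t independent."""
        offs = patch_offsets(self.patch_size, cond.psi)
        mp = sample_patches(cond.mask, centers, offs)
        iy = centers[:, 0].astype(int)
        ix = centers[:, 1].astype(int)
        scal = cond.scalars[:, iy, ix].T
        pp = None
        if self.prior is not None:
            h, w = cond.mask.shape
            key = ("prior_map", id(self.prior))
            if key not in cond._cache:
                allscal = cond.scalars.reshape(cond.scalars.shape[0], -1).T
                cond._cache[key] = self.prior.forward(allscal).reshape(h, w)
            prior_map = cond._cache[key]
            pp = sample_patches(prior_map, centers, offs)
            scal = np.concatenate(
                [scal, prior_map[iy, ix][:, None]], axis=1)
        return mp, pp, scal

    def _assemble(self, xp, xp2, static, t: int):
        """Returns (feature matrix, skip) — the skip term is the noise the
        current field implies if the clean image equalled the prior map,
        evaluated at the centre pixel; the network output is added to it,
        so an untrained network already generates the prior."""
        mp, pp, scal = static
        ab = self.schedule.alpha_bar_at(t)
        emb = np.broadcast_to(
            _time_embedding(t, self.schedule.T, self.schedule),
            (xp.shape[0], self.N_TIME),
        )
        blocks = [xp, xp2, mp]
        skip = 0.0
        if pp is not None:
            rp = (xp - np.sqrt(ab) * pp) / np.sqrt(1.0 - ab)
            blocks.append(mp * rp)
            c = self.patch_size**2 // 2
            skip = rp[:, c : c + 1]
        blocks += [scal, emb]
        return np.concatenate(blocks, axis=1), skip

    def features(self, x_t: np.ndarray, cond: ConditionFeatures, t: int,
                 centers: np.ndarray, static=None):
        offs = patch_offsets(self.patch_size, cond.psi)
        xp = sample_patches(x_t, centers, offs)
        xp2 = sample_patches(x_t, centers, 2.0 * offs)
        if static is None:
            static = self._static_features(cond, centers)
        return self._assemble(xp, xp2, static, t)

    def predict_noise(self, x_t: np.ndarray, cond: ConditionFeatures,
                      t: int) -> np.ndarray:
        h, w = x_t.shape
        key = ("full_grid", self.patch_size, h, w)
        if key not in cond._cache:
            ys, xs = np.mgrid[0:h, 0:w]
            centers = np.column_stack([ys.ravel(), xs.ravel()]).astype(float)
            offs = patch_offsets(self.patch_size, cond.psi)
            sampler = BilinearSampler((h, w), centers, offs)
            sampler2 = BilinearSampler((h, w), centers, 2.0 * offs)
            static = self._static_features(cond, centers)
            cond._cache[key] = (sampler, sampler2, static)
        sampler, sampler2, static = cond._cache[key]
        X, skip = self._assemble(sampler(x_t), sampler2(x_t), static, t)
        return (self.mlp.forward(X) + skip).reshape(h, w)


# ---------------------------------------------------------------------------
# training and generation


@dataclass
class DiffTrainConfig:
    batch_size: int = 16
    learning_rate: float = 1.5e-4
    epochs: int = 1500
    T: int = 800
    sub_length: int = 80
    patch_size: int = 7
    hidden: tuple[int, ...] = (96, 96)
    pixels_per_image: int = 256
    prior_epochs: int = 30
    prior_hidden: tuple[int, ...] = (32, 32)
    prior_learning_rate: float = 5e-3
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.T, self.sub_length,
               self.patch_size, self.pixels_per_image) <= 0:
            raise ValueError("training parameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


#: Named training profiles: ``full`` mirrors the reference training setup at
#: 256x256; ``tiny`` is a CPU-scale variant for tests and examples.
PROFILES: dict[str, dict] = {
    "full": dict(batch_size=16, learning_rate=1.5e-4, epochs=1500,
                 patch_size=9, hidden=(128, 128), pixels_per_image=512),
    "tiny": dict(batch_size=16, learning_rate=2e-3, epochs=30,
                 patch_size=7, hidden=(96, 96), pixels_per_image=512),
}


def _orient_variant(arr: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.rot90(arr, k)
    return out[:, ::-1] if flip else out


@dataclass
class ConditionalDiffusion:
    """Trained conditional generator: shape in, stress-fiber image out."""

    denoiser: PatchDenoiser
    schedule: NoiseSchedule
    subsequence: SubSequence
    config: DiffTrainConfig | None = None
    loss_history: list[float] = field(default_factory=list)

    def generate(self, cell: CellMask, seed: int = 0) -> ImageGrid:
        cond = getattr(cell, "_cond_features", None)
        if cond is None:
            cond = condition_features(cell)
            cell._cond_features = cond  # reused across repeated generations
        img = sample(self.denoiser, cond, self.schedule, self.subsequence,
                     seed=seed)
        return ImageGrid(img, pixel_size=cell.pixel_size)


def sample(model, condition_c, schedule: NoiseSchedule,
           subsequence: SubSequence, seed: int = 0) -> np.ndarray:
    """Generate one 8-bit grayscale SF image from seeded Gaussian noise.

    ``condition_c`` may be a CellMask or precomputed ConditionFeatures; its
    raster must match the model's expectations.  Deterministic in
    (model, condition, seed).
    """
    cond = (condition_c if isinstance(condition_c, ConditionFeatures)
            else condition_features(condition_c))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(cond.mask.shape)
    taus = subsequence.tau
    prevs = np.concatenate([[0], taus[:-1]])
    for t_cur, t_prev in zip(taus[::-1], prevs[::-1]):
        eps_hat = model.predict_noise(x, cond, int(t_cur))
        x = ddim_step(x, eps_hat, schedule, int(t_cur), int(t_prev),
                      clip_x0=True)
    return from_model_range(x)


def train_diffusion(pairs, cfg: DiffTrainConfig | None = None,
                    profile: str | None = None) -> ConditionalDiffusion:
    """Train the conditional denoiser on paired (SF image, cell shape) data.

    Each optimiser step draws ``batch_size`` training pairs; every pair gets
    an independent uniform timestep, a fresh noise field and (optionally) a
    random right-angle rotation/flip applied jointly to image and shape.
    The per-epoch mean of the noise-prediction MSE is logged.
    """
    if not pairs:
        raise ValueError("empty dataset")
    cfg = cfg or DiffTrainConfig()
    if profile is not None:
        cfg = DiffTrainConfig(**{**cfg.__dict__, **PROFILES[profile]})
    schedule = cosine_schedule(cfg.T)
    subseq = make_subsequence(schedule, cfg.sub_length)
    rng = np.random.default_rng(cfg.seed)

    # cache x0 fields, masks and per-orientation condition features
    x0s, masks, pxs = [], [], []
    for p in pairs:
        img = p.sf_image if hasattr(p, "sf_image") else p[0]
        cell = p.mask if hasattr(p, "mask") else p[1]
        x0s.append(to_model_range(img))
        masks.append(cell.mask)
        pxs.append(cell.pixel_size)
    feat_cache: dict = {}

    def features_for(i: int, k: int, flip: bool) -> tuple:
        key = (i, k, flip)
        if key not in feat_cache:
            m = _orient_variant(masks[i], k, flip)
            from .fixtures import _mask_to_cellmask

            feat_cache[key] = condition_features(_mask_to_cellmask(m, pxs[i]))
        return feat_cache[key]

    n = len(pairs)

    # stage 1: condition prior — regress the clean image on shape scalars
    prior = None
    if cfg.prior_epochs > 0:
        prior = MLP([6, *cfg.prior_hidden, 1], np.random.default_rng(cfg.seed + 1))
        popt = Adam(prior.params, lr=cfg.prior_learning_rate)
        for _ in range(cfg.prior_epochs):
            for i in rng.permutation(n):
                k, flip = (int(rng.integers(4)), bool(rng.integers(2))) \
                    if cfg.augment else (0, False)
                x0 = _orient_variant(x0s[i], k, flip)
                cond = features_for(int(i), k, flip)
                h, w = x0.shape
                ys = rng.integers(0, h, cfg.pixels_per_image)
                xs = rng.integers(0, w, cfg.pixels_per_image)
                X = cond.scalars[:, ys, xs].T
                y = x0[ys, xs][:, None]
                cache: list = []
                pred = prior.forward(X, cache)
                popt.step(prior.backward(cache, 2.0 * (pred - y) / len(y)))

    den = PatchDenoiser(cfg.patch_size, cfg.hidden, schedule, seed=cfg.seed,
                        prior=prior)
    opt = Adam(den.mlp.params, lr=cfg.learning_rate)
    model = ConditionalDiffusion(denoiser=den, schedule=schedule,
                                 subsequence=subseq, config=cfg)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            X_list, y_list = [], []
            for i in order[start : start + cfg.batch_size]:
                k, flip = (int(rng.integers(4)), bool(rng.integers(2))) \
                    if cfg.augment else (0, False)
                x0 = _orient_variant(x0s[i], k, flip)
                cond = features_for(int(i), k, flip)
                t = int(rng.integers(1, schedule.T + 1))
                eps = rng.standard_normal(x0.shape)
                x_t = forward_diffuse(x0, eps, t, schedule)
                h, w = x0.shape
                ys = rng.integers(0, h, cfg.pixels_per_image)
                xs = rng.integers(0, w, cfg.pixels_per_image)
                centers = np.column_stack([ys, xs]).astype(float)
                Xi, skip_i = den.features(x_t, cond, t, centers)
                X_list.append(Xi)
                y_list.append(eps[ys, xs][:, None]
                              - (skip_i if np.ndim(skip_i) else 0.0))
            X = np.vstack(X_list)
            y = np.vstack(y_list)
            cache: list = []
            pred = den.mlp.forward(X, cache)
            losses.append(float(np.mean((pred - y) ** 2)))
            grads = den.mlp.backward(cache, 2.0 * (pred - y) / X.shape[0])
            opt.step(grads)
        model.loss_history.append(float(np.mean(losses)))
    return model


# ---------------------------------------------------------------------------
# evaluation protocol utility


def cycle_splits(n_items: int = 1293, n_cycles: int = 13,
                 test_size: int = 100, seed: int = 0):
    """Disjoint train/test cycles covering every item exactly once in test.

    The first ``n_cycles - 1`` cycles hold out ``test_size`` items each; the
    last cycle takes the remainder (1293 items -> 12 x 100 + 1 x 93).
    """
    if n_cycles * test_size < n_items:
        raise ValueError("cycles cannot cover all items")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    splits = []
    for c in range(n_cycles):
        lo = c * test_size
        hi = min(lo + test_size, n_items)
        test = np.sort(perm[lo:hi])
        train = np.sort(np.setdiff1d(perm, test))
        splits.append((train, test))
        if hi == n_items:
            break
    return splits
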