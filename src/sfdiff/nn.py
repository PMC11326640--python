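"""Minimal neural-network engine: patch-feature MLPs trained with Adam.

The segmenter and the diffusion denoiser are both per-pixel regressors over
local receptive fields: an image patch (optionally sampled on a rotated
offset grid) plus auxiliary per-pixel features feeds a small fully-connected
network.  Everything is plain NumPy with hand-written backpropagation, which
keeps the package dependency-light and fast enough for CPU-scale problems.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "patch_offsets", "sample_patches", "BilinearSampler"]


class MLP:
    """Fully-connected network with ReLU hidden layers.

    ``out`` selects the output head: ``"linear"`` for regression or
    ``"sigmoid"`` for probabilities.  Weights use He initialisation from the
    supplied generator so training is reproducible.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 out: str = "linear"):
        if out not in ("linear", "sigmoid"):
            raise ValueError("out must be 'linear' or 'sigmoid'")
        self.sizes = list(sizes)
        self.out = out
        self.W = [
            rng.standard_normal((m, n)) * np.sqrt(2.0 / m)
            for m, n in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(n) for n in sizes[1:]]

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = X
        if cache is not None:
            cache.append(a)
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < last:
                a = np.maximum(z, 0.0)
            elif self.out == "sigmoid":
                a = 1.0 / (1.0 + np.exp(-z))
            else:
                a = z
            if cache is not None:
                cache.append(a)
        return a

    def backward(self, cache: list, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients for all parameters given d(loss)/d(pre-activation output).

        For the sigmoid head pass d(loss)/d(logit) directly (BCE does this
        naturally); for the linear head pass d(loss)/d(output).
        """
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = cache[i]
            gW[i] = a_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (cache[i] > 0)
        return gW + gb

    def state_dict(self) -> dict:
        return {
            "sizes": self.sizes,
            "out": self.out,
            "W": [w.copy() for w in self.W],
            "b": [b.copy() for b in self.b],
        }

    @classmethod
    def from_state(cls, state: dict) -> "MLP":
        net = cls.__new__(cls)
        net.sizes = list(state["sizes"])
        net.out = state["out"]
        net.W = [np.asarray(w, dtype=float) for w in state["W"]]
        net.b = [np.asarray(b, dtype=float) for b in state["b"]]
        return net


class Adam:
    """Adam optimiser over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def patch_offsets(patch_size: int, angle: float = 0.0) -> np.ndarray:
    """(k*k, 2) array of (dy, dx) offsets, optionally rotated by ``angle``.

    Rotating the offset grid aligns the receptive field with a reference
    direction (e.g. the cell's major axis) so oriented structure always
    appears in a canonical frame.
    """
    k = patch_size
    r = np.arange(k) - (k - 1) / 2.0
    dy, dx = np.meshgrid(r, r, indexing="ij")
    c, s = np.cos(angle), np.sin(angle)
    rdx = c * dx - s * dy
    rdy = s * dx + c * dy
    return np.column_stack([rdy.ravel(), rdx.ravel()])


class BilinearSampler:
    """Precomputed bilinear gather for fixed patch geometry.

    When the same centers/offsets are sampled repeatedly against different
    images (every reverse-diffusion step), the gather indices and weights
    can be built once.
    """

    def __init__(self, shape: tuple[int, int], centers_yx: np.ndarray,
                 offsets: np.ndarray):
        h, w = shape
        yy = np.clip(centers_yx[:, 0:1] + offsets[:, 0][None, :], 0.0, h - 1.0)
        xx = np.clip(centers_yx[:, 1:2] + offsets[:, 1][None, :], 0.0, w - 1.0)
        y0 = yy.astype(int)
        x0 = xx.astype(int)
        y1 = np.minimum(y0 + 1, h - 1)
        x1 = np.minimum(x0 + 1, w - 1)
        wy = yy - y0
        wx = xx - x0
        self.idx = (y0 * w + x0, y0 * w + x1, y1 * w + x0, y1 * w + x1)
        self.wgt = ((1 - wy) * (1 - wx), (1 - wy) * wx, wy * (1 - wx), wy * wx)
        self.shape = shape

    def __call__(self, image: np.ndarray) -> np.ndarray:
        flat = np.asarray(image, dtype=float).ravel()
        i00, i01, i10, i11 = self.idx
        w00, w01, w10, w11 = self.wgt
        return (w00 * flat[i00] + w01 * flat[i01]
                + w10 * flat[i10] + w11 * flat[i11])


def sample_patches(image: np.ndarray, centers_yx: np.ndarray,
                   offsets: np.ndarray) -> np.ndarray:
    """Bilinear patch samples: (n_centers, k*k) matrix.

    ``centers_yx`` is (n, 2) in (y, x); coordinates outside the image are
    sampled with nearest-edge padding.  Vectorised by hand since this sits
    on the sampling hot path.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    yy = centers_yx[:, 0:1] + offsets[:, 0][None, :]
    xx = centers_yx[:, 1:2] + offsets[:, 1][None, :]
    yy = np.clip(yy, 0.0, h - 1.0)
    xx = np.clip(xx, 0.0, w - 1.0)
    y0 = yy.astype(int)
    x0 = xx.astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    wy = yy - y0
    wx = xx - x0
    flat = img.ravel()
    v00 = flat[y0 * w + x0]
    v01 = flat[y0 * w + x1]
    v10 = flat[y1 * w + x0]
    v11 = flat[y1 * w + x1]
    return (
        (1 - wy) * ((1 - wx) * v00 + wx * v01)
        + wy * ((1 - wx) * v10 + wx * v11)
    )
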