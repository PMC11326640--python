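"""Contour curvature, local intensity and the Laplace-law tension balance.

The local curvature of the cell contour is measured by sliding a window of
diameter ``L = P_cell / 30`` (one-thirtieth of the perimeter) along the
contour, rotating the points into the local tangent frame and fitting a
quadratic ``g(x) = a x^2 + b x + c``; then

    kappa = |g''| / (1 + g'^2)^(3/2)

evaluated at the window centre, with positive sign for convex arcs
(bulging away from the cell centroid) and negative for concave arcs.
Peripheral mechanics follow the Laplace law ``R = 1/kappa = lambda/sigma``
with the line tension given by Hooke's law ``lambda = E A eps``, so arcs
supported by stiffer fiber bundles are flatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .core import CellMask, SFDiffError, as_array

__all__ = [
    "ContourProfile",
    "LaplaceInputs",
    "resample_contour",
    "local_curvature",
    "curvature_profile",
    "local_intensity",
    "intensity_profile",
    "profile_correlation",
    "laplace_radius",
    "local_force_average",
    "contour_profile",
]


@dataclass
class ContourProfile:
    """Per-point profiles along a uniformly resampled closed contour."""

    points: np.ndarray
    window_L: float
    kappa: np.ndarray
    intensity: np.ndarray | None = None
    prob: np.ndarray | None = None
    force: np.ndarray | None = None


@dataclass
class LaplaceInputs:
    """Hooke + Laplace force-balance inputs (SI units)."""

    youngs_E: float             # Pa
    cross_section_Acs: float    # m^2
    strain_eps: float           # dimensionless
    surface_tension_sigma: float  # N/m

    @property
    def line_tension_lambda(self) -> float:
        return self.youngs_E * self.cross_section_Acs * self.strain_eps


def resample_contour(contour: np.ndarray, spacing: float = 1.0,
                     smooth: float = 2.0) -> np.ndarray:
    """Resample a closed contour to uniform arc-length spacing.

    ``smooth`` is the sigma (in samples) of a circular Gaussian applied to
    the resampled coordinates; it suppresses the half-pixel staircase of
    marching-squares contours, which otherwise dominates curvature fits at
    window scales of a few pixels.  Set to 0 to disable.
    """
    pts = np.asarray(contour, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise SFDiffError("degenerate contour")
    n_out = max(int(round(total / spacing)), 8)
    si = np.arange(n_out) * total / n_out
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    if smooth > 0:
        x = gaussian_filter1d(x, smooth, mode="wrap")
        y = gaussian_filter1d(y, smooth, mode="wrap")
    return np.column_stack([x, y])


def _window_indices(n: int, index: int, half_n: int) -> np.ndarray:
    return (index + np.arange(-half_n, half_n + 1)) % n


def local_curvature(contour: np.ndarray, index: int, window_L: float,
                    centroid: tuple[float, float],
                    spacing: float = 1.0) -> float:
    """Signed curvature at one contour point (contour must be uniformly
    resampled at ``spacing``; window membership is by arc distance)."""
    pts = np.asarray(contour, dtype=float)
    n = len(pts)
    half_n = max(int(round(window_L / (2 * spacing))), 3)
    if 2 * half_n + 1 > n:
        raise SFDiffError("window longer than the contour")
    idx = _window_indices(n, index, half_n)
    w = pts[idx]
    p = pts[index]
    rel = w - p
    # tangent direction from the window's principal axis
    cov = rel.T @ rel
    evals, evecs = np.linalg.eigh(cov)
    t_hat = evecs[:, np.argmax(evals)]
    n_hat = np.array([-t_hat[1], t_hat[0]])
    u = rel @ t_hat
    v = rel @ n_hat
    if np.ptp(u) < 1e-9:
        raise SFDiffError("degenerate window: collinear duplicate points")
    a, b, _c = np.polyfit(u, v, 2)
    kappa = abs(2 * a) / (1 + b**2) ** 1.5
    # sign: convex if the centre point bulges away from the centroid
    # relative to the window chord
    chord_mid = 0.5 * (w[0] + w[-1])
    cx, cy = centroid
    d_point = np.hypot(p[0] - cx, p[1] - cy)
    d_chord = np.hypot(chord_mid[0] - cx, chord_mid[1] - cy)
    return float(kappa if d_point >= d_chord else -kappa)


def curvature_profile(cell: CellMask, window_L: float | None = None,
                      spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray, float]:
    """(resampled points, kappa array, window_L); default L = perimeter/30."""
    if window_L is None:
        window_L = cell.perimeter_px / 30.0
    if window_L <= 0:
        raise ValueError("window_L must be positive")
    # smoothing scaled to the window keeps the staircase noise well below
    # the curvature signal at every window size
    pts = resample_contour(cell.contour, spacing,
                           smooth=max(2.0, window_L / spacing))
    centroid = cell.centroid
    kappa = np.array(
        [local_curvature(pts, i, window_L, centroid, spacing)
         for i in range(len(pts))]
    )
    return pts, kappa, window_L


def local_intensity(image, contour: np.ndarray, index: int, window_L: float,
                    cell_mask: CellMask | np.ndarray) -> float:
    """Mean image intensity in the circular window of diameter L centred on
    a contour point, restricted to in-cell pixels."""
    img = as_array(image).astype(float)
    mask = cell_mask.mask if isinstance(cell_mask, CellMask) else np.asarray(
        cell_mask, dtype=bool)
    x0, y0 = np.asarray(contour, dtype=float)[index]
    r = window_L / 2.0
    h, w = img.shape
    ylo, yhi = max(int(np.floor(y0 - r)), 0), min(int(np.ceil(y0 + r)), h - 1)
    xlo, xhi = max(int(np.floor(x0 - r)), 0), min(int(np.ceil(x0 + r)), w - 1)
    X, Y = np.meshgrid(np.arange(xlo, xhi + 1), np.arange(ylo, yhi + 1))
    inside = (np.hypot(X - x0, Y - y0) <= r) & mask[ylo : yhi + 1, xlo : xhi + 1]
    if not inside.any():
        raise SFDiffError("window entirely extracellular")
    return float(img[ylo : yhi + 1, xlo : xhi + 1][inside].mean())


def intensity_profile(image, points: np.ndarray, window_L: float,
                      cell_mask) -> np.ndarray:
    return np.array(
        [local_intensity(image, points, i, window_L, cell_mask)
         for i in range(len(points))]
    )


def profile_correlation(a, b) -> float:
    """Pearson correlation between two aligned per-point series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must be aligned with length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise SFDiffError("zero-variance series")
    return float(pearsonr(a, b).statistic)


def laplace_radius(inputs: LaplaceInputs) -> dict:
    """Curvature radius from the tension balance R = lambda / sigma."""
    if inputs.surface_tension_sigma <= 0:
        raise ValueError("surface tension must be positive")
    lam = inputs.line_tension_lambda
    R = lam / inputs.surface_tension_sigma
    return {"radius": R, "kappa": 1.0 / R if R != 0 else np.inf,
            "line_tension": lam}


def local_force_average(force_points, contour: np.ndarray, index: int,
                        window_L: float) -> float:
    """Mean force magnitude over points within distance L of the contour
    point; NaN (flagged missing) when the neighbourhood is empty.

    ``force_points`` is an (N, 3) array-like or DataFrame of x, y, magnitude.
    """
    arr = np.asarray(force_points, dtype=float)
    if arr.size == 0:
        return float("nan")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("force table must have columns x, y, magnitude")
    p = np.asarray(contour, dtype=float)[index]
    d = np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1])
    near = d < window_L
    if not near.any():
        return float("nan")
    return float(arr[near, 2].mean())


def contour_profile(cell: CellMask, image=None, prob=None, force_points=None,
                    window_L: float | None = None,
                    spacing: float = 1.0) -> ContourProfile:
    """Build aligned per-point profiles (curvature, intensity, P, force)."""
    pts, kappa, L = curvature_profile(cell, window_L, spacing)
    intensity = prob_arr = force_arr = None
    if image is not None:
        intensity = intensity_profile(image, pts, L, cell)
    if prob is not None:
        prob_arr = intensity_profile(prob, pts, L, cell)
    if force_points is not None:
        force_arr = np.array(
            [local_force_average(force_points, pts, i, L)
             for i in range(len(pts))]
        )
    return ContourProfile(points=pts, window_L=L, kappa=kappa,
                          intensity=intensity, prob=prob_arr, force=force_arr)
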