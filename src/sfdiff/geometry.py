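"""Fiber-level and cell-level morphometrics.

Fiber geometry is summarised by the total length ``l = sum_m l_m``, the
length-weighted principal direction ``phi_bar`` and the nematic order
parameter

    S = sum_m [2 cos^2(phi_m - phi_bar) - 1] * omega_m,   omega_m = l_m / l,

which is 1 for perfectly aligned fibers and 0 for an isotropic ensemble.
Cell morphology is summarised through the second central moments of the
mask indicator: the cell direction ``psi`` is the major-axis angle of the
moment-equivalent ellipse, and the aspect ratio is its axis ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import perimeter_crofton
from skimage.morphology import skeletonize
from skimage.transform import probabilistic_hough_line

from .core import (
    CellMask,
    EmptyMaskError,
    EmptySegmentsError,
    SegmentSet,
    as_array,
)

__all__ = [
    "MorphologyMetrics",
    "detect_segments",
    "fiber_stats",
    "axial_mean",
    "cell_morphometrics",
    "area_ratio_model",
    "mask_moments",
]


# ---------------------------------------------------------------------------
# fiber statistics


def axial_mean(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted mean of pi-periodic (axial) angles via doubled-angle vectors.

    Returns a value in [0, pi).  This reduces to the plain weighted mean for
    angles clustered away from the 0/pi wrap, and is the convention under
    which the order parameter is rotation invariant.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise EmptySegmentsError("mean angle undefined for empty input")
    if weights is None:
        weights = np.full(angles.shape, 1.0 / angles.size)
    c = float(np.sum(weights * np.cos(2.0 * angles)))
    s = float(np.sum(weights * np.sin(2.0 * angles)))
    return float(np.mod(0.5 * np.arctan2(s, c), np.pi))


def fiber_stats(
    segs: SegmentSet, mean_convention: str = "axial"
) -> tuple[float, float, float]:
    """Total length l, principal direction phi_bar and order parameter S.

    ``mean_convention`` selects how phi_bar is computed: ``"axial"`` (default)
    uses doubled-angle vector averaging; ``"arithmetic"`` is the literal
    length-weighted arithmetic mean of the angles, which is frame dependent
    near the 0/pi wrap but matches the printed definition.
    """
    if len(segs) == 0:
        raise EmptySegmentsError("fiber statistics undefined for an empty set")
    w = segs.weights
    phi = segs.angles
    if mean_convention == "axial":
        phi_bar = axial_mean(phi, w)
    elif mean_convention == "arithmetic":
        phi_bar = float(np.sum(phi * w))
    else:
        raise ValueError(f"unknown mean_convention {mean_convention!r}")
    S = float(np.sum((2.0 * np.cos(phi - phi_bar) ** 2 - 1.0) * w))
    return segs.total_length, phi_bar, S


# ---------------------------------------------------------------------------
# segment detection


def _merge_pass(segs: list[np.ndarray], angle_tol: float, perp_tol: float,
                gap_tol: float) -> tuple[list[np.ndarray], bool]:
    merged_any = False
    out: list[np.ndarray] = []
    used = np.zeros(len(segs), dtype=bool)
    for i in range(len(segs)):
        if used[i]:
            continue
        cur = segs[i]
        used[i] = True
        changed = True
        while changed:
            changed = False
            d = cur[2:4] - cur[0:2]
            L = np.linalg.norm(d)
            u = d / L
            ang = np.mod(np.arctan2(u[1], u[0]), np.pi)
            mid = 0.5 * (cur[0:2] + cur[2:4])
            for j in range(i + 1, len(segs)):
                if used[j]:
                    continue
                other = segs[j]
                d2 = other[2:4] - other[0:2]
                ang2 = np.mod(np.arctan2(d2[1], d2[0]), np.pi)
                dang = np.abs(ang - ang2)
                dang = min(dang, np.pi - dang)
                if dang > angle_tol:
                    continue
                # perpendicular offset of the other segment's midpoint
                mid2 = 0.5 * (other[0:2] + other[2:4])
                rel = mid2 - mid
                perp = abs(rel[0] * -u[1] + rel[1] * u[0])
                if perp > perp_tol:
                    continue
                # gap along the common direction
                proj = np.array(
                    [np.dot(p - mid, u) for p in (cur[0:2], cur[2:4],
                                                  other[0:2], other[2:4])]
                )
                lo1, hi1 = min(proj[0], proj[1]), max(proj[0], proj[1])
                lo2, hi2 = min(proj[2], proj[3]), max(proj[2], proj[3])
                gap = max(lo2 - hi1, lo1 - hi2)
                if gap > gap_tol:
                    continue
                # merge: extreme projections onto the direction of the longer
                pts = np.vstack([cur[0:2], cur[2:4], other[0:2], other[2:4]])
                t = pts @ u
                cur = np.concatenate([pts[np.argmin(t)], pts[np.argmax(t)]])
                used[j] = True
                merged_any = True
                changed = True
        out.append(cur)
    return out, merged_any


def detect_segments(
    binary_sf,
    min_length: int = 10,
    line_gap: int = 4,
    threshold: int = 8,
    angle_tol_deg: float = 7.5,
    perp_tol: float = 3.5,
    gap_tol: float = 6.0,
    seed: int = 0,
) -> SegmentSet:
    """Extract straight fiber segments from a binary SF raster.

    Built-in backend: morphological skeletonisation followed by a
    probabilistic Hough transform, then iterative merging of collinear,
    nearly touching fragments into single segments.  Any detector producing
    endpoint pairs can stand in for this one.
    """
    img = as_array(binary_sf)
    mask = img > (127 if img.max() > 1 else 0)
    if not mask.any():
        return SegmentSet()
    skel = skeletonize(mask)
    rng = np.random.default_rng(seed)
    lines = probabilistic_hough_line(
        skel,
        threshold=threshold,
        line_length=min_length,
        line_gap=line_gap,
        rng=rng,
    )
    if not lines:
        return SegmentSet()
    segs = [np.array([p0[0], p0[1], p1[0], p1[1]], dtype=float)
            for p0, p1 in lines]
    angle_tol = np.deg2rad(angle_tol_deg)
    for _ in range(20):
        segs, merged = _merge_pass(segs, angle_tol, perp_tol, gap_tol)
        if not merged:
            break
    # endpoint refinement: the Hough vote threshold truncates segment tips;
    # extend each segment to the extremes of its skeleton support
    ys, xs = np.nonzero(skel)
    pts = np.column_stack([xs, ys]).astype(float)
    refined = []
    for seg in segs:
        d = seg[2:4] - seg[0:2]
        u = d / np.linalg.norm(d)
        nvec = np.array([-u[1], u[0]])
        mid = 0.5 * (seg[0:2] + seg[2:4])
        rel = pts - mid
        t = rel @ u
        perp = np.abs(rel @ nvec)
        half = 0.5 * np.linalg.norm(d) + gap_tol
        tube = (perp <= perp_tol) & (np.abs(t) <= half)
        if tube.any():
            lo, hi = t[tube].min(), t[tube].max()
            refined.append(np.concatenate([mid + lo * u, mid + hi * u]))
        else:
            refined.append(seg)
    return SegmentSet(np.vstack(refined))


# ---------------------------------------------------------------------------
# cell morphometrics


def mask_moments(mask: np.ndarray) -> dict:
    """Centroid and second central moments of a binary mask indicator."""
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise EmptyMaskError("moments undefined for an empty mask")
    xbar, ybar = xs.mean(), ys.mean()
    dx, dy = xs - xbar, ys - ybar
    return {
        "centroid": (float(xbar), float(ybar)),
        "mu20": float(np.sum(dx * dx)),
        "mu02": float(np.sum(dy * dy)),
        "mu11": float(np.sum(dx * dy)),
        "area": int(xs.size),
    }


@dataclass
class MorphologyMetrics:
    cell_area_px: int
    cell_area_um2: float
    perimeter_px: float
    cell_direction_psi: float
    aspect_ratio: float
    circularity: float
    centroid: tuple[float, float]
    mu20: float
    mu02: float
    mu11: float
    major_axis_px: float
    minor_axis_px: float
    isotropic: bool


def cell_morphometrics(
    cell: CellMask, isotropy_rtol: float = 0.01
) -> MorphologyMetrics:
    """Moment-based morphology of a cell mask.

    ``psi = 0.5 * atan2(2*mu11, mu20 - mu02)`` is the major-axis angle of the
    ellipse sharing the mask's second moments; the aspect ratio is the ratio
    of that ellipse's axes and circularity is ``4*pi*A / P^2``.  When the
    moment matrix is isotropic within ``isotropy_rtol`` the direction is
    noise-driven and the ``isotropic`` flag is set (psi is still reported).
    """
    m = mask_moments(cell.mask)
    mu20, mu02, mu11, area = m["mu20"], m["mu02"], m["mu11"], m["area"]
    psi = float(np.mod(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02), np.pi))
    tr = mu20 + mu02
    disc = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11**2)
    lam1 = tr / 2.0 + disc
    lam2 = tr / 2.0 - disc
    # solid ellipse of area A with semi-axes a >= b has mu20' = A a^2 / 4
    major = 2.0 * np.sqrt(max(lam1, 0.0) / area)
    minor = 2.0 * np.sqrt(max(lam2, 0.0) / area)
    ar = float(major / minor) if minor > 0 else np.inf
    # Crofton estimator: unbiased on smooth shapes, unlike the staircase
    # marching-squares polyline length
    perim = float(perimeter_crofton(cell.mask, directions=4))
    circ = float(4.0 * np.pi * area / perim**2) if perim > 0 else 0.0
    iso = bool(
        abs(mu20 - mu02) <= isotropy_rtol * tr and abs(mu11) <= 0.5 * isotropy_rtol * tr
    )
    return MorphologyMetrics(
        cell_area_px=area,
        cell_area_um2=area * cell.pixel_size**2,
        perimeter_px=perim,
        cell_direction_psi=psi,
        aspect_ratio=ar,
        circularity=circ,
        centroid=m["centroid"],
        mu20=mu20,
        mu02=mu02,
        mu11=mu11,
        major_axis_px=float(major),
        minor_axis_px=float(minor),
        isotropic=iso,
    )


def area_ratio_model(
    cell: CellMask, binary_sf, fiber_width_w: float, total_length: float | None = None
) -> dict:
    """Area-ratio model A_SF = A * Phi = w * l.

    Returns Phi = A_SF / A and the implied total fiber length
    ``l_hat = A * Phi / w``; when the measured total length is supplied the
    relative consistency error |l_hat - l| / l is reported too.
    """
    area = cell.area_px
    if area == 0:
        raise EmptyMaskError("area-ratio model undefined for zero cell area")
    sf = as_array(binary_sf)
    a_sf = int((sf > (127 if sf.max() > 1 else 0)).sum())
    phi = a_sf / area
    ell_hat = area * phi / fiber_width_w
    out = {"phi": float(phi), "sf_area_px": a_sf, "ell_hat": float(ell_hat)}
    if total_length is not None:
        if total_length <= 0:
            raise ValueError("total_length must be positive for consistency check")
        out["consistency_error"] = float(abs(ell_hat - total_length) / total_length)
    return out
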