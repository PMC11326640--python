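"""Shared containers and conventions.

Coordinates are (x, y) with x = column and y = row, origin at the top-left
pixel centre, 0-based.  Axial angles (fiber orientations) live on [0, pi) and
are measured from the +x axis toward +y.  Contours are ordered polylines with
positive shoelace area in (x, y) coordinates; the first point is not repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Native pixel pitch of the raw micrographs, um/px (8 px = 1.1 um).
RAW_PIXEL_SIZE_UM = 0.1375


class SFDiffError(Exception):
    """Base class for package errors."""


class NoForegroundError(SFDiffError):
    """Raised when outline extraction finds no cell in the image."""


class EmptyMaskError(SFDiffError):
    """Raised when an operation requires a non-empty mask."""


class EmptySegmentsError(SFDiffError):
    """Raised when fiber statistics are requested for an empty segment set."""


@dataclass
class ImageGrid:
    """2-D intensity raster with physical pixel size and value-range metadata."""

    data: np.ndarray
    pixel_size: float = RAW_PIXEL_SIZE_UM
    vrange: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("ImageGrid requires a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def as_array(image) -> np.ndarray:
    """Return the raw 2-D array behind an ImageGrid (or pass arrays through)."""
    if isinstance(image, ImageGrid):
        return image.data
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    return arr


def contour_length(contour: np.ndarray, closed: bool = True) -> float:
    """Polyline length of an (N, 2) contour; closed contours wrap around."""
    pts = np.asarray(contour, dtype=float)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _signed_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def orient_ccw(contour: np.ndarray) -> np.ndarray:
    """Orient a closed contour to positive shoelace area in (x, y)."""
    contour = np.asarray(contour, dtype=float)
    if _signed_area(contour) < 0:
        contour = contour[::-1]
    return contour


@dataclass
class CellMask:
    """Binary foreground mask plus its ordered closed contour."""

    mask: np.ndarray
    contour: np.ndarray
    pixel_size: float = RAW_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.contour = orient_ccw(np.asarray(self.contour, dtype=float))

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size**2

    @property
    def perimeter_px(self) -> float:
        return contour_length(self.contour)

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(xs.mean()), float(ys.mean())


@dataclass
class SegmentSet:
    """Straight fiber segments as an (M, 4) table of (x1, y1, x2, y2) pixels."""

    segments: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float).reshape(-1, 4)

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def count(self) -> int:
        return len(self)

    @property
    def lengths(self) -> np.ndarray:
        d = self.segments[:, 2:4] - self.segments[:, 0:2]
        return np.linalg.norm(d, axis=1)

    @property
    def angles(self) -> np.ndarray:
        """Axial angles phi_m in [0, pi)."""
        d = self.segments[:, 2:4] - self.segments[:, 0:2]
        return np.mod(np.arctan2(d[:, 1], d[:, 0]), np.pi)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def weights(self) -> np.ndarray:
        """Length weights omega_m = l_m / l (sum to 1 for M >= 1)."""
        ell = self.total_length
        if ell == 0:
            raise EmptySegmentsError("weights undefined for an empty segment set")
        return self.lengths / ell

    def to_table(self):
        import pandas as pd

        df = pd.DataFrame(self.segments, columns=["x1", "y1", "x2", "y2"])
        df["length_px"] = self.lengths
        df["angle_rad"] = self.angles
        return df
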