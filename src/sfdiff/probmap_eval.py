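"""Probability-field aggregation and grid ROC evaluation.

Generation is stochastic, so predictions are summarised by the per-pixel
probability ``P = N_S / N_I``: the fraction of ``N_I`` generated images in
which the pixel is classified as stress fiber (8-bit value >= 128).  For
comparison against a reference segmentation, the raster is divided into
coarse grids (64 x 64 grids over the full-resolution field of view, i.e.
2.2 um per grid); a grid is an SF grid if any pixel inside it is
foreground.  Extracellular grids are excluded and the ROC curve is swept
over thresholds P_th, with the operating point chosen nearest the ideal
(FPR, TPR) = (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CellMask, SFDiffError, as_array

__all__ = [
    "ProbabilityField",
    "GridLabels",
    "RocResult",
    "aggregate_P",
    "grid_labels",
    "roc",
    "prediction_errors",
]


@dataclass
class ProbabilityField:
    P: np.ndarray
    n_images: int
    bin_threshold: int = 128
    cell_mask: CellMask | None = None

    def __post_init__(self) -> None:
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("P must lie in [0, 1]")


@dataclass
class GridLabels:
    labels: np.ndarray        # boolean (gh, gw)
    intracellular: np.ndarray  # boolean (gh, gw)
    grid_shape: tuple[int, int]
    cell_size_px: tuple[int, int]


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    best_threshold: float


def aggregate_P(samples, bin_threshold: int = 128,
                cell_mask: CellMask | None = None) -> ProbabilityField:
    """Pixel-wise fraction of samples whose 8-bit value is >= threshold."""
    if not samples:
        raise ValueError("need at least one sample")
    arrs = [as_array(s) for s in samples]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("samples must share one shape")
    stack = np.stack([a >= bin_threshold for a in arrs])
    return ProbabilityField(
        P=stack.mean(axis=0),
        n_images=len(arrs),
        bin_threshold=bin_threshold,
        cell_mask=cell_mask,
    )


def _block_any(arr: np.ndarray, gh: int, gw: int) -> np.ndarray:
    """Per-grid OR; the raster is zero-padded right/bottom to a multiple."""
    h, w = arr.shape
    ch, cw = -(-h // gh), -(-w // gw)  # ceil cell sizes
    padded = np.zeros((ch * gh, cw * gw), dtype=bool)
    padded[:h, :w] = arr
    return padded.reshape(gh, ch, gw, cw).any(axis=(1, 3)), (ch, cw)


def grid_labels(raster, cell_mask: CellMask | np.ndarray,
                p_threshold: float | None = None,
                grid_shape: tuple[int, int] = (64, 64)) -> GridLabels:
    """Label each grid as SF/non-SF and intracellular/extracellular.

    ``raster`` may be a binary image, or a probability field when
    ``p_threshold`` is given (foreground where ``P > P_th``).  A grid is SF
    if at least one constituent pixel is foreground, and intracellular if at
    least one pixel lies inside the cell; padded grids are extracellular.
    """
    arr = as_array(raster)
    if p_threshold is not None:
        fg = arr > p_threshold
    else:
        fg = arr > (127 if arr.max() > 1 else 0)
    mask = cell_mask.mask if isinstance(cell_mask, CellMask) else np.asarray(
        cell_mask, dtype=bool)
    gh, gw = grid_shape
    labels, cell_sz = _block_any(fg, gh, gw)
    intra, _ = _block_any(mask, gh, gw)
    return GridLabels(labels=labels, intracellular=intra,
                      grid_shape=grid_shape, cell_size_px=cell_sz)


def _grid_scores(field: ProbabilityField, grid_shape) -> np.ndarray:
    """Per-grid score = max P inside the grid (a grid turns SF at P_th just
    below its max), zero-padded like the labels."""
    gh, gw = grid_shape
    h, w = field.P.shape
    ch, cw = -(-h // gh), -(-w // gw)
    padded = np.zeros((ch * gh, cw * gw))
    padded[:h, :w] = field.P
    return padded.reshape(gh, ch, gw, cw).max(axis=(1, 3))


def roc(field: ProbabilityField, truth: GridLabels) -> RocResult:
    """Grid ROC of a probability field against reference grid labels.

    Sweeps P_th over the unique intracellular grid scores plus the {0, 1}
    endpoints; AUC by the trapezoid rule; the best threshold minimises the
    Euclidean distance to (FPR, TPR) = (0, 1).
    """
    scores = _grid_scores(field, truth.grid_shape)
    keep = truth.intracellular
    y = truth.labels[keep]
    s = scores[keep]
    if y.all() or not y.any():
        raise SFDiffError("ROC undefined: truth grids are a single class")
    ths = np.unique(np.concatenate([s, [0.0, 1.0]]))
    pos = y.sum()
    neg = y.size - pos
    tpr = np.array([(s > t)[y].sum() / pos for t in ths])
    fpr = np.array([(s > t)[~y].sum() / neg for t in ths])
    # strict thresholds never produce the all-positive corner; append the
    # trivial (0,0)/(1,1) endpoints for integration
    f_ext = np.concatenate([fpr, [0.0, 1.0]])
    t_ext = np.concatenate([tpr, [0.0, 1.0]])
    order = np.lexsort((t_ext, f_ext))
    auc = float(np.trapezoid(t_ext[order], f_ext[order]))
    best = ths[np.argmin(np.hypot(fpr - 0.0, tpr - 1.0))]
    return RocResult(thresholds=ths, fpr=fpr, tpr=tpr, auc=auc,
                     best_threshold=float(best))


def prediction_errors(pred_stats, real_stats,
                      small_angle: float = 0.1) -> dict:
    """Relative errors of predicted vs reference fiber summary statistics.

    ``*_stats`` are (total_length, principal_direction) pairs.  Errors are
    |l_p - l_r| / l_r and |phi_p - phi_r| / phi_r with both angles reduced
    to [0, pi).  The direction error divides by the reference angle, which
    is frame dependent; references below ``small_angle`` radians are flagged
    (``direction_reference_small``) since the quotient then loses meaning.
    """
    ell_p, phi_p = float(pred_stats[0]), float(pred_stats[1])
    ell_r, phi_r = float(real_stats[0]), float(real_stats[1])
    if ell_r == 0:
        raise ZeroDivisionError("reference total length is zero")
    if phi_r == 0:
        raise ZeroDivisionError("reference direction is zero")
    phi_p = float(np.mod(phi_p, np.pi))
    phi_r = float(np.mod(phi_r, np.pi))
    return {
        "length_error": abs(ell_p - ell_r) / ell_r,
        "direction_error": abs(phi_p - phi_r) / phi_r,
        "direction_reference_small": phi_r < small_angle,
    }
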