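"""Extract a cell mask from a noisy synthetic micrograph.

Renders a realistic fluorescence image (fibers + textured cytoplasm +
sensor noise), runs the outline pipeline (downsample, smooth, adaptive
threshold, morphology, largest component, hole filling) and reports how
well the recovered mask matches the generator's truth.
"""

import numpy as np

from sfdiff import (
    FiberModel,
    ShapeSpec,
    extract_outline,
    make_fibers,
    make_shape,
    render_micrograph,
)
from sfdiff.fixtures import SyntheticPair

spec = ShapeSpec(kind="blob", aspect_ratio=2.0, area=1.8e3, resolution=256,
                 pixel_size=0.55, orientation=0.6, seed=4)
cell = make_shape(spec)
img, segs = make_fibers(cell, FiberModel(n_fibers=25, seed=5,
                                         length_range=(25, 60)))
raw = render_micrograph(SyntheticPair(cell, img, segs), seed=6)

recovered = extract_outline(raw)
iou = (recovered.mask & cell.mask).sum() / (recovered.mask | cell.mask).sum()

print(f"truth mask: {cell.area_px} px  ({cell.area_um2:.0f} um^2)")
print(f"recovered:  {recovered.area_px} px at "
      f"{recovered.mask.shape[0]}x{recovered.mask.shape[1]}")
print(f"IoU(recovered, truth) = {iou:.3f}")
print("IoU above ~0.9 means the adaptive-threshold pipeline found the cell")
print("outline despite fiber texture and background noise.")
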