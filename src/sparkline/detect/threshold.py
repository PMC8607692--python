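"""Traditional threshold-based spark detection.

The classical pipeline against which the learning-based detector is
compared: boxcar-smooth the normalized image, mark pixels brighter than
``mu + cri*sigma`` (``cri`` conventionally 3.8), extract 8-connected
components, discard tiny ones, and grow each survivor out to the
``mu + 2*sigma`` contour so the characterization stage sees the full event
footprint.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..linescan import BackgroundModel, DegenerateInputError, LineScanImage
from .boxes import SparkDetection

_STRUCT8 = np.ones((3, 3), dtype=int)


def smooth_boxcar(data: np.ndarray, wx: int = 3, wt: int = 3) -> np.ndarray:
    """Mean filter with reflective edges (wx pixels x wt lines)."""
    return ndimage.uniform_filter(data, size=(wx, wt), mode="reflect")


def detect_threshold(
    img: LineScanImage,
    bg: BackgroundModel,
    cri: float = 3.8,
    min_area: int = 8,
    smooth: tuple[int, int] = (3, 3),
    grow_sigma: float = 2.0,
) -> list[SparkDetection]:
    """Detect sparks by thresholding the smoothed image at mu + cri*sigma.

    Returns detections sorted by peak smoothed value, score fixed at 1.0
    (the method is binary).  Raises for non-normalized input or a
    zero-sigma background model.
    """
    if not img.normalized:
        raise ValueError("detect_threshold expects a normalized (F/F0) image")
    if bg.sigma <= 0:
        raise DegenerateInputError("background sigma must be positive")
    if cri <= 0 or min_area < 1:
        raise ValueError("cri must be > 0 and min_area >= 1")
    sm = smooth_boxcar(img.data, *smooth)
    core = sm > bg.mu + cri * bg.sigma
    if not core.any():
        return []
    support = sm > bg.mu + grow_sigma * bg.sigma
    labels_core, n_core = ndimage.label(core, structure=_STRUCT8)
    # area filter on the above-threshold core
    areas = ndimage.sum_labels(core, labels_core, index=np.arange(1, n_core + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        return []
    core_kept = np.isin(labels_core, keep)
    # grow: connected support components that contain a surviving core
    labels_sup, _ = ndimage.label(support, structure=_STRUCT8)
    sup_keep = np.unique(labels_sup[core_kept])
    sup_keep = sup_keep[sup_keep > 0]
    dets = []
    slices = ndimage.find_objects(labels_sup)
    for lab in sup_keep:
        sl = slices[lab - 1]
        box = (sl[0].start, sl[0].stop, sl[1].start, sl[1].stop)
        region = np.where(labels_sup[sl] == lab, sm[sl], -np.inf)
        px, pt = np.unravel_index(np.argmax(region), region.shape)
        peak = (box[0] + int(px), box[2] + int(pt))
        dets.append(
            SparkDetection(box=box, score=1.0, source="threshold", peak_xy=peak)
        )
    dets.sort(key=lambda d: -sm[d.peak_xy])
    return dets
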