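"""Line-scan image I/O, F/F0 normalization and background statistics.

A confocal line-scan records one spatial line repeatedly, producing a 2-D
image with space along one axis and time along the other.  Throughout this
package the convention is ``data[x, t]``: axis 0 is space (pixels along the
scan line, ``dx`` micrometres per pixel) and axis 1 is time (scan lines,
``dt`` milliseconds per line).  All bounding boxes are half-open
``[start, end)`` in pixel/line units.

Fluorescence is analysed as F/F0, the raw signal divided by a per-position
baseline F0.  Background statistics (mu, sigma) of the normalized image are
estimated with iterative exclusion of candidate events so that sparks do not
inflate sigma.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import tifffile
from scipy import ndimage


class FormatError(ValueError):
    """Raised when an image file is not a single-channel grayscale TIFF."""


class DegenerateInputError(ValueError):
    """Raised for inputs with no noise structure (e.g. constant images)."""


@dataclass(frozen=True)
class LineScanImage:
    """A space x time fluorescence matrix with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (n_space, n_time)
        Non-negative intensities; F/F0 if ``normalized`` is True.
    dx : float
        Micrometres per spatial pixel.
    dt : float
        Milliseconds per scan line (2.5 ms at 400 lines/s).
    normalized : bool
        True once the image has been divided by its baseline F0.
    """

    data: np.ndarray
    dx: float
    dt: float
    normalized: bool = False

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise FormatError(f"expected a 2-D image, got shape {data.shape}")
        if data.shape[0] < 8 or data.shape[1] < 8:
            raise ValueError(f"image too small: {data.shape}; need >= 8 in both axes")
        if not np.all(np.isfinite(data)):
            raise ValueError("image contains non-finite values")
        if data.min() < 0:
            raise ValueError("image contains negative intensities")
        if not (self.dx > 0 and self.dt > 0):
            raise ValueError("dx and dt must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_space(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def scan_length_um(self) -> float:
        return self.n_space * self.dx

    @property
    def duration_s(self) -> float:
        return self.n_time * self.dt / 1000.0


@dataclass
class BackgroundModel:
    """Background statistics of a normalized line-scan image.

    ``mu`` and ``sigma`` are the mean and SD of pixels judged to be noise;
    ``mask`` is True on pixels excluded as candidate events; ``f0`` carries
    the per-pixel baseline when the model was built from a raw image.
    """

    mu: float
    sigma: float
    mask: np.ndarray
    iterations: int
    f0: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu": float(self.mu),
                "sigma": float(self.sigma),
                "iterations": int(self.iterations),
                "mask_fraction": float(self.mask.mean()),
            },
            sort_keys=True,
        )


def read_linescan(
    path,
    dx: float,
    dt: float,
    *,
    time_axis: int | None = None,
) -> LineScanImage:
    """Read a single-channel grayscale TIFF as a line-scan image.

    The longer axis is taken as time unless ``time_axis`` overrides it.
    8/16-bit integer and float TIFFs are accepted; RGB or multi-channel
    images raise :class:`FormatError`.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel grayscale TIFF, got shape {arr.shape}"
        )
    if arr.size == 0:
        raise ValueError(f"{path}: zero-sized image")
    if arr.dtype == np.bool_ or (arr.dtype.kind == "u" and arr.dtype.itemsize < 1):
        raise FormatError(f"{path}: unsupported bit depth {arr.dtype}")
    if time_axis is None:
        time_axis = 0 if arr.shape[0] >= arr.shape[1] else 1
    if time_axis == 0:
        arr = arr.T
    return LineScanImage(arr.astype(np.float64), dx=dx, dt=dt, normalized=False)


def write_linescan(path, img: LineScanImage) -> None:
    """Write the image as a float32 grayscale TIFF (space x time layout)."""
    tifffile.imwrite(str(path), img.data.astype(np.float32))


def compute_f0(img: LineScanImage, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-spatial-pixel baseline: mean of the lower half of each pixel's trace.

    For each spatial pixel the samples at or below the pixel's (unmasked)
    temporal median are averaged.  This is robust to sparks as long as they
    occupy less than half of the pixel's timeline.  Pixels whose whole trace
    is masked fall back to the global unmasked lower-half mean.
    """
    if img.normalized:
        raise ValueError("compute_f0 expects a raw (non-normalized) image")
    data = img.data
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise ValueError("mask shape must match image shape")
        if mask.all():
            raise ValueError("all pixels masked; cannot estimate F0")
    f0 = np.empty(data.shape[0])
    valid_all = data[~mask] if mask is not None else data.ravel()
    global_med = np.median(valid_all)
    global_f0 = valid_all[valid_all <= global_med].mean()
    for x in range(data.shape[0]):
        trace = data[x]
        if mask is not None:
            trace = trace[~mask[x]]
        if trace.size == 0:
            f0[x] = global_f0
            continue
        med = np.median(trace)
        f0[x] = trace[trace <= med].mean()
    if np.any(f0 <= 0):
        # dark pixels would blow up F/F0; fall back to the global baseline
        f0[f0 <= 0] = global_f0 if global_f0 > 0 else 1.0
    return f0


def normalize(img: LineScanImage, f0: np.ndarray) -> LineScanImage:
    """Divide each spatial pixel's trace by its baseline F0."""
    f0 = np.asarray(f0, dtype=np.float64)
    if f0.shape != (img.n_space,):
        raise ValueError(f"f0 must have length {img.n_space}, got {f0.shape}")
    if np.any(f0 <= 0):
        raise ValueError("f0 entries must be strictly positive")
    return replace(img, data=img.data / f0[:, None], normalized=True)


def estimate_background(
    img: LineScanImage,
    cri: float = 3.8,
    max_iter: int = 5,
    grow_sigma: float = 2.0,
) -> BackgroundModel:
    """Estimate mu/sigma of the noise floor with iterative event exclusion.

    Each pass masks pixels brighter than ``mu + cri*sigma`` together with
    their 8-connected neighbourhood above ``mu + grow_sigma*sigma`` (so spark
    flanks do not inflate sigma), then recomputes mu and sigma on the
    remaining pixels.  Stops when the mask is stable, ``max_iter`` is
    reached, or the mask would exceed half the image.
    """
    if not img.normalized:
        raise ValueError("estimate_background expects a normalized image")
    if cri <= 0:
        raise ValueError("cri must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    data = img.data
    mask = np.zeros(data.shape, dtype=bool)
    mu = float(data.mean())
    sigma = float(data.std())
    if sigma == 0:
        raise DegenerateInputError("constant image: background sigma is zero")
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        strong = data > mu + cri * sigma
        weak = data > mu + grow_sigma * sigma
        labels, n = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
        if n:
            keep = np.unique(labels[strong])
            keep = keep[keep > 0]
            new_mask = np.isin(labels, keep)
        else:
            new_mask = np.zeros_like(mask)
        if new_mask.mean() > 0.5:
            warnings.warn(
                "event mask would cover more than half the image; "
                "stopping background refinement",
                stacklevel=2,
            )
            break
        if np.array_equal(new_mask, mask) and iterations > 1:
            break
        mask = new_mask
        rest = data[~mask]
        mu = float(rest.mean())
        sigma = float(rest.std())
        if sigma == 0:
            raise DegenerateInputError("background sigma collapsed to zero")
    return BackgroundModel(mu=mu, sigma=sigma, mask=mask, iterations=iterations)


def normalize_image(img: LineScanImage, cri: float = 3.8) -> tuple[LineScanImage, BackgroundModel]:
    """Full baseline pipeline: F0 -> F/F0 -> background, with one refinement.

    A first normalization pass locates candidate events, whose mask is then
    fed back into the F0 estimate so bright events cannot bias the baseline.
    """
    f0 = compute_f0(img)
    norm = normalize(img, f0)
    bg = estimate_background(norm, cri=cri)
    if bg.mask.any():
        f0 = compute_f0(img, mask=bg.mask)
        norm = normalize(img, f0)
        bg = estimate_background(norm, cri=cri)
    bg.f0 = f0
    return norm, bg
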