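"""Fiber-orientation extraction from images and the degree of alignment.

Orientation is estimated with the local-gradient method: the intensity
gradient at a fiber edge points across the fiber, so the local fiber
orientation is the gradient direction rotated by 90 deg, weighted by the
squared gradient magnitude. Orientations are axial (mod 180 deg) and are
histogrammed into 180 one-degree bins centered at 0..179 deg.

Degree of alignment: the fraction of orientation mass inside the aligned
window around the flow axis (90 +- 22 deg, realized as the 46 integer
bins 68..113 so the uniform baseline is exactly 46/180 = 25.56%) divided
by that uniform baseline. 1.0 means isotropic; the maximum is 180/46.

Image convention: 2D grayscale arrays indexed (row, col); the y axis is
the row index, so angles are measured from the +x (column) axis toward
increasing rows. Axial statistics make the convention innocuous for all
the symmetric quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.restoration import rolling_ball

from .errors import UndefinedHistogramError
from .orientation_grid import DEFAULT_BOX_SIZE, GridSpec, OrientationGrid

log = logging.getLogger(__name__)

N_BINS = 180
ALIGNED_WINDOW = (68, 113)  # inclusive integer-degree bins, 46 of 180
UNIFORM_BASELINE = (ALIGNED_WINDOW[1] - ALIGNED_WINDOW[0] + 1) / N_BINS


@dataclass(frozen=True)
class AlignmentParams:
    """Aligned-window bins (inclusive) and the uniform baseline fraction."""

    window: tuple[int, int] = ALIGNED_WINDOW
    baseline: float = UNIFORM_BASELINE

    def __post_init__(self):
        lo, hi = self.window
        if not np.isclose((hi - lo + 1) / N_BINS, self.baseline):
            raise ValueError("window bin count / 180 must equal the baseline")


@dataclass
class OrientationHistogram:
    """180-bin axial orientation histogram, bin centers at 0..179 deg."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_BINS,) or (w < 0).any():
            raise ValueError("histogram needs 180 non-negative weights")
        self.weights = w

    @property
    def is_normalized(self):
        return np.isclose(self.weights.sum(), 1.0)

    def normalized(self):
        tot = self.weights.sum()
        if tot <= 0:
            raise UndefinedHistogramError("histogram has zero total weight")
        return OrientationHistogram(self.weights / tot)

    def modal_bin(self):
        return int(np.argmax(self.weights))

    @classmethod
    def uniform(cls):
        """Uniform reference histogram.

        Equal integer weights rather than 1/180: bin sums are then exact
        in floating point, so the aligned-window fraction is exactly
        46/180 and the degree of alignment exactly 1.0.
        """
        return cls(np.full(N_BINS, 1.0))


@dataclass(frozen=True)
class PreprocessParams:
    """Gaussian blur sigma (px), rolling-ball radius (px) and threshold
    ('otsu' or an absolute value on the background-subtracted image)."""

    gaussian_sigma: float = 2.0
    rolling_radius: float = 25.0
    threshold: object = "otsu"


@dataclass
class PreprocessResult:
    image: np.ndarray       # smoothed, background-subtracted
    mask: np.ndarray        # boolean foreground
    params: PreprocessParams
    empty_foreground: bool = False


def preprocess(image, params: PreprocessParams = PreprocessParams()):
    """Gaussian blur -> rolling-ball background subtraction -> threshold.

    An empty foreground (e.g. a constant image) is flagged with a warning
    and returned as an all-false mask rather than an error, so downstream
    operations can decide how to fail.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    smoothed = gaussian(img, sigma=params.gaussian_sigma, preserve_range=True)
    background = rolling_ball(smoothed, radius=params.rolling_radius)
    flat = smoothed - background
    if np.ptp(flat) == 0:
        log.warning("preprocess: constant image, empty foreground")
        return PreprocessResult(flat, np.zeros(img.shape, bool), params, True)
    thr = threshold_otsu(flat) if params.threshold == "otsu" else float(params.threshold)
    mask = flat > thr
    if not mask.any():
        log.warning("preprocess: empty foreground after thresholding")
        return PreprocessResult(flat, mask, params, True)
    return PreprocessResult(flat, mask, params, False)


def _gradient_orientation(image):
    """Per-pixel axial orientation (deg) and squared-gradient weight."""
    img = np.asarray(image, dtype=float)
    gx = ndi.sobel(img, axis=1)
    gy = ndi.sobel(img, axis=0)
    weight = gx**2 + gy**2
    angle = (np.degrees(np.arctan2(gy, gx)) + 90.0) % 180.0
    return angle, weight


def orientation_histogram(image, mask=None) -> OrientationHistogram:
    """Normalized 180-bin orientation histogram over the foreground.

    Raises ``UndefinedHistogramError`` when the total gradient weight is
    zero (e.g. a constant image).
    """
    angle, weight = _gradient_orientation(image)
    if mask is not None:
        weight = weight * np.asarray(mask, bool)
    bins = np.rint(angle).astype(int) % N_BINS
    hist = np.bincount(bins.ravel(), weights=weight.ravel(), minlength=N_BINS)
    total = hist.sum()
    if total <= 0:
        raise UndefinedHistogramError("zero total gradient weight")
    return OrientationHistogram(hist / total)


def degree_of_alignment(hist: OrientationHistogram,
                        params: AlignmentParams = AlignmentParams()) -> float:
    """Aligned-window mass divided by the uniform baseline.

    Exactly 1.0 for a uniform histogram; 0 when no mass falls in the
    window; at most 180/46 when all mass is aligned.
    """
    total = hist.weights.sum()
    if total <= 0:
        raise UndefinedHistogramError("histogram has zero total weight")
    if not hist.is_normalized:
        log.info("degree_of_alignment: normalizing input histogram")
    lo, hi = params.window
    mass = hist.weights[lo:hi + 1].sum() / total
    return float(mass / params.baseline)


def orientation_grid_from_image(image, mask=None, pixel_size=1.0,
                                box_size=DEFAULT_BOX_SIZE,
                                origin=(0.0, 0.0)) -> OrientationGrid:
    """Per-box axial mean of local-gradient orientations.

    Pixel (row, col) maps to physical coordinates
    (origin + (col + 0.5, row + 0.5) * pixel_size). Boxes without any
    foreground weight are filled from the nearest valid box and flagged.
    """
    angle, weight = _gradient_orientation(image)
    if mask is not None:
        weight = weight * np.asarray(mask, bool)
    if weight.sum() <= 0:
        raise UndefinedHistogramError("no foreground gradient weight")
    ny_px, nx_px = angle.shape
    rows, cols = np.mgrid[0:ny_px, 0:nx_px]
    x = origin[0] + (cols + 0.5) * pixel_size
    y = origin[1] + (rows + 0.5) * pixel_size
    spec = GridSpec(
        nx=max(1, int(np.ceil(nx_px * pixel_size / box_size))),
        ny=max(1, int(np.ceil(ny_px * pixel_size / box_size))),
        box_size=box_size, origin=origin)
    return OrientationGrid.from_samples(spec, x, y, angle, weights=weight)
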