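"""Synthetic inputs: fiber images with known ground truth, spheroid masks
and tracer trajectories.

``render_fiber_image`` emulates a fluorescently labeled collagen channel:
anti-aliased line segments whose axial orientation follows a prescribed
field plus controllable axial jitter, blurred by a Gaussian PSF and
corrupted by Gaussian or Poisson noise. The ground-truth angle table is
returned alongside the image so orientation-extraction can be tested as a
round trip. All generators are reproducible bit-exactly from (spec, seed).

Image convention matches the analysis module: arrays are (row, col) with
y = row; physical coordinates are pixels times ``pixel_size`` (default
1 um/px, a declared synthetic scale -- the microscope pixel size is not
modeled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk, line_aa
from skimage.filters import gaussian

from .orientation_grid import OrientationGrid


@dataclass(frozen=True)
class ImageSpec:
    """Synthetic fiber-image parameters.

    size: (rows, cols) px; pixel_size: um/px; fiber lengths in um
    (normal distribution, truncated at 1 px); jitter_kappa: von Mises
    concentration on the doubled angle (higher = tighter alignment;
    ~0 = isotropic); background/amplitude in arbitrary counts;
    noise: 'gaussian' (sigma = noise_level) or 'poisson'.
    """

    size: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0
    n_fibers: int = 400
    fiber_length: float = 47.5
    fiber_length_sd: float = 10.0
    jitter_kappa: float = 8.0
    background: float = 10.0
    amplitude: float = 100.0
    noise: str = "gaussian"
    noise_level: float = 2.0
    psf_sigma: float = 1.0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.fiber_length < self.pixel_size:
            raise ValueError("fiber length must be at least one pixel")
        if self.noise not in ("gaussian", "poisson"):
            raise ValueError("noise must be 'gaussian' or 'poisson'")


def _clip_segment(p0, p1, shape):
    """Clip segment p0-p1 (row, col floats) to the image rectangle.

    Liang-Barsky parametric clipping; returns None when fully outside.
    """
    t0, t1 = 0.0, 1.0
    d = (p1[0] - p0[0], p1[1] - p0[1])
    for axis in (0, 1):
        lo, hi = 0.0, shape[axis] - 1.0
        p, q0 = d[axis], p0[axis]
        for sign, bound in ((-1.0, lo), (1.0, hi)):
            denom = sign * p
            num = sign * (bound - q0)
            if denom == 0:
                if num < 0:
                    return None
            else:
                t = num / denom
                if denom < 0:
                    t0 = max(t0, t)
                else:
                    t1 = min(t1, t)
        if t0 > t1:
            return None
    a = (p0[0] + t0 * d[0], p0[1] + t0 * d[1])
    b = (p0[0] + t1 * d[0], p0[1] + t1 * d[1])
    return a, b


def _field_angle(field, x, y):
    """Axial angle (deg) of the generating field at physical points."""
    if isinstance(field, OrientationGrid):
        return field.angle_at(np.column_stack([x, y]))
    return np.full(x.shape, float(field) % 180.0)


def render_fiber_image(field, spec: ImageSpec = ImageSpec(), seed=0):
    """Render a synthetic fiber image.

    ``field`` is an OrientationGrid (queried in physical image
    coordinates) or a single global axial angle in degrees. Fibers partly
    outside the canvas are clipped, not an error. Returns
    (image, truth) where ``truth`` is a DataFrame with one row per drawn
    fiber: center x/y (um), axial angle (deg) and length (um).
    """
    rng = np.random.default_rng(seed)
    ny, nx = spec.size
    img = np.zeros((ny, nx), dtype=float)
    w_um = nx * spec.pixel_size
    h_um = ny * spec.pixel_size
    cx = rng.uniform(0.0, w_um, spec.n_fibers)
    cy = rng.uniform(0.0, h_um, spec.n_fibers)
    base = _field_angle(field, cx, cy)
    if spec.jitter_kappa > 0:
        jit = rng.vonmises(0.0, spec.jitter_kappa, spec.n_fibers) / 2.0
    else:
        jit = rng.uniform(-np.pi / 2.0, np.pi / 2.0, spec.n_fibers)
    angle = (base + np.degrees(jit)) % 180.0
    length = np.clip(rng.normal(spec.fiber_length, spec.fiber_length_sd,
                                spec.n_fibers),
                     spec.pixel_size, None)
    th = np.radians(angle)
    half = length / 2.0
    for i in range(spec.n_fibers):
        dx, dy = half[i] * np.cos(th[i]), half[i] * np.sin(th[i])
        p0 = ((cy[i] - dy) / spec.pixel_size, (cx[i] - dx) / spec.pixel_size)
        p1 = ((cy[i] + dy) / spec.pixel_size, (cx[i] + dx) / spec.pixel_size)
        seg = _clip_segment(p0, p1, (ny, nx))
        if seg is None:
            continue
        rr, cc, val = line_aa(int(round(seg[0][0])), int(round(seg[0][1])),
                              int(round(seg[1][0])), int(round(seg[1][1])))
        img[rr, cc] += val * spec.amplitude
    if spec.psf_sigma > 0:
        img = gaussian(img, sigma=spec.psf_sigma, preserve_range=True)
    img = img + spec.background
    if spec.noise == "gaussian":
        img = img + rng.normal(0.0, spec.noise_level, img.shape)
    else:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    truth = pd.DataFrame({"x": cx, "y": cy, "angle_deg": angle,
                          "length_um": length})
    return img, truth


def spheroid_mask(center, radius, spec: ImageSpec = ImageSpec()):
    """Binary disk mask (physical um coordinates; clipped at the canvas)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    mask = np.zeros(spec.size, dtype=bool)
    rr, cc = disk((center[1] / spec.pixel_size, center[0] / spec.pixel_size),
                  radius / spec.pixel_size, shape=spec.size)
    mask[rr, cc] = True
    return mask


def tracer_trajectories(model, n=20, dt=5.0, T=1500.0, seed=0,
                        band_width=None, start_y=None):
    """Passive tracer polylines advected by the flow (RK2 midpoint).

    Tracers are released on a horizontal line upstream of the obstacle,
    uniformly over ``band_width`` (default: four obstacle diameters)
    centered on the flow axis. Mirrors the minimum-projection overlays of
    bead movies recorded during polymerization.
    """
    rng = np.random.default_rng(seed)
    a = model.obstacle.radius
    cx, cy = model.obstacle.center
    bw = 8.0 * a if band_width is None else band_width
    y0 = cy + 6.0 * a if start_y is None else start_y
    xs = cx + rng.uniform(-bw / 2.0, bw / 2.0, n)
    trajs = []
    for x0 in xs:
        p = np.array([x0, y0])
        pts = [p.copy()]
        for _ in range(int(T / dt)):
            try:
                v1 = model.velocity(p)
                pm = p + 0.5 * dt * v1
                rm = np.hypot(pm[0] - cx, pm[1] - cy)
                if rm < a:
                    pm = np.array([cx, cy]) + (pm - [cx, cy]) * (a / rm)
                v2 = model.velocity(pm)
            except Exception:
                break
            p = p + dt * v2
            r = np.hypot(p[0] - cx, p[1] - cy)
            if r < a:
                p = np.array([cx, cy]) + (p - [cx, cy]) * (a / r)
            if (abs(p[0]) > model.geometry.width / 2.0
                    or abs(p[1]) > model.geometry.length / 2.0):
                break
            pts.append(p.copy())
        trajs.append(np.array(pts))
    return trajs
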