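"""Box-averaged fiber-orientation fields.

The invasion model consumes a per-box mean fiber orientation alpha(x, y)
computed on square boxes of side d = 103 um, the same discretization used
when extracting orientations from images. Boxes hold an axial angle in
[0, 180) deg (90 deg = flow axis), a sample count and a coherence value
(resultant length of the doubled-angle vectors).

The grid is total: every query point maps to exactly one box (indices are
clamped at the edges, so points outside the gridded field of view receive
the nearest box angle), and boxes without samples are filled from their
nearest sampled box and flagged, so cells inside the spheroid still see a
defined orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .axial import wrap_axial

DEFAULT_BOX_SIZE = 103.0  # um


@dataclass
class GridSpec:
    """Geometry of an orientation grid.

    ``origin`` is the lower-left corner of box (0, 0) in physical
    coordinates (um). ``centered`` builds a grid whose central box center
    coincides with a given point (the spheroid center by convention).
    """

    nx: int = 20
    ny: int = 20
    box_size: float = DEFAULT_BOX_SIZE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or self.box_size <= 0:
            raise ValueError("grid must have positive shape and box size")

    @classmethod
    def centered(cls, center=(0.0, 0.0), nx=20, ny=20, box_size=DEFAULT_BOX_SIZE):
        ox = center[0] - (nx // 2) * box_size - box_size / 2.0
        oy = center[1] - (ny // 2) * box_size - box_size / 2.0
        return cls(nx=nx, ny=ny, box_size=box_size, origin=(ox, oy))

    def box_centers(self):
        """(X, Y) meshgrids of box-center coordinates, shape (ny, nx)."""
        x = self.origin[0] + (np.arange(self.nx) + 0.5) * self.box_size
        y = self.origin[1] + (np.arange(self.ny) + 0.5) * self.box_size
        return np.meshgrid(x, y)


class OrientationGrid:
    """Axial orientation field on a regular box grid.

    Parameters
    ----------
    spec : GridSpec
    angle : (ny, nx) array of axial angles, degrees in [0, 180)
    count : per-box sample count (0 for boxes filled by propagation)
    coherence : per-box resultant length in [0, 1]
    filled : boolean mask of boxes that had no samples and were filled
        from the nearest sampled box
    analytic : optional callable mapping an (n, 2) array of points to
        axial angles in degrees; when present, ``angle_at`` evaluates it
        instead of the box lookup. Used by the canonical test fields whose
        geometry is exact (e.g. a radial field must be radial at the query
        point, not at the box center).
    """

    def __init__(self, spec, angle, count=None, coherence=None, filled=None,
                 analytic=None):
        self.spec = spec
        self.angle = wrap_axial(np.asarray(angle, dtype=float))
        if self.angle.shape != (spec.ny, spec.nx):
            raise ValueError("angle array shape does not match grid spec")
        self.count = (np.zeros_like(self.angle) if count is None
                      else np.asarray(count, dtype=float))
        self.coherence = (np.ones_like(self.angle) if coherence is None
                          else np.asarray(coherence, dtype=float))
        self.filled = (np.zeros(self.angle.shape, dtype=bool) if filled is None
                       else np.asarray(filled, dtype=bool))
        self.analytic = analytic

    # ------------------------------------------------------------------ #

    def box_index(self, points):
        """Clamped (iy, ix) box indices for an (n, 2) array of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.spec.box_size
        ix = np.clip(((p[:, 0] - self.spec.origin[0]) // d).astype(int),
                     0, self.spec.nx - 1)
        iy = np.clip(((p[:, 1] - self.spec.origin[1]) // d).astype(int),
                     0, self.spec.ny - 1)
        return iy, ix

    def angle_at(self, points):
        """Axial angle (deg) at each query point; total over the plane."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self.analytic is not None:
            return wrap_axial(np.asarray(self.analytic(p), dtype=float))
        iy, ix = self.box_index(p)
        return self.angle[iy, ix]

    # ------------------------------------------------------------------ #

    @classmethod
    def from_samples(cls, spec, x, y, angles_deg, weights=None, analytic=None):
        """Bin axial angle samples into boxes (doubled-angle vector mean).

        Empty boxes are filled from the nearest sampled box and flagged.
        Raises ``ValueError`` when there are no samples at all.
        """
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        a2 = np.radians(2.0 * np.asarray(angles_deg, dtype=float).ravel())
        w = (np.ones_like(x) if weights is None
             else np.asarray(weights, dtype=float).ravel())
        d = spec.box_size
        ix = ((x - spec.origin[0]) // d).astype(int)
        iy = ((y - spec.origin[1]) // d).astype(int)
        keep = (ix >= 0) & (ix < spec.nx) & (iy >= 0) & (iy < spec.ny) & (w > 0)
        if not keep.any():
            raise ValueError("no samples fall inside the grid")
        ix, iy, a2, w = ix[keep], iy[keep], a2[keep], w[keep]
        C = np.zeros((spec.ny, spec.nx))
        S = np.zeros((spec.ny, spec.nx))
        W = np.zeros((spec.ny, spec.nx))
        N = np.zeros((spec.ny, spec.nx))
        np.add.at(C, (iy, ix), w * np.cos(a2))
        np.add.at(S, (iy, ix), w * np.sin(a2))
        np.add.at(W, (iy, ix), w)
        np.add.at(N, (iy, ix), 1.0)
        angle = np.degrees(np.arctan2(S, C)) / 2.0 % 180.0
        coher = np.where(W > 0, np.hypot(C, S) / np.where(W > 0, W, 1.0), 0.0)
        empty = W == 0
        if empty.any():
            jj, ii = distance_transform_edt(empty, return_indices=True,
                                            return_distances=False)
            angle = angle[jj, ii]
            coher = coher[jj, ii]
        return cls(spec, angle, count=N, coherence=coher, filled=empty,
                   analytic=analytic)

    # ------------------------------------------------------------------ #
    # serialization: long-form CSV plus a JSON metadata side-car

    def to_frame(self):
        iy, ix = np.mgrid[0:self.spec.ny, 0:self.spec.nx]
        return pd.DataFrame({
            "iy": iy.ravel(), "ix": ix.ravel(),
            "angle_deg": self.angle.ravel(),
            "count": self.count.ravel(),
            "coherence": self.coherence.ravel(),
            "filled": self.filled.ravel().astype(int),
        })

    def to_csv(self, path):
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {"nx": self.spec.nx, "ny": self.spec.ny,
                "box_size": self.spec.box_size,
                "origin": list(self.spec.origin)}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))
        return path

    @classmethod
    def from_csv(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        spec = GridSpec(nx=meta["nx"], ny=meta["ny"], box_size=meta["box_size"],
                        origin=tuple(meta["origin"]))
        df = pd.read_csv(path)
        shape = (spec.ny, spec.nx)
        g = {k: np.zeros(shape) for k in ("angle_deg", "count", "coherence", "filled")}
        for k in g:
            g[k][df["iy"], df["ix"]] = df[k]
        return cls(spec, g["angle_deg"], count=g["count"],
                   coherence=g["coherence"], filled=g["filled"].astype(bool))
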