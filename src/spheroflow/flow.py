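"""Depth-averaged channel flow around an immobilized spheroid.

The microfluidic chamber is shallow (height 0.4 mm versus width 3.8 mm) and
the flow rate of 0.2 ul/min puts the Reynolds number far below one. In that
Hele-Shaw limit the depth-averaged in-plane velocity is a potential flow,
and the flow past a rigid circular obstacle has the classical closed form
"uniform stream + doublet". Working with the complex velocity makes both
the velocity and its gradient exact, which is what the rod kinematics and
the test oracles need.

Coordinate convention: origin at the obstacle center, main flow along -y
(top to bottom), so orientation angle 90 deg is the flow axis. Side-wall
no-slip is neglected (obstacle diameter ~0.2 mm << channel width 3.8 mm).

Units: lengths in um, time in s, flow rate in ul/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError, OutOfDomainError

UL_PER_MIN_TO_UM3_PER_S = 1.0e9 / 60.0


@dataclass(frozen=True)
class ChannelGeometry:
    """Microfluidic channel footprint and inflow.

    width/length/height in um (defaults: 3.8 mm x 17 mm x 0.4 mm),
    flow_rate in ul/min (default 0.2).
    """

    width: float = 3800.0
    length: float = 17000.0
    height: float = 400.0
    flow_rate: float = 0.2

    def __post_init__(self):
        if min(self.width, self.length, self.height) <= 0:
            raise InvalidGeometryError("channel dimensions must be positive")
        if self.flow_rate < 0:
            raise InvalidGeometryError("flow rate must be non-negative")
        if self.height > self.width:
            raise InvalidGeometryError("shallow-channel model needs height <= width")


@dataclass(frozen=True)
class ObstacleSpec:
    """Immobilized spheroid treated as a rigid impermeable disk.

    center in um (channel coordinates), diameter in um (default 208,
    a HeLa aggregate).
    """

    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 208.0

    @property
    def radius(self):
        return self.diameter / 2.0

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidGeometryError("obstacle diameter must be positive")


def mean_inflow_speed(geometry: ChannelGeometry) -> float:
    """Mean inflow speed U = Q / (width x height), in um/s."""
    q = geometry.flow_rate * UL_PER_MIN_TO_UM3_PER_S
    return q / (geometry.width * geometry.height)


@dataclass(frozen=True)
class FlowModel:
    """Potential flow past a disk in a uniform stream along -y.

    Complex velocity (u - i v) at position z relative to the obstacle
    center: f(z) = i U (1 + a^2 / z^2); far field (0, -U), zero normal
    velocity on |z| = a, divergence- and curl-free away from the disk.
    """

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    obstacle: ObstacleSpec = field(default_factory=ObstacleSpec)

    def __post_init__(self):
        cx, cy = self.obstacle.center
        a = self.obstacle.radius
        if (abs(cx) + a > self.geometry.width / 2.0
                or abs(cy) + a > self.geometry.length / 2.0):
            raise InvalidGeometryError("obstacle not fully inside the channel")

    @property
    def mean_speed(self) -> float:
        return mean_inflow_speed(self.geometry)

    # ------------------------------------------------------------------ #

    def _rel(self, points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        cx, cy = self.obstacle.center
        return (p[:, 0] - cx) + 1j * (p[:, 1] - cy)

    def _check_domain(self, points, z):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a = self.obstacle.radius
        if np.any(np.abs(z) < a * (1.0 - 1e-9)):
            raise OutOfDomainError("point inside the obstacle")
        if (np.any(np.abs(p[:, 0]) > self.geometry.width / 2.0)
                or np.any(np.abs(p[:, 1]) > self.geometry.length / 2.0)):
            raise OutOfDomainError("point outside the channel footprint")

    def velocity(self, points):
        """Velocity (um/s) at one point (2,) or many points (n, 2)."""
        pts = np.asarray(points, dtype=float)
        z = self._rel(pts)
        self._check_domain(pts, z)
        f = 1j * self.mean_speed * (1.0 + self.obstacle.radius**2 / z**2)
        v = np.column_stack([f.real, -f.imag])
        return v[0] if pts.ndim == 1 else v

    def velocity_gradient(self, points):
        """Velocity-gradient tensor L_ij = dv_i/dx_j (1/s).

        From the analytic derivative f'(z) = -2 i U a^2 / z^3 with
        f = u - i v: u_x = Re f', v_x = -Im f'; irrotationality gives
        u_y = v_x and incompressibility v_y = -u_x, so L is symmetric and
        traceless.
        """
        pts = np.asarray(points, dtype=float)
        z = self._rel(pts)
        self._check_domain(pts, z)
        fp = -2j * self.mean_speed * self.obstacle.radius**2 / z**3
        ux, vx = fp.real, -fp.imag
        L = np.empty(z.shape + (2, 2))
        L[..., 0, 0] = ux
        L[..., 0, 1] = vx
        L[..., 1, 0] = vx
        L[..., 1, 1] = -ux
        return L[0] if pts.ndim == 1 else L

    # ------------------------------------------------------------------ #

    def streamline(self, start, step=5.0, n_steps=2000):
        """Integrate a streamline with classical 4th-order Runge-Kutta.

        ``step`` is the time step in seconds. Integration stops when the
        path would leave the channel footprint or touch the obstacle
        (overshoot is clipped back to the boundary); at a stagnation point
        it simply stops advancing. Returns an (m, 2) polyline.
        """
        x = np.asarray(start, dtype=float)
        z0 = self._rel(x)
        self._check_domain(x, z0)
        a = self.obstacle.radius
        cx, cy = self.obstacle.center
        pts = [x.copy()]

        def vel_or_none(p):
            try:
                return self.velocity(p)
            except OutOfDomainError:
                return None

        for _ in range(n_steps):
            k1 = vel_or_none(x)
            if k1 is None:
                break
            k2 = vel_or_none(x + 0.5 * step * k1)
            k3 = vel_or_none(x + 0.5 * step * k2) if k2 is not None else None
            k4 = vel_or_none(x + step * k3) if k3 is not None else None
            if k2 is None or k3 is None or k4 is None:
                break
            x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            r = np.hypot(x[0] - cx, x[1] - cy)
            if r < a:  # clip overshoot back onto the obstacle surface
                x = np.array([cx, cy]) + (x - [cx, cy]) * (a / r)
            if (abs(x[0]) > self.geometry.width / 2.0
                    or abs(x[1]) > self.geometry.length / 2.0):
                break
            pts.append(x.copy())
        return np.array(pts)

    # ------------------------------------------------------------------ #

    def sample_grid(self, extent, n=41):
        """Velocity field on a square grid for export/plotting.

        Returns a DataFrame (x, y, vx, vy); points inside the obstacle get
        NaN velocities.
        """
        import pandas as pd

        xs = np.linspace(-extent, extent, n)
        X, Y = np.meshgrid(xs, xs)
        p = np.column_stack([X.ravel(), Y.ravel()])
        z = self._rel(p)
        inside = np.abs(z) < self.obstacle.radius
        v = np.full((len(p), 2), np.nan)
        if (~inside).any():
            v[~inside] = self.velocity(p[~inside])
        return pd.DataFrame({"x": p[:, 0], "y": p[:, 1],
                             "vx": v[:, 0], "vy": v[:, 1]})
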