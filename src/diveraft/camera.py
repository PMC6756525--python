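"""Pinhole camera model for an elevated, obliquely inclined shore camera.

The camera sits ``elevation`` metres above a flat sea surface and looks
down-range; ``inclination`` is the angle from the vertical to the ray
through the *bottom edge* of the sensor (the steepest visible ray), so
the optical axis points ``inclination + vfov/2`` from vertical.  Pixel
coordinates are 0-based with the origin at the top-left corner, x (u)
rightward and y (v) downward; ground coordinates are metres with the
camera base at the origin, y increasing away from the camera and x to
the right.  Forward projection and back-projection are exact inverses on
the visible ground footprint.

A negative ``inclination`` is permitted so the optical axis can pass
through the nadir (bottom-edge ray behind the vertical), in which limit
the pixel-to-ground map becomes a pure similarity transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["CameraModel"]


@dataclass(frozen=True)
class CameraModel:
    elevation: float = 31.6  # metres above the sea surface
    inclination: float = 79.46  # degrees from vertical to the bottom sensor edge
    heading: float = 0.0  # degrees; metadata only, projection is camera-frame
    fps: float = 25.0
    width: int = 1920
    height: int = 1080
    hfov: float = 10.0  # horizontal field of view, degrees

    def __post_init__(self) -> None:
        if not self.elevation > 0:
            raise ValueError("elevation must be positive")
        if not -90.0 < self.inclination < 90.0:
            raise ValueError("inclination must be in (-90, 90) degrees")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("resolution must be positive")
        if not 0 < self.hfov < 180:
            raise ValueError("hfov must be in (0, 180) degrees")

    # -- intrinsic geometry -------------------------------------------
    @property
    def focal_px(self) -> float:
        return (self.width / 2.0) / math.tan(math.radians(self.hfov) / 2.0)

    @property
    def cx(self) -> float:
        return (self.width - 1) / 2.0

    @property
    def cy(self) -> float:
        return (self.height - 1) / 2.0

    @property
    def vfov_half(self) -> float:
        """Half the vertical field of view, degrees."""
        return math.degrees(math.atan((self.height / 2.0) / self.focal_px))

    @property
    def axis_inclination(self) -> float:
        """Optical-axis angle from the vertical, degrees."""
        return self.inclination + self.vfov_half

    def _basis(self):
        a = math.radians(self.axis_inclination)
        axis = np.array([0.0, math.sin(a), -math.cos(a)])
        down = np.array([0.0, -math.cos(a), -math.sin(a)])  # image +v direction
        right = np.array([1.0, 0.0, 0.0])
        return right, down, axis

    # -- projections ---------------------------------------------------
    def project(self, x_m, y_m):
        """Ground (metres) -> pixel (u, v).  Points behind the camera plane
        (non-positive depth along the optical axis) come back as NaN."""
        x_m = np.asarray(x_m, dtype=float)
        y_m = np.asarray(y_m, dtype=float)
        right, down, axis = self._basis()
        vx, vy, vz = x_m, y_m, -self.elevation
        w = vy * axis[1] + vz * axis[2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.cx + self.focal_px * (vx * right[0]) / w
            v = self.cy + self.focal_px * (vy * down[1] + vz * down[2]) / w
        bad = w <= 0
        u = np.where(bad, np.nan, u)
        v = np.where(bad, np.nan, v)
        return u, v

    def back_project(self, u, v):
        """Pixel (u, v) -> ground (metres).

        Raises ValueError if any requested ray is parallel to or above the
        horizon (never intersects the sea surface).
        """
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        right, down, axis = self._basis()
        xc = (u - self.cx) / self.focal_px
        yc = (v - self.cy) / self.focal_px
        dx = xc * right[0]
        dy = yc * down[1] + axis[1]
        dz = yc * down[2] + axis[2]
        if np.any(dz >= 0):
            raise ValueError("pixel ray parallel to or above the horizon")
        t = self.elevation / -dz
        return t * dx, t * dy

    def ground_footprint(self):
        """Ground coordinates (metres) of the four frame corners,
        ordered (top-left, top-right, bottom-right, bottom-left)."""
        us = np.array([0.0, self.width - 1.0, self.width - 1.0, 0.0])
        vs = np.array([0.0, 0.0, self.height - 1.0, self.height - 1.0])
        return self.back_project(us, vs)

    def ground_center(self):
        """Ground point (metres) seen by the frame centre pixel."""
        x, y = self.back_project(self.cx, self.cy)
        return float(x), float(y)

    def metres_per_pixel(self, u, v):
        """Local horizontal ground scale at a pixel (central difference)."""
        x0, y0 = self.back_project(np.asarray(u) - 0.5, v)
        x1, y1 = self.back_project(np.asarray(u) + 0.5, v)
        return np.hypot(x1 - x0, y1 - y0)
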