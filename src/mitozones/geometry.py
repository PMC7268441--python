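"""Observation windows and planar point patterns.

All coordinates and distances are in micrometres (µm). A :class:`Window`
is the reference region of a spatial analysis — either a rectangle or a
circle (e.g. the 550 µm circular region of interest used for growth-zone
statistics). A :class:`PointPattern` couples a finite set of 2-D points
(cell centroids) with the window they were observed in; it is the unit
every spatial statistic operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidParameterError(ValueError):
    """Raised when a generator or statistic receives an invalid parameter."""


@dataclass(frozen=True)
class Window:
    """Rectangular or circular observation window.

    Use :meth:`rectangle` or :meth:`circle` to construct; ``bounds`` holds
    ``(x_min, y_min, x_max, y_max)`` for rectangles and
    ``(center_x, center_y, radius)`` for circles, all in µm.
    """

    shape: str
    bounds: tuple

    @classmethod
    def rectangle(cls, x_min: float, y_min: float, x_max: float, y_max: float) -> "Window":
        if not (x_max > x_min and y_max > y_min):
            raise InvalidParameterError("rectangle window must have positive area")
        return cls("rectangle", (float(x_min), float(y_min), float(x_max), float(y_max)))

    @classmethod
    def circle(cls, center_x: float, center_y: float, radius: float) -> "Window":
        if not radius > 0:
            raise InvalidParameterError("circle window must have positive radius")
        return cls("circle", (float(center_x), float(center_y), float(radius)))

    @property
    def area(self) -> float:
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.bounds
            return (x1 - x0) * (y1 - y0)
        _, _, r = self.bounds
        return np.pi * r * r

    @property
    def diameter(self) -> float:
        """Length of the longest chord of the window."""
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.bounds
            return float(np.hypot(x1 - x0, y1 - y0))
        return 2.0 * self.bounds[2]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the window (boundary inclusive)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.bounds
            return (
                (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
                & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
            )
        cx, cy, r = self.bounds
        return (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= r * r * (1 + 1e-12)

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each (interior) point to the window boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.bounds
            return np.minimum.reduce(
                [pts[:, 0] - x0, x1 - pts[:, 0], pts[:, 1] - y0, y1 - pts[:, 1]]
            )
        cx, cy, r = self.bounds
        return r - np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly at random inside the window."""
        if n == 0:
            return np.empty((0, 2))
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.bounds
            xy = rng.uniform((x0, y0), (x1, y1), size=(n, 2))
            return xy
        cx, cy, r = self.bounds
        rad = r * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])

    def reference_grid(self, n_target: int) -> np.ndarray:
        """Regular grid of roughly ``n_target`` reference locations inside
        the window, used by the empty-space statistic."""
        step = float(np.sqrt(self.area / max(n_target, 1)))
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.bounds
        else:
            cx, cy, r = self.bounds
            x0, y0, x1, y1 = cx - r, cy - r, cx + r, cy + r
        xs = np.arange(x0 + step / 2, x1, step)
        ys = np.arange(y0 + step / 2, y1, step)
        gx, gy = np.meshgrid(xs, ys)
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        return grid[self.contains(grid)]


@dataclass(frozen=True)
class PointPattern:
    """A finite planar point set together with its observation window.

    ``points`` is an ``(n, 2)`` float array of (x, y) positions in µm.
    Construction validates that coordinates are finite and inside the
    window.
    """

    points: np.ndarray
    window: Window

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise InvalidParameterError("point pattern contains non-finite coordinates")
        if pts.size and not np.all(self.window.contains(pts)):
            raise InvalidParameterError("point pattern contains points outside its window")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    @property
    def intensity(self) -> float:
        """Empirical intensity λ̂ = n / window area (points per µm²)."""
        return self.n / self.window.area
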