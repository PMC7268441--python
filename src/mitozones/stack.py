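"""Serial-section stack alignment and 3-D cell-cloud assembly.

Serial sections are mounted with small, independent rigid offsets
(translation + rotation). :func:`align_stack` registers each section to
its already-aligned predecessor by intensity cross-correlation: a
bounded rotation grid search wrapped around a sub-pixel phase
correlation for translation. The resulting per-section corrections map
cell coordinates into a common frame; :func:`assemble_cloud` stacks the
corrected per-section cell tables into an (x, y, z) cloud with z set
from the inter-section spacing (default 100 µm), and
:func:`density_projection` renders the sagittal-plane kernel density
map used to visualise growth zones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .geometry import InvalidParameterError

__all__ = [
    "RigidTransform",
    "CellCloud",
    "DensityMap",
    "transform_image",
    "align_stack",
    "assemble_cloud",
    "density_projection",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation by ``theta_deg`` about the image centre followed by a
    translation ``(dx, dy)``, all in pixel units.

    Acting on a point p (x right, y down):  p' = R(θ)(p − c) + c + t.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta_deg: float = 0.0

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(0.0, 0.0, 0.0)

    def _rot(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray, center: Tuple[float, float]) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(center, dtype=float)
        return (pts - c) @ self._rot().T + c + np.array([self.dx, self.dy])

    def inverse(self) -> "RigidTransform":
        rinv = RigidTransform(0, 0, -self.theta_deg)._rot()
        t = -rinv @ np.array([self.dx, self.dy])
        return RigidTransform(float(t[0]), float(t[1]), -self.theta_deg)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        t = self._rot() @ np.array([other.dx, other.dy]) + np.array([self.dx, self.dy])
        return RigidTransform(float(t[0]), float(t[1]), self.theta_deg + other.theta_deg)


def transform_image(image: np.ndarray, t: RigidTransform, order: int = 1) -> np.ndarray:
    """Resample ``image`` so content previously at p appears at t(p)."""
    inv = t.inverse()
    h, w = image.shape
    c_rc = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    th = np.deg2rad(inv.theta_deg)
    co, si = np.cos(th), np.sin(th)
    # matrix acting on (row, col) offsets, equivalent to R(θ) on (x, y)
    m = np.array([[co, si], [-si, co]])
    t_rc = np.array([inv.dy, inv.dx])
    offset = c_rc + t_rc - m @ c_rc
    return ndimage.affine_transform(
        image.astype(np.float64), m, offset=offset, order=order, mode="constant", cval=float(np.median(image))
    )


def _register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_rotation: float = 10.0,
    upsample: int = 20,
) -> RigidTransform:
    """Estimate the rigid perturbation T of ``moving`` relative to
    ``fixed`` (moving ≈ fixed content moved by T). Coarse 1° rotation
    grid, 0.1° refinement, phase-correlation translation at each step."""

    def score_theta(theta: float) -> Tuple[float, np.ndarray]:
        # undo candidate rotation, then find the residual translation
        unrot = transform_image(moving, RigidTransform(0, 0, -theta))
        shift, error, _ = phase_cross_correlation(
            fixed, unrot, upsample_factor=upsample, normalization=None
        )
        return float(error), shift

    best_theta, (best_err, best_shift) = 0.0, score_theta(0.0)
    for theta in np.arange(-max_rotation, max_rotation + 1e-9, 1.0):
        err, shift = score_theta(float(theta))
        if err < best_err:
            best_theta, best_err, best_shift = float(theta), err, shift
    for step, span in ((0.1, 0.9), (0.02, 0.08)):
        for theta in np.arange(best_theta - span, best_theta + span + 1e-9, step):
            err, shift = score_theta(float(theta))
            if err < best_err:
                best_theta, best_err, best_shift = float(theta), err, shift
    # unrot(p) = moving(R_theta(p-c)+c); residual shift s: unrot content sits
    # at +s relative to fixed => full estimate: rotate then translate by R s
    s_xy = np.array([best_shift[1], best_shift[0]])  # (dx, dy), content offset
    t_xy = RigidTransform(0, 0, best_theta)._rot() @ (-s_xy)
    return RigidTransform(float(t_xy[0]), float(t_xy[1]), best_theta)


def align_stack(
    stack: Sequence[np.ndarray], max_rotation: float = 10.0
) -> Tuple[List[RigidTransform], List[np.ndarray]]:
    """Sequentially register each section to its aligned predecessor.

    Returns ``(corrections, aligned)``: ``corrections[k]`` is the rigid
    transform that maps section k's coordinates into the common frame
    (identity for section 0); ``aligned[k]`` is the resampled image.
    """
    if len(stack) == 0:
        raise InvalidParameterError("empty stack")
    shapes = {s.shape for s in stack}
    if len(shapes) != 1:
        raise InvalidParameterError("sections must share dimensions")
    corrections = [RigidTransform.identity()]
    aligned = [np.asarray(stack[0], dtype=np.float64)]
    for k in range(1, len(stack)):
        moving = np.asarray(stack[k], dtype=np.float64)
        est = _register_pair(aligned[k - 1], moving, max_rotation=max_rotation)
        corr = est.inverse()
        corrections.append(corr)
        aligned.append(transform_image(moving, corr))
    return corrections, aligned


@dataclass(frozen=True)
class CellCloud:
    """Cell table with z (µm) assigned as section_index × spacing."""

    cells: pd.DataFrame
    spacing: float = 100.0


def assemble_cloud(tables: Dict[int, pd.DataFrame], spacing: float = 100.0) -> CellCloud:
    """Concatenate per-section cell tables into a 3-D cloud.

    ``tables`` maps section index → cell table (post-alignment µm
    coordinates). Duplicate section indices are rejected by the dict
    contract; a list of (index, table) pairs is also accepted and
    checked for duplicates.
    """
    if not isinstance(tables, dict):
        pairs = list(tables)
        idx = [i for i, _ in pairs]
        if len(idx) != len(set(idx)):
            raise InvalidParameterError("duplicate section indices")
        tables = dict(pairs)
    frames = []
    for k in sorted(tables):
        df = tables[k].copy()
        df["section_index"] = k
        df["z_um"] = k * spacing
        frames.append(df)
    if frames:
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["x_um", "y_um", "section_index", "z_um"])
    return CellCloud(cells=cells, spacing=spacing)


@dataclass(frozen=True)
class DensityMap:
    """Gaussian kernel density of projected cell positions.

    ``values`` has units cells/µm² on the (x, y) grid given by the
    centre coordinates ``x`` (columns) and ``y`` (rows); the integral
    ``values.sum() * grid_step**2`` equals the cell count.
    """

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    grid_step: float

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.grid_step**2)


def density_projection(
    cloud, bandwidth: float = 50.0, grid_step: float = 10.0
) -> DensityMap:
    """Project all cells to the sagittal (x, y) plane and smooth with an
    isotropic Gaussian kernel of scale ``bandwidth`` (µm).

    The grid extends three bandwidths beyond the data so virtually no
    kernel mass is lost; an empty cloud yields an all-zero map.
    """
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be positive")
    if isinstance(cloud, CellCloud):
        df = cloud.cells
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float) if len(df) else np.empty((0, 2))
    else:
        xy = np.asarray(cloud, dtype=float).reshape(-1, 2)
    if xy.shape[0] == 0:
        z = np.zeros((1, 1))
        return DensityMap(values=z, x=np.zeros(1), y=np.zeros(1), grid_step=grid_step)
    pad = 3.0 * bandwidth + grid_step
    x0, y0 = xy.min(axis=0) - pad
    x1, y1 = xy.max(axis=0) + pad
    xs = np.arange(x0, x1 + grid_step, grid_step)
    ys = np.arange(y0, y1 + grid_step, grid_step)
    counts, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=[_edges(ys), _edges(xs)])
    smooth = ndimage.gaussian_filter(counts, sigma=bandwidth / grid_step, mode="constant")
    return DensityMap(values=smooth / grid_step**2, x=xs, y=ys, grid_step=grid_step)


def _edges(centers: np.ndarray) -> np.ndarray:
    step = centers[1] - centers[0] if len(centers) > 1 else 1.0
    return np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
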