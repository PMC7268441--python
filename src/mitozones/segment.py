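"""Nucleus detection and quantification in 16-bit fluorescence sections.

The detection scheme mirrors a classic two-step recipe for nuclear
markers such as PH3 and DAPI:

1. *Maxima finding.* Local intensity maxima are kept only if their
   topographic prominence exceeds a ``noise_tolerance``: a reported
   maximum is the highest point of a region that cannot be reached from
   a higher maximum without descending more than ``noise_tolerance``
   below its own peak. Plateau maxima report the centroid of the
   plateau. This is implemented exactly with a descending-order
   union-find flood.
2. *Otsu masking.* A global threshold on the native 16-bit histogram
   (65 536 bins) separates signal from background by maximising
   between-class variance; maxima outside the mask are discarded.

Each surviving maximum seeds a watershed basin; the basin intersected
with the Otsu mask is the cell region, from which centroid, area and the
moment-equivalent ellipse axes are measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .geometry import InvalidParameterError

__all__ = [
    "SectionImage",
    "CellObject",
    "Maximum",
    "DegenerateHistogramError",
    "find_maxima",
    "find_maxima_detailed",
    "otsu_threshold",
    "segment_cells",
    "quantify_roundness",
    "ellipse_axes",
]


class DegenerateHistogramError(ValueError):
    """Raised when thresholding a constant (single-valued) image."""


@dataclass(frozen=True)
class SectionImage:
    """One channel of one serial section.

    ``pixels`` is a 2-D array of 16-bit intensities; ``pixel_size`` is the
    lateral sampling in µm/px. ``channel`` is ``"PH3"`` or ``"DAPI"``.
    """

    pixels: np.ndarray
    pixel_size: float = 0.65
    channel: str = "DAPI"
    section_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InvalidParameterError("section image must be 2-D")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class CellObject:
    """A segmented nucleus.

    Position is the intensity-weighted centroid in µm in the image frame
    (x rightward, y downward, origin at the top-left pixel centre).
    ``roundness`` is major/minor axis of the moment-equivalent ellipse
    and is always ≥ 1; ``degenerate`` flags regions whose minor axis had
    to be floored at one pixel.
    """

    x: float
    y: float
    section_index: int
    area: float
    major_axis: float
    minor_axis: float
    roundness: float
    channel: str
    degenerate: bool = False


@dataclass(frozen=True)
class Maximum:
    """A detected prominence maximum (pixel units)."""

    x: float
    y: float
    anchor: Tuple[int, int]  # (row, col) of a pixel at the peak plateau
    prominence: float


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, SectionImage):
        return image.pixels
    return np.asarray(image)


def find_maxima_detailed(image, noise_tolerance: float) -> List[Maximum]:
    """Prominence-based maxima with plateau centroids and anchors.

    Union-find flood in descending intensity order. When two catchment
    components meet at saddle level ``v``, the lower-peaked component is
    absorbed; it is reported as a maximum iff its prominence
    ``peak − v`` exceeds ``noise_tolerance``. The final surviving
    component is reported iff ``peak − min(image)`` exceeds the
    tolerance, so a constant image yields no maxima.
    """
    if noise_tolerance < 0:
        raise InvalidParameterError("noise_tolerance must be >= 0")
    img = _as_pixels(image).astype(np.float64)
    h, w = img.shape
    n = h * w
    flat = img.ravel()
    order = np.argsort(-flat, kind="stable")

    parent = np.full(n, -1, dtype=np.int64)  # -1: not yet processed
    peak = np.empty(n)
    # plateau accumulators (pixels at the component's peak value)
    prow = np.zeros(n)
    pcol = np.zeros(n)
    pcnt = np.zeros(n, dtype=np.int64)
    anchor = np.zeros(n, dtype=np.int64)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    maxima: List[Maximum] = []
    neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    for p in order:
        v = flat[p]
        r, c = divmod(int(p), w)
        roots = []
        for dr, dc in neigh:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                q = rr * w + cc
                if parent[q] >= 0:  # processed earlier => value >= v
                    rt = find(q)
                    if rt not in roots:
                        roots.append(rt)
        if not roots:
            parent[p] = p
            peak[p] = v
            prow[p], pcol[p], pcnt[p] = r, c, 1
            anchor[p] = p
            continue
        # attach to the first component; extend its plateau if at peak level
        main = roots[0]
        parent[p] = main
        if v == peak[main]:
            prow[main] += r
            pcol[main] += c
            pcnt[main] += 1
        # merge any further components through this saddle pixel
        for other in roots[1:]:
            a, b = find(main), find(other)
            if a == b:
                continue
            if peak[a] == peak[b] == v:
                # same top plateau reached from two sides: pool pixels
                parent[b] = a
                prow[a] += prow[b]
                pcol[a] += pcol[b]
                pcnt[a] += pcnt[b]
                main = a
                continue
            lo, hi = (a, b) if peak[a] < peak[b] else (b, a)
            if peak[lo] - v > noise_tolerance:
                maxima.append(_emit(lo, v, peak, prow, pcol, pcnt, anchor, w))
            parent[lo] = hi
            main = hi
    # the single surviving component
    root = find(int(order[0]))
    base = float(flat.min())
    if peak[root] - base > noise_tolerance:
        maxima.append(_emit(root, base, peak, prow, pcol, pcnt, anchor, w))
    maxima.sort(key=lambda m: (m.y, m.x))
    return maxima


def _emit(comp, saddle, peak, prow, pcol, pcnt, anchor, w) -> Maximum:
    cy = prow[comp] / pcnt[comp]
    cx = pcol[comp] / pcnt[comp]
    ar, ac = divmod(int(anchor[comp]), w)
    return Maximum(x=float(cx), y=float(cy), anchor=(ar, ac), prominence=float(peak[comp] - saddle))


def find_maxima(image, noise_tolerance: float) -> np.ndarray:
    """Return the (x_px, y_px) positions of prominence maxima as an array."""
    det = find_maxima_detailed(image, noise_tolerance)
    if not det:
        return np.empty((0, 2))
    return np.array([[m.x, m.y] for m in det])


def otsu_threshold(image) -> Tuple[float, np.ndarray]:
    """Otsu threshold on the native 16-bit histogram.

    Returns ``(threshold, mask)`` where ``mask = pixels > threshold``.
    Raises :class:`DegenerateHistogramError` on a constant image.
    """
    px = _as_pixels(image)
    if px.min() == px.max():
        raise DegenerateHistogramError("cannot threshold a constant image")
    # 65,536 bins: threshold on the original 16-bit intensity resolution
    t = threshold_otsu(px, nbins=65536)
    return float(t), px > t


def ellipse_axes(region_mask: np.ndarray) -> Tuple[float, float, bool]:
    """Major and minor axis lengths (px) of the moment-equivalent ellipse.

    Degenerate (e.g. collinear) regions have a zero second moment along
    one axis; the corresponding axis is floored at 1 px and flagged.
    """
    rows, cols = np.nonzero(region_mask)
    if rows.size == 0:
        raise InvalidParameterError("empty region")
    y = rows - rows.mean()
    x = cols - cols.mean()
    mxx = np.mean(x * x)
    myy = np.mean(y * y)
    mxy = np.mean(x * y)
    common = np.sqrt((mxx - myy) ** 2 + 4 * mxy**2)
    major = 4.0 * np.sqrt(max((mxx + myy + common) / 2, 0.0))
    minor = 4.0 * np.sqrt(max((mxx + myy - common) / 2, 0.0))
    degenerate = False
    if minor < 1.0:
        minor = 1.0
        degenerate = True
        major = max(major, minor)
    return float(major), float(minor), degenerate


def quantify_roundness(region_mask: np.ndarray) -> Tuple[float, bool]:
    """Roundness = major/minor axis ratio of a binary region (≥ 1).

    Returns ``(roundness, degenerate_flag)``; degenerate regions get the
    minor axis floored at one pixel and are flagged with a warning.
    """
    major, minor, degenerate = ellipse_axes(np.asarray(region_mask, dtype=bool))
    if degenerate:
        warnings.warn("degenerate region: minor axis floored at 1 px", stacklevel=2)
    return major / minor, degenerate


def segment_cells(
    image,
    noise_tolerance: float = 100.0,
    min_area: int = 3,
    pixel_size: Optional[float] = None,
    channel: Optional[str] = None,
    section_index: Optional[int] = None,
) -> List[CellObject]:
    """Detect nuclei: prominence maxima inside the Otsu mask, regions by
    watershed-basin ∩ mask, quantified as :class:`CellObject`.

    ``min_area`` (px) suppresses single-pixel noise objects. Returns an
    empty list for blank (constant) images.
    """
    if isinstance(image, SectionImage):
        px = image.pixels
        pixel_size = image.pixel_size if pixel_size is None else pixel_size
        channel = image.channel if channel is None else channel
        section_index = image.section_index if section_index is None else section_index
    else:
        px = np.asarray(image)
        pixel_size = 1.0 if pixel_size is None else pixel_size
        channel = channel or "DAPI"
        section_index = section_index or 0

    try:
        _, mask = otsu_threshold(px)
    except DegenerateHistogramError:
        return []
    detected = find_maxima_detailed(px, noise_tolerance)
    seeds = [m for m in detected if mask[m.anchor]]
    if not seeds:
        return []

    markers = np.zeros(px.shape, dtype=np.int32)
    for i, m in enumerate(seeds, start=1):
        markers[m.anchor] = i
    labels = watershed(-px.astype(np.float64), markers=markers, mask=mask, connectivity=2)

    cells: List[CellObject] = []
    fimg = px.astype(np.float64)
    for prop in regionprops(labels, intensity_image=fimg):
        if prop.area < min_area:
            continue
        region = labels == prop.label
        major, minor, degenerate = ellipse_axes(region)
        cy, cx = prop.centroid_weighted
        cells.append(
            CellObject(
                x=float(cx) * pixel_size,
                y=float(cy) * pixel_size,
                section_index=section_index,
                area=float(prop.area) * pixel_size**2,
                major_axis=major * pixel_size,
                minor_axis=minor * pixel_size,
                roundness=major / minor,
                channel=channel,
                degenerate=degenerate,
            )
        )
    cells.sort(key=lambda c: (c.y, c.x))
    return cells


def cells_to_table(cells: Sequence[CellObject]):
    """Tabulate CellObjects as a pandas DataFrame (the CSV cell table)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x_um": [c.x for c in cells],
            "y_um": [c.y for c in cells],
            "section_index": [c.section_index for c in cells],
            "channel": [c.channel for c in cells],
            "area_um2": [c.area for c in cells],
            "major_um": [c.major_axis for c in cells],
            "minor_um": [c.minor_axis for c in cells],
            "roundness": [c.roundness for c in cells],
        }
    )
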