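"""Synthetic data generators for every stage of the pipeline.

The study this pipeline targets images serial sagittal sections of
embryo heads: 10 µm cryosections collected every 100 µm, two channels
(DAPI marking every nucleus, PH3 marking the mitotic subset), 16-bit
wide-field images. No such images are available digitally, so this
module fabricates them with known ground truth:

* planar point processes with controlled spatial structure — complete
  spatial randomness (:func:`gen_csr`), Thomas-type clustering
  (:func:`gen_cluster`) and sequential-inhibition hard-core repulsion
  (:func:`gen_hardcore`);
* rendered two-channel section stacks with Gaussian-blob nuclei at
  known 3-D positions, additive noise and recorded per-section rigid
  misalignment (:func:`render_sections`);
* multi-zone embryo phantoms with per-point zone labels
  (:func:`gen_embryo_phantom`), emulating discrete growth zones;
* Brownian-motion trait evolution on a tree with recorded true internal
  states (:func:`sim_bm_traits`), plus random bifurcating trees.

All generators are bit-reproducible under a fixed seed and work in µm;
pixels appear only at render time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import InvalidParameterError, PointPattern, Window
from .phylo import Phylogeny
from .segment import SectionImage
from .stack import RigidTransform

__all__ = [
    "gen_csr",
    "gen_binomial",
    "gen_cluster",
    "gen_hardcore",
    "render_sections",
    "gen_embryo_phantom",
    "sim_bm_traits",
    "gen_random_tree",
    "GroundTruthSection",
    "TraitSimulation",
    "ZoneSpec",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_csr(intensity: float, window: Window, seed=None) -> PointPattern:
    """Homogeneous Poisson process: Poisson(λ·|W|) points uniform in W."""
    if intensity <= 0:
        raise InvalidParameterError("intensity must be positive")
    rng = _rng(seed)
    n = rng.poisson(intensity * window.area)
    return PointPattern(window.sample_uniform(n, rng), window)


def gen_binomial(n: int, window: Window, seed=None) -> PointPattern:
    """CSR conditioned on the point count (binomial process); the null
    model of the Monte-Carlo envelope test."""
    rng = _rng(seed)
    return PointPattern(window.sample_uniform(int(n), rng), window)


def gen_cluster(
    parent_intensity: float,
    offspring_mean: float,
    offspring_sd: float,
    window: Window,
    seed=None,
) -> PointPattern:
    """Thomas-type cluster process.

    Poisson parents at ``parent_intensity``; each parent gets a
    Poisson(``offspring_mean``) number of offspring displaced by an
    isotropic normal of scale ``offspring_sd``; offspring falling
    outside the window are dropped.
    """
    if parent_intensity <= 0 or offspring_mean < 0 or offspring_sd <= 0:
        raise InvalidParameterError("cluster process parameters must be positive")
    rng = _rng(seed)
    parents = window.sample_uniform(rng.poisson(parent_intensity * window.area), rng)
    pts = []
    for p in parents:
        k = rng.poisson(offspring_mean)
        if k:
            pts.append(p + rng.normal(0.0, offspring_sd, size=(k, 2)))
    if pts:
        xy = np.concatenate(pts)
        xy = xy[window.contains(xy)]
    else:
        xy = np.empty((0, 2))
    return PointPattern(xy, window)


def gen_hardcore(
    intensity: float, r_min: float, window: Window, seed=None, max_attempts_factor: int = 100
) -> PointPattern:
    """Sequential-inhibition hard-core process: candidates are accepted
    only if at least ``r_min`` from every accepted point.

    Requires a feasible packing (λ·π·r_min² < 0.5); gives up with an
    error after ``max_attempts_factor`` × target rejections.
    """
    if intensity <= 0 or r_min < 0:
        raise InvalidParameterError("intensity must be positive and r_min >= 0")
    # packing fraction of exclusion disks (radius r_min/2) must stay below 1/2
    if intensity * np.pi * (r_min / 2) ** 2 >= 0.5:
        raise InvalidParameterError("infeasible hard-core packing (lambda * pi * (r_min/2)^2 >= 0.5)")
    rng = _rng(seed)
    target = rng.poisson(intensity * window.area)
    accepted: List[np.ndarray] = []
    attempts = 0
    limit = max(max_attempts_factor * max(target, 1), 1)
    while len(accepted) < target:
        if attempts >= limit:
            raise RuntimeError("hard-core sampling exceeded the rejection budget")
        cand = window.sample_uniform(1, rng)[0]
        attempts += 1
        if all(np.hypot(*(cand - a)) >= r_min for a in accepted):
            accepted.append(cand)
    xy = np.array(accepted) if accepted else np.empty((0, 2))
    return PointPattern(xy, window)


@dataclass(frozen=True)
class GroundTruthSection:
    """A rendered two-channel section plus its ground truth.

    ``true_nuclei`` holds the nucleus positions *after* the recorded
    rigid perturbation, i.e. in the frame of the rendered pixels, with
    columns x_um, y_um, z_um, is_mitotic. PH3-positive nuclei are
    always a subset of the DAPI nuclei.
    """

    section_index: int
    dapi: SectionImage
    ph3: SectionImage
    true_nuclei: pd.DataFrame
    transform_applied: RigidTransform


def _render_channel(
    positions_px: np.ndarray,
    shape: Tuple[int, int],
    psf_sigma_px: float,
    amplitude: float,
    background_mean: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float64)
    rad = int(np.ceil(5 * psf_sigma_px))
    h, w = shape
    for x, y in positions_px:
        r0, r1 = int(np.floor(y)) - rad, int(np.floor(y)) + rad + 1
        c0, c1 = int(np.floor(x)) - rad, int(np.floor(x)) + rad + 1
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        if r0c >= r1c or c0c >= c1c:
            continue
        rr = np.arange(r0c, r1c)[:, None]
        cc = np.arange(c0c, c1c)[None, :]
        img[r0c:r1c, c0c:c1c] += amplitude * np.exp(
            -((cc - x) ** 2 + (rr - y) ** 2) / (2 * psf_sigma_px**2)
        )
    img += background_mean
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def render_sections(
    nuclei_3d,
    psf_sigma: float = 2.5,
    amplitude: float = 10000.0,
    background_mean: float = 500.0,
    noise_sd: float = 0.0,
    pixel_size: float = 0.65,
    section_thickness: float = 10.0,
    section_spacing: float = 100.0,
    misalign_sd: Tuple[float, float] = (0.0, 0.0),
    seed=None,
    shape_px: Optional[Tuple[int, int]] = None,
) -> List[GroundTruthSection]:
    """Render a serial-section acquisition of 3-D nuclei.

    ``nuclei_3d`` is an (n, 4) array-like of (x_um, y_um, z_um,
    is_mitotic) or a DataFrame with those columns. A nucleus at depth z
    appears only in the section whose slab ``[k·spacing,
    k·spacing + thickness)`` contains z — partial-volume effects are
    ignored since the 10 µm slab exceeds the nucleus size. Every
    nucleus is rendered as a 2-D Gaussian blob of scale ``psf_sigma``
    (µm) on the DAPI channel and, if mitotic, also on PH3. Each section
    k > 0 receives an independent rigid perturbation drawn from
    ``misalign_sd = (sd_px, sd_degrees)``, applied to the coordinates
    before rasterisation and recorded in ``transform_applied``.
    """
    if section_spacing < section_thickness:
        raise InvalidParameterError("section_spacing must be >= section_thickness")
    if pixel_size <= 0 or psf_sigma <= 0:
        raise InvalidParameterError("pixel_size and psf_sigma must be positive")
    rng = _rng(seed)
    if isinstance(nuclei_3d, pd.DataFrame):
        arr = nuclei_3d[["x_um", "y_um", "z_um", "is_mitotic"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(nuclei_3d, dtype=float).reshape(-1, 4)
    if shape_px is None:
        margin = 10 * psf_sigma / pixel_size
        w = int(np.ceil(arr[:, 0].max() / pixel_size + margin)) if len(arr) else 64
        h = int(np.ceil(arr[:, 1].max() / pixel_size + margin)) if len(arr) else 64
        shape_px = (h, w)
    center = ((shape_px[1] - 1) / 2.0, (shape_px[0] - 1) / 2.0)  # (cx, cy) px

    n_sections = int(arr[:, 2].max() // section_spacing) + 1 if len(arr) else 1
    sections: List[GroundTruthSection] = []
    for k in range(n_sections):
        z0 = k * section_spacing
        in_slab = (arr[:, 2] >= z0) & (arr[:, 2] < z0 + section_thickness)
        sub = arr[in_slab]
        if k > 0 and (misalign_sd[0] > 0 or misalign_sd[1] > 0):
            t = RigidTransform(
                dx=float(rng.normal(0, misalign_sd[0])),
                dy=float(rng.normal(0, misalign_sd[0])),
                theta_deg=float(rng.normal(0, misalign_sd[1])),
            )
        else:
            t = RigidTransform.identity()
        pos_px = sub[:, :2] / pixel_size
        pos_px = t.apply(pos_px, center) if len(pos_px) else pos_px
        mitotic = sub[:, 3] > 0.5
        dapi = _render_channel(pos_px, shape_px, psf_sigma / pixel_size,
                               amplitude, background_mean, noise_sd, rng)
        ph3 = _render_channel(pos_px[mitotic], shape_px, psf_sigma / pixel_size,
                              amplitude, background_mean, noise_sd, rng)
        truth = pd.DataFrame(
            {
                "x_um": pos_px[:, 0] * pixel_size,
                "y_um": pos_px[:, 1] * pixel_size,
                "z_um": sub[:, 2],
                "is_mitotic": mitotic,
            }
        )
        sections.append(
            GroundTruthSection(
                section_index=k,
                dapi=SectionImage(dapi, pixel_size, "DAPI", k),
                ph3=SectionImage(ph3, pixel_size, "PH3", k),
                true_nuclei=truth,
                transform_applied=t,
            )
        )
    return sections


@dataclass(frozen=True)
class ZoneSpec:
    """One growth zone of an embryo phantom: a point cloud of
    ``n_points`` around ``center`` with scale ``spread`` (µm)."""

    center: Tuple[float, float]
    spread: float
    n_points: int
    process: str = "gaussian"  # or "uniform" (disk)


def gen_embryo_phantom(
    zone_specs: Sequence,
    window: Window,
    mitotic_fraction: float = 0.05,
    seed=None,
    depth: float = 300.0,
) -> pd.DataFrame:
    """Union of per-zone point clouds with recorded true zone labels.

    Returns a DataFrame with columns x_um, y_um, z_um, is_mitotic,
    zone. Depth coordinates are uniform on [0, ``depth``). The mitotic
    (PH3) subset is sampled per zone at ``mitotic_fraction``, so PH3
    points are a strict subset of the DAPI points.
    """
    if len(zone_specs) == 0:
        raise InvalidParameterError("zone_specs must be non-empty")
    if not (0 < mitotic_fraction <= 1):
        raise InvalidParameterError("mitotic_fraction must be in (0, 1]")
    rng = _rng(seed)
    frames = []
    for zi, spec in enumerate(zone_specs):
        if not isinstance(spec, ZoneSpec):
            spec = ZoneSpec(*spec)
        pts = np.empty((0, 2))
        guard = 0
        while len(pts) < spec.n_points:
            need = spec.n_points - len(pts)
            if spec.process == "uniform":
                rad = spec.spread * np.sqrt(rng.uniform(size=need))
                ang = rng.uniform(0, 2 * np.pi, size=need)
                cand = np.asarray(spec.center) + np.column_stack(
                    [rad * np.cos(ang), rad * np.sin(ang)]
                )
            else:
                cand = rng.normal(spec.center, spec.spread, size=(need, 2))
            cand = cand[window.contains(cand)]
            pts = np.concatenate([pts, cand]) if len(cand) else pts
            guard += 1
            if guard > 1000:
                raise RuntimeError("zone placement failed: zone falls outside the window")
        z = rng.uniform(0, depth, size=spec.n_points)
        n_mit = int(round(mitotic_fraction * spec.n_points))
        mit = np.zeros(spec.n_points, dtype=bool)
        mit[rng.choice(spec.n_points, size=n_mit, replace=False)] = True
        frames.append(
            pd.DataFrame(
                {"x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": z,
                 "is_mitotic": mit, "zone": zi}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TraitSimulation:
    """A Brownian-motion trait history on a tree: the diffusion rate
    σ² (trait² per unit branch length), the root state, simulated tip
    states and the recorded true internal-node states."""

    tree: Phylogeny
    sigma2: float
    root_state: float
    tip_states: Dict[str, float]
    true_node_states: Dict[str, float]


def sim_bm_traits(tree: Phylogeny, sigma2: float, root_state: float, seed=None) -> TraitSimulation:
    """Simulate Brownian motion root→tips: each branch of length v adds
    an independent normal(0, σ²·v) increment."""
    if sigma2 < 0:
        raise InvalidParameterError("sigma2 must be >= 0")
    rng = _rng(seed)
    states: Dict[str, float] = {}
    tip_states: Dict[str, float] = {}
    node_states: Dict[str, float] = {}
    for node in tree.preorder():
        if node.parent is None:
            val = float(root_state)
        else:
            val = states[node.parent.label] + float(
                rng.normal(0.0, np.sqrt(sigma2 * node.branch_length))
            )
        states[node.label] = val
        (tip_states if node.is_leaf else node_states)[node.label] = val
    return TraitSimulation(tree=tree, sigma2=sigma2, root_state=root_state,
                           tip_states=tip_states, true_node_states=node_states)


def gen_random_tree(n_tips: int, seed=None, min_bl: float = 0.2, max_bl: float = 2.0) -> Phylogeny:
    """Random rooted bifurcating tree: successive random joins with
    uniform branch lengths; tips labelled t1..tn."""
    if n_tips < 2:
        raise InvalidParameterError("need at least 2 tips")
    rng = _rng(seed)

    def bl() -> float:
        return float(rng.uniform(min_bl, max_bl))

    subtrees = [f"t{i + 1}:{bl():.6f}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        joined = f"({a},{b})"
        subtrees.append(joined if len(subtrees) == 0 else f"{joined}:{bl():.6f}")
    return Phylogeny.from_newick(subtrees[0] + ";")
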