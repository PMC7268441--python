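"""Spatial statistics for growth-zone analysis of mitotic cells.

Three questions about a planar point pattern of cell positions are
answered here:

* *How many growth zones?* K-means over a range of K with the elbow
  criterion on the dispersion curve (:func:`kmeans_elbow`): the chosen
  K maximises the discrete curvature (second difference) of the mean
  within-cluster distance, operationalising the visual "bend".
* *How compact are cells?* Nearest-neighbour distances (:func:`nnd`);
  under complete spatial randomness (CSR) at intensity λ the mean NND
  is 1/(2√λ).
* *Clustered, random or dispersed?* Distance-distribution statistics —
  the empty-space function F (distance from reference locations to the
  nearest cell) and the nearest-neighbour CDF G — compared against a
  Monte-Carlo envelope of CSR patterns with the observed point count
  (:func:`mc_envelope`). The empirical curve escaping the envelope on
  a contiguous run of distances is read as attraction (clustering) or
  repulsion (dispersion).

Both F and G use the reduced-sample border correction: at distance r,
reference locations (or points) closer than r to the window boundary
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .geometry import InvalidParameterError, PointPattern, Window

__all__ = [
    "nnd",
    "kmeans_elbow",
    "empty_space_function",
    "nn_distance_function",
    "mc_envelope",
    "ClusterResult",
    "EnvelopeResult",
    "csr_mean_nnd",
    "csr_f_theoretical",
]


def csr_mean_nnd(intensity: float) -> float:
    """Expected nearest-neighbour distance under CSR: 1/(2√λ)."""
    return 1.0 / (2.0 * np.sqrt(intensity))


def csr_f_theoretical(r, intensity: float):
    """Closed-form empty-space CDF under CSR: 1 − exp(−λπr²)."""
    r = np.asarray(r, dtype=float)
    return 1.0 - np.exp(-intensity * np.pi * r**2)


def nnd(pattern: PointPattern) -> Tuple[np.ndarray, float]:
    """Distance from each point to its nearest neighbour, plus the mean."""
    if pattern.n < 2:
        raise InvalidParameterError("nearest-neighbour analysis needs >= 2 points")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=2)
    return d[:, 1], float(d[:, 1].mean())


@dataclass(frozen=True)
class ClusterResult:
    """K-means growth-zone partition chosen by the elbow criterion."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    k_range: np.ndarray
    dispersion_curve: np.ndarray  # mean within-cluster distance per candidate K


def kmeans_elbow(
    points: np.ndarray,
    k_range: Sequence[int] = range(1, 11),
    n_init: int = 10,
    seed=None,
) -> ClusterResult:
    """Best-of-``n_init`` K-means for each K; the reported K maximises
    the second difference of the dispersion curve (the elbow).

    With fewer than three candidate K values no curvature exists and
    the K with the smallest dispersion is returned.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise InvalidParameterError("empty point set")
    ks = np.array(sorted(set(int(k) for k in k_range)))
    if ks.min() < 1 or ks.max() > pts.shape[0]:
        raise InvalidParameterError("k_range must lie within [1, n_points]")
    if n_init < 1:
        raise InvalidParameterError("n_init must be >= 1")
    rs = np.random.default_rng(seed).integers(0, 2**31 - 1)
    fits = {}
    dispersion = []
    for k in ks:
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=int(rs)).fit(pts)
        d = np.linalg.norm(pts - km.cluster_centers_[km.labels_], axis=1)
        fits[int(k)] = km
        dispersion.append(float(d.mean()))
    dispersion = np.array(dispersion)
    if len(ks) >= 3:
        # curvature of the log-dispersion curve: the elbow is where the
        # *relative* rate of decrease shifts, which is scale-free
        logd = np.log(np.maximum(dispersion, 1e-12))
        curvature = logd[:-2] - 2 * logd[1:-1] + logd[2:]
        best = int(ks[1 + int(np.argmax(curvature))])
    else:
        best = int(ks[int(np.argmin(dispersion))])
    km = fits[best]
    return ClusterResult(
        k=best,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        k_range=ks,
        dispersion_curve=dispersion,
    )


def _default_r_grid(pattern: PointPattern, n_r: int = 26) -> np.ndarray:
    # range out to where the CSR nearest-distance CDF has saturated
    lam = max(pattern.intensity, 1e-12)
    r_max = min(np.sqrt(np.log(100.0) / (lam * np.pi)), pattern.window.diameter / 2)
    return np.linspace(0.0, r_max, n_r)


def empty_space_function(
    pattern: PointPattern, r_grid: np.ndarray, n_ref_points: int = 1000
) -> np.ndarray:
    """Empty-space (F) function with reduced-sample border correction.

    F̂(r) is the fraction of regularly gridded reference locations whose
    nearest pattern point lies within r, among locations at least r
    from the window boundary.
    """
    if pattern.n == 0:
        raise InvalidParameterError("empty pattern")
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) <= 0):
        raise InvalidParameterError("r_grid must be strictly increasing")
    refs = pattern.window.reference_grid(n_ref_points)
    d = cKDTree(pattern.points).query(refs, k=1)[0]
    border = pattern.window.boundary_distance(refs)
    return _reduced_sample_cdf(d, border, r_grid)


def nn_distance_function(pattern: PointPattern, r_grid: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance CDF (G) with reduced-sample border
    correction."""
    d, _ = nnd(pattern)
    border = pattern.window.boundary_distance(pattern.points)
    return _reduced_sample_cdf(d, border, np.asarray(r_grid, dtype=float))


def _reduced_sample_cdf(d: np.ndarray, border: np.ndarray, r_grid: np.ndarray) -> np.ndarray:
    out = np.empty(len(r_grid))
    for i, r in enumerate(r_grid):
        ok = border >= r
        # beyond the window inradius nothing is eligible; fall back to
        # the uncorrected estimate so the curve stays defined
        out[i] = np.mean(d[ok] <= r) if ok.any() else np.mean(d <= r)
    # reduced-sample estimates can dip as the eligible set shrinks;
    # return the monotone (running-max) regularisation of the curve
    return np.fmax.accumulate(out)


@dataclass(frozen=True)
class EnvelopeResult:
    """Empirical distance-CDF curve against its CSR Monte-Carlo envelope."""

    statistic: str
    r_grid: np.ndarray
    empirical: np.ndarray
    null_mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    classification: str  # attraction | random | repulsion


def _statistic_curve(pattern: PointPattern, statistic: str, r_grid, n_ref_points):
    if statistic == "F":
        return empty_space_function(pattern, r_grid, n_ref_points)
    if statistic == "G":
        return nn_distance_function(pattern, r_grid)
    raise InvalidParameterError("statistic must be 'F' or 'G'")


def mc_envelope(
    pattern: PointPattern,
    statistic: str = "G",
    n_avg: int = 5,
    n_env: int = 39,
    alpha: float = 0.05,
    seed=None,
    r_grid: Optional[np.ndarray] = None,
    n_ref_points: int = 1000,
    run_length: int = 3,
) -> EnvelopeResult:
    """Monte-Carlo envelope goodness-of-fit test against CSR.

    The null model is CSR conditioned on the observed point count in
    the same window. ``n_avg`` realizations are averaged into the null
    mean curve; an independent set of ``n_env`` realizations forms the
    pointwise envelope (min/max for n_env ≤ 39, the α/2 quantile curves
    for larger sets). The pattern is classified as non-random only when
    the empirical curve stays outside the envelope for at least
    ``run_length`` consecutive distances; the direction is read
    per-statistic (for G, clustered points shift the curve up; for F,
    clustering empties space and shifts the curve down).
    """
    if pattern.n < 2:
        raise InvalidParameterError("need >= 2 points")
    if n_avg < 1:
        raise InvalidParameterError("n_avg must be >= 1")
    if n_env < int(np.ceil(1 / (alpha / 2))) - 1:
        raise InvalidParameterError("n_env too small for the requested alpha")
    rng = np.random.default_rng(seed)
    if r_grid is None:
        r_grid = _default_r_grid(pattern)
    w = pattern.window

    def null_curve() -> np.ndarray:
        pp = PointPattern(w.sample_uniform(pattern.n, rng), w)
        return _statistic_curve(pp, statistic, r_grid, n_ref_points)

    empirical = _statistic_curve(pattern, statistic, r_grid, n_ref_points)
    avg_set = np.array([null_curve() for _ in range(n_avg)])
    env_set = np.array([null_curve() for _ in range(n_env)])
    null_mean = np.nanmean(avg_set, axis=0)
    if n_env <= 39:
        lower = np.nanmin(env_set, axis=0)
        upper = np.nanmax(env_set, axis=0)
    else:
        lower = np.nanquantile(env_set, alpha / 2, axis=0)
        upper = np.nanquantile(env_set, 1 - alpha / 2, axis=0)
    # keep the averaged null curve inside the band by construction
    lower = np.fmin(lower, null_mean)
    upper = np.fmax(upper, null_mean)

    # classify by the direction of the first sustained excursion: a
    # hard-core pattern, e.g., sits below the envelope before r_min and
    # rebounds above it just after, and the early excursion is the signal
    first_above = _first_run(empirical > upper, run_length)
    first_below = _first_run(empirical < lower, run_length)
    if first_above is None and first_below is None:
        classification = "random"
    else:
        above_wins = first_below is None or (
            first_above is not None and first_above <= first_below
        )
        if statistic == "G":
            classification = "attraction" if above_wins else "repulsion"
        else:  # F: clustering empties space and depresses the CDF
            classification = "repulsion" if above_wins else "attraction"
    return EnvelopeResult(
        statistic=statistic,
        r_grid=np.asarray(r_grid, dtype=float),
        empirical=empirical,
        null_mean=null_mean,
        lower=lower,
        upper=upper,
        classification=classification,
    )


def _first_run(mask: np.ndarray, run_length: int):
    """Index where the first run of ``run_length`` Trues starts, or None."""
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if (m and not np.isnan(m)) else 0
        if run >= run_length:
            return i - run_length + 1
    return None
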