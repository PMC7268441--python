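"""Standardized proliferation and cross-species group statistics.

The comparative quantity is the mitotic index standardized for embryo
size: PH3-positive count / DAPI-positive count × 100 ("percent area
fraction"). Species are compared with a one-way ANOVA, many-to-one
contrasts against a reference (outgroup) species, Tukey's HSD over all
pairs, pairwise Wilcoxon rank-sum tests with multiplicity adjustment,
and the Shapiro–Wilk normality check that motivates the rank-based
tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geometry import InvalidParameterError

__all__ = [
    "standardize",
    "StageSeries",
    "percent_change",
    "anova_oneway",
    "AnovaResult",
    "tukey_hsd",
    "wilcoxon_pairwise",
    "shapiro_wilk",
]


def standardize(ph3_count: int, dapi_count: int) -> float:
    """Standardized proliferation: PH3/DAPI × 100 (percent area fraction)."""
    if dapi_count <= 0:
        raise InvalidParameterError("dapi_count must be positive")
    if ph3_count < 0:
        raise InvalidParameterError("ph3_count must be non-negative")
    return ph3_count / dapi_count * 100.0


@dataclass(frozen=True)
class StageSeries:
    """Ordered per-stage values with stage-to-stage percent change.

    ``percent_change[i]`` is the relative change from stage i to stage
    i+1 in percent, so a ninefold increase reports +800%.
    """

    stages: tuple
    values: tuple
    percent_change: Optional[tuple] = None


def percent_change(series: StageSeries) -> StageSeries:
    """Fill the percent-change column of a stage series."""
    vals = np.asarray(series.values, dtype=float)
    if np.any(vals <= 0):
        raise InvalidParameterError("percent change requires positive baseline values")
    pc = tuple((vals[1:] - vals[:-1]) / vals[:-1] * 100.0)
    return StageSeries(stages=tuple(series.stages), values=tuple(series.values), percent_change=pc)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    comparisons: Optional[pd.DataFrame] = None  # vs the reference group
    degenerate: bool = False


def _validate_groups(groups: Dict[str, Sequence[float]], min_size: int = 2) -> Dict[str, np.ndarray]:
    if len(groups) < 2:
        raise InvalidParameterError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_size:
            raise InvalidParameterError(f"group {name!r} needs >= {min_size} values")
        out[name] = arr
    return out


def anova_oneway(
    groups: Dict[str, Sequence[float]],
    reference: Optional[str] = None,
    adjust: str = "dunnett",
) -> AnovaResult:
    """One-way ANOVA with optional many-to-one reference contrasts.

    ``reference`` names the group (e.g. the outgroup species) every
    other group is compared against; the multiplicity adjustment is
    Dunnett's many-to-one procedure by default (``adjust`` may also be
    ``"tukey"`` or ``"holm"``). Zero within-group variance yields an
    infinite F with a warning instead of an exception.
    """
    g = _validate_groups(groups)
    names = list(g)
    k = len(names)
    n_total = sum(len(v) for v in g.values())
    grand = np.concatenate(list(g.values())).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in g.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in g.values())
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    degenerate = ms_within == 0
    if degenerate:
        warnings.warn("zero within-group variance: F reported as infinite", stacklevel=2)
        f = np.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, df_b, df_w))

    comparisons = None
    if reference is not None:
        if reference not in g:
            raise InvalidParameterError(f"reference group {reference!r} not found")
        others = [n for n in names if n != reference]
        diffs = [g[n].mean() - g[reference].mean() for n in others]
        if degenerate:
            p_adj = [0.0 if d != 0 else 1.0 for d in diffs]
        elif adjust == "dunnett":
            res = sps.dunnett(*[g[n] for n in others], control=g[reference])
            p_adj = list(res.pvalue)
        elif adjust == "tukey":
            table = tukey_hsd(groups)
            p_map = {}
            for _, row in table.iterrows():
                a, b = row["pair"].split("-")
                p_map[frozenset((a, b))] = row["p_adj"]
            p_adj = [p_map[frozenset((n, reference))] for n in others]
        elif adjust == "holm":
            raw = [
                sps.ttest_ind(g[n], g[reference], equal_var=True).pvalue for n in others
            ]
            p_adj = list(multipletests(raw, method="holm")[1])
        else:
            raise InvalidParameterError("adjust must be 'dunnett', 'tukey' or 'holm'")
        comparisons = pd.DataFrame(
            {"group": others, "difference": diffs, "p_adj": p_adj}
        )
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        df_between=df_b,
        df_within=df_w,
        comparisons=comparisons,
        degenerate=bool(degenerate),
    )


def tukey_hsd(groups: Dict[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey honest-significant-difference table over all group pairs.

    Rows are labelled "B-A" for sorted labels A < B and report
    ``difference = mean(B) − mean(A)``; confidence bounds use the
    studentized-range critical value with the pooled within-group
    variance, and ``p_adj`` comes from the studentized-range
    distribution. Column order matches the conventional report:
    pair, difference, lower, upper, p_adj.
    """
    g = _validate_groups(groups)
    names = sorted(g)
    k = len(names)
    df_w = sum(len(v) for v in g.values()) - k
    ms_within = sum(((v - v.mean()) ** 2).sum() for v in g.values()) / df_w
    rows = []
    degenerate = ms_within == 0
    if not degenerate:
        q_crit = sps.studentized_range.ppf(1 - alpha, k, df_w)
    for a, b in itertools.combinations(names, 2):
        diff = g[b].mean() - g[a].mean()
        if degenerate:
            lower = upper = diff
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(ms_within * (1 / len(g[a]) + 1 / len(g[b])))
            half = q_crit / np.sqrt(2) * se
            lower, upper = diff - half, diff + half
            q_obs = abs(diff) / (se / np.sqrt(2))
            p_adj = float(sps.studentized_range.sf(q_obs, k, df_w))
        rows.append(
            {"pair": f"{b}-{a}", "difference": float(diff),
             "lower": float(lower), "upper": float(upper), "p_adj": float(np.clip(p_adj, 0, 1))}
        )
    return pd.DataFrame(rows, columns=["pair", "difference", "lower", "upper", "p_adj"])


def wilcoxon_pairwise(
    groups: Dict[str, Sequence[float]], adjustment: str = "holm"
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with adjusted p-values.

    The exact null distribution is enumerated when both samples have
    n ≤ 10 and the pooled data are tie-free; otherwise the normal
    approximation with continuity and tie correction is used. The
    adjustment (``holm``, ``bh`` or ``bonferroni``) is applied across
    all pairs; the result is a symmetric matrix of adjusted p-values
    with 1.0 on the diagonal.
    """
    g = _validate_groups(groups, min_size=1)
    names = sorted(g)
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        x, y = g[a], g[b]
        pooled = np.concatenate([x, y])
        exact = len(x) <= 10 and len(y) <= 10 and len(np.unique(pooled)) == len(pooled)
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        raw.append(float(res.pvalue))
    method = {"holm": "holm", "bh": "fdr_bh", "bonferroni": "bonferroni"}.get(adjustment)
    if method is None:
        raise InvalidParameterError("adjustment must be 'holm', 'bh' or 'bonferroni'")
    adj = multipletests(raw, method=method)[1] if raw else []
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = float(min(p, 1.0))
    return mat


def shapiro_wilk(sample: Sequence[float]):
    """Shapiro–Wilk normality test (W, p) for 3 ≤ n ≤ 5000."""
    arr = np.asarray(sample, dtype=float)
    if not (3 <= arr.size <= 5000):
        raise InvalidParameterError("Shapiro-Wilk requires 3 <= n <= 5000")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)
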