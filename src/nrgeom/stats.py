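"""Shared statistics layer for the structure-comparison pipeline.

Thin, explicitly-contracted wrappers around scipy / statsmodels plus the
small closed-form quantities used throughout: coefficient of variation
(sample SD, n−1), Cohen's d on summary statistics, paired t-test,
Kruskal–Wallis with midrank tie correction, one-way ANOVA with Tukey HSD,
ordinary least squares, average-linkage hierarchical clustering on
standardized coordinates, and Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "StatsSummary",
    "summarize",
    "coefficient_of_variation",
    "cohens_d",
    "paired_t",
    "kruskal_wallis",
    "regression_slope",
    "hierarchical_cluster",
    "anova_tukey",
    "bonferroni_adjust",
]


@dataclass
class StatsSummary:
    mean: float
    sd: float
    cv: float  # percent
    n: int
    q1: float | None = None
    q3: float | None = None
    iqr: float | None = None


def summarize(values: Sequence[float], quartiles: bool = True) -> StatsSummary:
    """Mean, sample SD, CV% and (optionally) Type-7 quartiles / IQR."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = coefficient_of_variation(x)
    q1 = q3 = iqr = None
    if quartiles:
        q1, q3 = (float(q) for q in np.percentile(x, [25, 75]))  # linear interpolation
        iqr = q3 - q1
    return StatsSummary(mean=mean, sd=sd, cv=cv, n=x.size, q1=q1, q3=q3, iqr=iqr)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV = σ/μ × 100 with the sample SD (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / abs(mean) * 100.0)


def cv_from_summary(sd: float, mean: float) -> float:
    """CV% directly from printed summary statistics (σ, μ)."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return sd / abs(mean) * 100.0


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """|μ1−μ2| / sqrt((σ1²+σ2²)/2), the effect size on summary statistics."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = math.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0:
        raise ValueError("both standard deviations are zero")
    return abs(mean1 - mean2) / pooled


def paired_t(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Classical paired t-test on the differences; two-sided p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length samples of at least 3 values")
    if np.std(a - b, ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H with tie correction and its chi-square p-value."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need ≥ 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def regression_slope(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares: (slope, intercept, Pearson r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("need equal-length samples of at least 3 values")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def hierarchical_cluster(points: dict[str, tuple[float, float]]) -> dict:
    """Average-linkage agglomerative clustering on z-scored (r_eff, Ψ) pairs.

    Returns the scipy linkage matrix, the label order, and the sequence of
    merges as (members_a, members_b, distance) with original labels.
    """
    labels = list(points)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 points")
    X = np.array([points[k] for k in labels], dtype=float)
    sd = X.std(axis=0, ddof=0)
    Xz = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    Z = linkage(pdist(Xz), method="average")
    clusters: dict[int, list[str]] = {i: [lab] for i, lab in enumerate(labels)}
    merges = []
    for step, (i, j, dist, _) in enumerate(Z):
        a, b = clusters[int(i)], clusters[int(j)]
        merges.append((sorted(a), sorted(b), float(dist)))
        clusters[len(labels) + step] = a + b
    return {"labels": labels, "linkage": Z, "merges": merges}


def anova_tukey(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    group_names: Sequence[str] | None = None,
) -> dict:
    """One-way ANOVA plus Tukey HSD on all pairs of groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need ≥ 2 groups of ≥ 2 values each")
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.var(pooled) == 0:
        return {"F": 0.0, "p": 1.0, "pairwise": []}
    if all(np.var(a, ddof=1) == 0 for a in arrays):
        raise ValueError("degenerate: all groups have zero variance")
    f, p = sps.f_oneway(*arrays)
    names = list(group_names) if group_names else [f"g{i}" for i in range(len(arrays))]
    values = np.concatenate(arrays)
    codes = np.concatenate([[names[i]] * len(a) for i, a in enumerate(arrays)])
    tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
    pairwise = [
        {
            "group1": str(r[0]), "group2": str(r[1]),
            "meandiff": float(r[2]), "p_adj": float(r[3]),
            "significant": bool(r[6]),
        }
        for r in tk.summary().data[1:]
    ]
    return {"F": float(f), "p": float(p), "pairwise": pairwise}


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """min(1, p·m) for each of m p-values."""
    ps = list(p_values)
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    return [min(1.0, p * m) for p in ps]
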