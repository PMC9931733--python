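"""Statistical primitives used throughout the pipeline.

One-way ANOVA with least-significant-difference (LSD) post-hoc tests,
Benjamini-Hochberg adjustment, Pearson correlation with a least-squares
line, a rank-sum differential-expression screen, and the 2^(-ddCt)
relative-quantification fold change.  ANOVA, LSD and BH are written out
from their defining sums so they can be checked against independent
implementations to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = [
    "AnovaResult",
    "PearsonFit",
    "anova_lsd",
    "bh_adjust",
    "pearson_fit",
    "de_screen",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with LSD pairwise comparisons.

    ``pairwise`` maps each unordered group pair ``(a, b)`` (in input
    order) to the two-sided LSD p-value computed from the pooled
    within-group mean square and its degrees of freedom.
    """

    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    means: dict[str, float]
    ns: dict[str, int]
    pairwise: dict[tuple[str, str], float]


def anova_lsd(data: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA F/p plus LSD pairwise p-values.

    Each group needs n >= 2.  Degenerate inputs are resolved explicitly:
    if every observation is identical, F = 0 and all p-values are 1; if
    groups are internally constant but differ, F is infinite and p = 0.
    """
    if len(data) < 2:
        raise InvalidInputError("need at least 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    for k, v in groups.items():
        if v.ndim != 1 or len(v) < 2:
            raise InvalidInputError(f"group {k!r} needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError(f"group {k!r} has non-finite values")

    ns = {k: len(v) for k, v in groups.items()}
    means = {k: float(v.mean()) for k, v in groups.items()}
    n_total = sum(ns.values())
    k = len(groups)
    grand = sum(v.sum() for v in groups.values()) / n_total
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in groups)
    ss_within = sum(((v - means[g]) ** 2).sum() for g, v in groups.items())
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within

    if ms_within > 0:
        F = ms_between / ms_within
        p = float(scipy.stats.f.sf(F, df_between, df_within))
    elif ms_between > 0:
        F, p = float("inf"), 0.0
    else:
        F, p = 0.0, 1.0

    names = list(groups)
    pairwise: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = means[a] - means[b]
            if ms_within > 0:
                t = diff / np.sqrt(ms_within * (1.0 / ns[a] + 1.0 / ns[b]))
                pairwise[(a, b)] = float(2.0 * scipy.stats.t.sf(abs(t), df_within))
            else:
                pairwise[(a, b)] = 1.0 if diff == 0 else 0.0
    return AnovaResult(
        F=float(F),
        p=p,
        df_between=df_between,
        df_within=df_within,
        ms_within=float(ms_within),
        means=means,
        ns=ns,
        pairwise=pairwise,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InvalidInputError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise InvalidInputError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass(frozen=True)
class PearsonFit:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def pearson_fit(x, y) -> PearsonFit:
    """Pearson r with a two-sided t-based p-value and the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise InvalidInputError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    res = scipy.stats.linregress(x, y)
    return PearsonFit(
        r=float(res.rvalue),
        p=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(x),
    )


def de_screen(
    bundle,
    spot_mask,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    target_sum: float = 1e4,
    method: str = "bh",
) -> pd.DataFrame:
    """Two-group differential-expression screen on a spot subset.

    Counts are depth-normalised per spot (to ``target_sum`` total), group
    means give the fold change, a two-sided Wilcoxon rank-sum test gives
    the per-gene p-value, and ``|FC| > fc_threshold`` (two-sided on the
    log scale) with adjusted p < ``alpha`` sets ``passes_filter``.
    Genes with zero counts in both groups are dropped.
    """
    if method not in ("bh", "bonferroni"):
        raise InvalidInputError(f"unknown adjustment method {method!r}")
    if bundle.group is None:
        raise InvalidInputError("bundle has no group labels")
    mask = np.asarray(spot_mask, dtype=bool)
    in_a = mask & (np.asarray(bundle.group) == group_a)
    in_b = mask & (np.asarray(bundle.group) == group_b)
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise InvalidInputError("each group needs at least 3 spots in the subset")

    X = np.asarray(bundle.counts.todense(), dtype=float)
    depth = X.sum(axis=0)
    depth[depth == 0] = 1.0
    X = X / depth * target_sum

    A, B = X[:, in_a], X[:, in_b]
    keep = (A.sum(axis=1) + B.sum(axis=1)) > 0
    genes = np.asarray(bundle.gene_ids)[keep]
    A, B = A[keep], B[keep]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(divide="ignore"):
        fc = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.inf)
        log2_fc = np.log2(fc)

    pvals = np.ones(len(genes))
    for i in range(len(genes)):
        if np.ptp(A[i]) == 0 and np.ptp(B[i]) == 0 and A[i][0] == B[i][0]:
            continue  # identical constant gene: no evidence either way
        pvals[i] = scipy.stats.mannwhitneyu(A[i], B[i], alternative="two-sided").pvalue
    if method == "bh":
        p_adj = bh_adjust(pvals)
    else:
        p_adj = np.minimum(pvals * len(pvals), 1.0)

    passes = (np.abs(log2_fc) > np.log2(fc_threshold)) & (p_adj < alpha)
    return pd.DataFrame(
        {
            "gene": genes,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": log2_fc,
            "p": pvals,
            "p_adj": p_adj,
            "passes_filter": passes,
        }
    )


def ddct_fold_change(delta_delta_ct: float) -> float:
    """Relative qPCR fold change, 2^(-ddCt)."""
    if not np.isfinite(delta_delta_ct):
        raise InvalidInputError("delta-delta-Ct must be finite")
    return float(2.0 ** (-delta_delta_ct))
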