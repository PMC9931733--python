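"""Three-stage astrocyte endfoot gene (AEG) screening cascade.

Stage 1 selects astrocyte marker genes from a cell-type reference
expression table: genes whose astrocyte mean exceeds every other
vascular cell type's mean by more than ``fold_threshold`` (default 100).
Stage 2 keeps markers that are endfoot-positive — gene ratio > 0 — in
strictly more than ``positive_fraction_threshold`` (default 60%) of
perivascular AC spots of the reference population.  Stage 3 keeps AEGs
whose group-mean ratio fold change in the disease group deviates from 1
by more than ``change_threshold`` (default 0.15).  The subset chain
ad_related ⊆ aegs ⊆ markers holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

__all__ = ["AEGScreenResult", "screen_markers", "call_aegs", "call_ad_aegs", "screen_cascade"]


@dataclass
class AEGScreenResult:
    marker_genes: list[str]
    aegs: list[str]
    ad_related_aegs: list[str]
    marker_stats: pd.DataFrame
    aeg_stats: pd.DataFrame
    ad_stats: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.ad_related_aegs) <= set(self.aegs) <= set(self.marker_genes):
            raise InvalidInputError("screen result violates the subset chain")


def screen_markers(
    ref: pd.DataFrame,
    fold_threshold: float = 100.0,
    astro_col: str = "astrocyte",
    zero_denominator_eps: float = 1e-6,
) -> pd.DataFrame:
    """Astrocyte markers: astro mean / max other-cell-type mean > threshold.

    ``ref`` is a gene x cell-type table of mean expression.  A denominator
    of exactly 0 (a perfectly astrocyte-specific gene) is replaced by
    ``zero_denominator_eps * ref.max()`` so such genes pass rather than
    divide by zero.  Returns the passing genes with their fold changes,
    sorted by descending fold change.
    """
    if astro_col not in ref.columns:
        raise ConfigurationError(f"reference has no {astro_col!r} column")
    if ref.shape[1] < 2:
        raise ConfigurationError("reference needs at least 2 cell types")
    if (ref.to_numpy() < 0).any():
        raise InvalidInputError("reference expression must be non-negative")
    astro = ref[astro_col]
    other = ref.drop(columns=[astro_col]).max(axis=1)
    eps = zero_denominator_eps * float(ref.to_numpy().max())
    fold = astro / other.where(other > 0, eps if eps > 0 else 1.0)
    out = pd.DataFrame({"gene": ref.index, "astro_mean": astro, "max_other_mean": other, "fold": fold})
    out = out[out["fold"] > fold_threshold]  # strictly greater
    return out.sort_values("fold", ascending=False).reset_index(drop=True)


def call_aegs(
    ratio_table: pd.DataFrame,
    marker_genes,
    positive_fraction_threshold: float = 0.60,
    reference_group: str | None = "WT",
) -> pd.DataFrame:
    """AEGs: marker genes with ratio > 0 in more than 60% of perivascular AC.

    The denominator is the number of perivascular AC spots in the
    reference population (``reference_group``; ``None`` pools every
    group), so AC spots where the gene's ratio is undefined count as
    not positive.  Genes with zero defined records are flagged
    (``no_records``) and never called.
    """
    marker_genes = list(marker_genes)
    sub = ratio_table
    if reference_group is not None:
        if "group" not in sub.columns:
            raise InvalidInputError("ratio table has no group column")
        sub = sub[sub["group"] == reference_group]
    n_ac = sub["barcode"].nunique()
    if n_ac == 0:
        raise InvalidInputError("no AC records in the reference population")
    rows = []
    by_gene = dict(tuple(sub.groupby("gene")))
    for gene in marker_genes:
        g = by_gene.get(gene)
        if g is None or len(g) == 0:
            rows.append({"gene": gene, "n_ac": n_ac, "n_positive": 0,
                         "positive_fraction": np.nan, "is_aeg": False, "flag": "no_records"})
            continue
        n_pos = int((g["ratio"] > 0).sum())
        frac = n_pos / n_ac
        rows.append({"gene": gene, "n_ac": n_ac, "n_positive": n_pos,
                     "positive_fraction": frac,
                     "is_aeg": frac > positive_fraction_threshold, "flag": ""})
    return pd.DataFrame(rows)


def call_ad_aegs(
    summary: pd.DataFrame,
    aegs,
    change_threshold: float = 0.15,
    disease_group: str = "APP/PS1",
    mode: str = "unsigned",
) -> pd.DataFrame:
    """AD-related AEGs: mean-ratio fold change deviating from 1 by > 0.15.

    ``summary`` is a :func:`aqpolar.polarization.summarize_ratios` table
    whose fold changes are relative to the healthy reference group.
    ``mode`` is "unsigned" (|fc - 1| > threshold, the default — keeps
    the rule symmetric) or "decrease" (1 - fc > threshold only).  Genes
    with an undefined fold change are flagged and excluded.
    """
    if mode not in ("unsigned", "decrease"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    aegs = list(aegs)
    dis = summary[summary["group"] == disease_group].set_index("gene")["fold_change"]
    rows = []
    for gene in aegs:
        fc = dis.get(gene, np.nan)
        if not np.isfinite(fc):
            rows.append({"gene": gene, "fold_change": np.nan, "ratio_change": np.nan,
                         "is_ad_related": False, "flag": "undefined_fold_change"})
            continue
        change = abs(fc - 1.0) if mode == "unsigned" else 1.0 - fc
        rows.append({"gene": gene, "fold_change": float(fc), "ratio_change": float(change),
                     "is_ad_related": change > change_threshold, "flag": ""})
    return pd.DataFrame(rows)


def screen_cascade(
    ref: pd.DataFrame,
    ratio_table: pd.DataFrame,
    summary: pd.DataFrame,
    fold_threshold: float = 100.0,
    positive_fraction_threshold: float = 0.60,
    change_threshold: float = 0.15,
    reference_group: str | None = "WT",
    disease_group: str = "APP/PS1",
    mode: str = "unsigned",
) -> AEGScreenResult:
    """Run the full marker -> AEG -> AD-related-AEG cascade."""
    marker_stats = screen_markers(ref, fold_threshold=fold_threshold)
    markers = list(marker_stats["gene"])
    covered = [g for g in markers if g in set(ratio_table["gene"])]
    aeg_stats = call_aegs(
        ratio_table, covered,
        positive_fraction_threshold=positive_fraction_threshold,
        reference_group=reference_group,
    )
    aegs = list(aeg_stats.loc[aeg_stats["is_aeg"], "gene"])
    ad_stats = call_ad_aegs(
        summary, aegs,
        change_threshold=change_threshold,
        disease_group=disease_group,
        mode=mode,
    )
    ad = list(ad_stats.loc[ad_stats["is_ad_related"], "gene"])
    return AEGScreenResult(
        marker_genes=markers, aegs=aegs, ad_related_aegs=ad,
        marker_stats=marker_stats, aeg_stats=aeg_stats, ad_stats=ad_stats,
    )
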