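"""The endfoot gene-ratio statistic and its group summaries.

For an AC spot with count ``a`` of a gene and an adjacent BBB spot with
count ``b``, the gene ratio is ``b / (a + b)`` — the share of the pair's
transcripts sitting at the vessel side, a proxy for how much of the
gene's mRNA has been trafficked to the astrocyte endfoot.  An AC spot
with several BBB neighbours takes the maximum ratio over neighbours.
Ratios are computed on raw counts within the matched spot pair; 0/0
pairs are undefined and dropped (imputing 0 would bias polarization
estimates of low-expression genes downward).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats
from .errors import ConfigurationError, InvalidInputError, UndefinedStatisticError
from .spotio import SpotBundle

__all__ = ["gene_ratio", "build_ratio_table", "summarize_ratios", "ratio_vs_ratio_fit"]

log = logging.getLogger(__name__)


def gene_ratio(ac_expr: float, bbb_exprs) -> float:
    """Max over neighbours b of ``b / (ac_expr + b)``; in [0, 1].

    Raises :class:`UndefinedStatisticError` when the AC count and every
    neighbour count are zero (0/0 has no polarization information).
    """
    bbb = np.asarray(bbb_exprs, dtype=float)
    if bbb.size == 0:
        raise InvalidInputError("need at least one BBB neighbour")
    if ac_expr < 0 or bbb.min() < 0:
        raise InvalidInputError("counts must be non-negative")
    denom = ac_expr + bbb
    defined = denom > 0
    if not defined.any():
        raise UndefinedStatisticError("0/0 gene ratio is undefined")
    return float(np.max(bbb[defined] / denom[defined]))


def build_ratio_table(
    bundle: SpotBundle,
    adjacency: dict[str, tuple[str, ...]],
    genes,
) -> pd.DataFrame:
    """One gene-ratio record per (perivascular AC, gene) with a defined ratio.

    Columns: barcode, gene, ac_expr, bbb_expr, ratio, neighbor, sample,
    group, region.  ``neighbor``/``bbb_expr`` identify the BBB spot that
    achieved the maximum (ties broken by ascending barcode).  Undefined
    (0/0) pairs are omitted; their count is recorded in
    ``df.attrs["qc"]`` and logged.
    """
    if not adjacency:
        raise InvalidInputError("adjacency map is empty")
    genes = list(genes)
    for g in genes:
        if g not in bundle.gene_ids:
            raise ConfigurationError(f"gene {g!r} not in the panel")

    barcode_index = {b: i for i, b in enumerate(bundle.barcodes)}
    ac_barcodes = sorted(adjacency)
    ac_idx, nb_idx, pair_ac = [], [], []
    for b in ac_barcodes:
        i = barcode_index[b]
        for nb in adjacency[b]:  # already in ascending barcode order
            ac_idx.append(i)
            nb_idx.append(barcode_index[nb])
            pair_ac.append(b)
    ac_idx = np.asarray(ac_idx)
    nb_idx = np.asarray(nb_idx)

    meta = bundle.spots_meta()
    dense = np.asarray(bundle.counts[[bundle.gene_index(g) for g in genes]].todense())

    frames = []
    n_pairs_total = len(genes) * len(ac_barcodes)  # (gene, AC) combinations
    pair_ac = np.asarray(pair_ac, dtype=object)
    for gi, gene in enumerate(genes):
        a = dense[gi, ac_idx]
        b = dense[gi, nb_idx]
        denom = a + b
        ok = denom > 0
        if not ok.any():
            continue
        df = pd.DataFrame(
            {
                "barcode": pair_ac[ok],
                "ac_expr": a[ok],
                "bbb_expr": b[ok],
                "ratio": b[ok] / denom[ok],
                "neighbor": np.asarray(bundle.barcodes)[nb_idx[ok]],
            }
        )
        # max rule; idxmax keeps the first (lowest-barcode) neighbour on ties
        best = df.loc[df.groupby("barcode", sort=False)["ratio"].idxmax()].copy()
        best.insert(1, "gene", gene)
        frames.append(best)

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["barcode", "gene", "ac_expr", "bbb_expr", "ratio", "neighbor"]
        )
    for col in ("sample", "group", "region"):
        if col in meta.columns:
            table[col] = meta[col].reindex(table["barcode"]).to_numpy()
    n_records = len(table)
    n_undefined = n_pairs_total - n_records
    table.attrs["qc"] = {"n_records": n_records, "n_undefined": n_undefined}
    log.info("ratio table: %d records, %d undefined (0/0) pairs dropped", n_records, n_undefined)
    return table


def summarize_ratios(
    table: pd.DataFrame,
    reference_group: str = "WT",
    by_region: bool = False,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Group means, fold changes vs the reference, and ANOVA/LSD p-values.

    One row per gene (x region when ``by_region``) x group with columns
    n, mean_ratio, fold_change (group mean / reference mean), anova_F,
    anova_p and lsd_p_vs_ref.  By default AC records are pooled across
    samples; ``per_sample`` first averages within each sample and treats
    sample means as the observations.  Strata where any group has n < 2
    are flagged and their test statistics left undefined.
    """
    if "group" not in table.columns:
        raise InvalidInputError("ratio table has no group column")
    groups_present = table["group"].unique()
    if len(groups_present) < 2 or reference_group not in groups_present:
        raise InvalidInputError("need >= 2 groups including the reference")

    strata = ["gene", "region"] if by_region else ["gene"]
    rows = []
    for key, sub in table.groupby(strata, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if per_sample:
            obs = sub.groupby(["group", "sample"])["ratio"].mean().reset_index()
            grouped = {g: v["ratio"].to_numpy() for g, v in obs.groupby("group")}
        else:
            grouped = {g: v.to_numpy() for g, v in sub.groupby("group")["ratio"]}
        ok = reference_group in grouped and len(grouped) >= 2
        degenerate = (not ok) or any(len(v) < 2 for v in grouped.values())
        res = None if degenerate else stats.anova_lsd(grouped)
        ref_mean = grouped[reference_group].mean() if reference_group in grouped else np.nan
        for g, vals in grouped.items():
            mean = float(np.mean(vals))
            lsd = np.nan
            if res is not None and g != reference_group:
                pair = (g, reference_group)
                lsd = res.pairwise.get(pair, res.pairwise.get(pair[::-1], np.nan))
            rows.append(
                dict(
                    zip(strata, key),
                    group=g,
                    n=len(vals),
                    mean_ratio=mean,
                    fold_change=mean / ref_mean if ref_mean and ref_mean > 0 else np.nan,
                    anova_F=res.F if res else np.nan,
                    anova_p=res.p if res else np.nan,
                    lsd_p_vs_ref=lsd,
                    flag="" if not degenerate else "undersized_stratum",
                )
            )
    return pd.DataFrame(rows)


def ratio_vs_ratio_fit(table_gene_a: pd.DataFrame, table_gene_b: pd.DataFrame) -> stats.PearsonFit:
    """Pearson fit between two genes' ratios over their common AC spots."""
    merged = pd.merge(
        table_gene_a[["barcode", "ratio"]],
        table_gene_b[["barcode", "ratio"]],
        on="barcode",
        suffixes=("_a", "_b"),
    )
    if len(merged) < 3:
        raise InvalidInputError("need >= 3 common AC spots")
    return stats.pearson_fit(merged["ratio_a"].to_numpy(), merged["ratio_b"].to_numpy())
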