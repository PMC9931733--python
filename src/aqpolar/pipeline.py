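"""End-to-end orchestration: simulate -> gate -> ratio -> screen -> score -> DE.

``AnalysisConfig`` is the single source of every named threshold; the
run manifest records it together with the seed so a result directory is
fully reproducible (a rerun with the same inputs is byte-identical).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aegscreen, gating, genescore, polarization, stats, synthdata
from .errors import AqpolarError
from .spotio import GeneSet, SpotBundle, save_bundle, save_results

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Every tunable threshold of the pipeline, with its default."""

    ac_markers: dict[str, float] = field(default_factory=lambda: {"Gfap": 0, "Aqp4": 0})
    bbb_markers: dict[str, float] = field(default_factory=lambda: {"Pecam1": 0, "Flt1": 0})
    ac_excluded_regions: tuple[str, ...] = ("glia limitans", "ependyma", "choroid plexus")
    bbb_excluded_regions: tuple[str, ...] = ("choroid plexus",)
    overlap_policy: str = "bbb"
    max_steps: int = 1
    reference_group: str = "WT"
    disease_group: str = "APP/PS1"
    marker_fold_threshold: float = 100.0
    positive_fraction_threshold: float = 0.60
    ratio_change_threshold: float = 0.15
    de_fc_threshold: float = 1.5
    de_alpha: float = 0.05
    score_bins: int = 24
    score_controls: int = 100
    score_threshold: float = 0.8
    if_percent: float = 1.0
    if_coated_threshold: float = 0.25
    if_pairing_radius_px: float = 3.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ac_excluded_regions"] = list(self.ac_excluded_regions)
        d["bbb_excluded_regions"] = list(self.bbb_excluded_regions)
        return d

    def gate_config(self) -> gating.GateConfig:
        return gating.GateConfig(
            ac_markers=self.ac_markers,
            bbb_markers=self.bbb_markers,
            ac_excluded_regions=self.ac_excluded_regions,
            bbb_excluded_regions=self.bbb_excluded_regions,
            overlap_policy=self.overlap_policy,
        )


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    synth_params: synthdata.SynthParams | None = None,
    bundle: SpotBundle | None = None,
    ratio_genes: list[str] | None = None,
    gene_sets: list[GeneSet] | None = None,
    celltype_ref: pd.DataFrame | None = None,
    write_bundle: bool = False,
) -> Path:
    """Run every stage and write TSV results plus a manifest to ``out_dir``.

    Provide either ``synth_params`` (the bundle and all side inputs are
    generated) or a loaded ``bundle`` (optionally with a gene-set list
    and cell-type reference).  Any stage failure aborts with the stage
    name prefixed to the cause.
    """
    if (synth_params is None) == (bundle is None):
        raise AqpolarError("provide exactly one of synth_params or bundle")
    out = Path(out_dir)
    tables: dict[str, pd.DataFrame] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise AqpolarError(f"stage {name!r} failed: {exc}") from exc

    truth = None
    if synth_params is not None:
        bundle, truth = stage("simulate", lambda: synthdata.generate_tissue(synth_params))
        tables["truth"] = truth
        allocated = list(synth_params.pi)
        if ratio_genes is None:
            ratio_genes = allocated
        if celltype_ref is None:
            bg = [g for g in bundle.gene_ids if str(g).startswith("Bg")][:30]
            markers = [g for g in allocated if g not in ("Pecam1", "Flt1")]
            celltype_ref = synthdata.generate_celltype_reference(
                markers, bg, seed=config.seed
            )
        if gene_sets is None:
            bg_all = [str(g) for g in bundle.gene_ids if str(g).startswith("Bg")]
            if len(bg_all) >= 20:
                rng = np.random.default_rng(config.seed)
                picked = sorted(rng.choice(bg_all, size=20, replace=False).tolist())
                gene_sets = [GeneSet("demo_set", "synthetic", tuple(picked))]
    if ratio_genes is None:
        ratio_genes = [g for g in ("Aqp4", "Gfap") if g in bundle.gene_ids]

    cls = stage("gate", lambda: gating.gate_spots(bundle, config.gate_config()))
    tables["classification"] = pd.DataFrame(
        {"barcode": cls.barcodes, "label": cls.labels}
    )
    adjacency = stage(
        "adjacency", lambda: gating.find_adjacent_pairs(cls, bundle, max_steps=config.max_steps)
    )
    tables["adjacency"] = pd.DataFrame(
        {"ac_barcode": list(adjacency), "bbb_barcodes": [",".join(v) for v in adjacency.values()]}
    )

    ratio_table = stage(
        "ratio", lambda: polarization.build_ratio_table(bundle, adjacency, ratio_genes)
    )
    tables["gene_ratios"] = ratio_table
    summary = stage(
        "summarize",
        lambda: polarization.summarize_ratios(ratio_table, reference_group=config.reference_group),
    )
    tables["ratio_summary"] = summary

    if celltype_ref is not None:
        screen = stage(
            "screen",
            lambda: aegscreen.screen_cascade(
                celltype_ref,
                ratio_table,
                summary,
                fold_threshold=config.marker_fold_threshold,
                positive_fraction_threshold=config.positive_fraction_threshold,
                change_threshold=config.ratio_change_threshold,
                reference_group=config.reference_group,
                disease_group=config.disease_group,
            ),
        )
        tables["marker_screen"] = screen.marker_stats
        tables["aeg_screen"] = screen.aeg_stats
        tables["ad_aeg_screen"] = screen.ad_stats

    if gene_sets:
        scores = stage(
            "score",
            lambda: genescore.module_scores(
                bundle,
                gene_sets,
                n_bins=config.score_bins,
                n_ctrl=config.score_controls,
                seed=config.seed,
            ),
        )
        tables["module_scores"] = scores
        comparisons = []
        for gs in gene_sets:
            comp = genescore.compare_scores(
                scores[scores["set_name"] == gs.name],
                threshold=config.score_threshold,
                reference_group=config.reference_group,
            )
            comp.insert(0, "set_name", gs.name)
            comparisons.append(comp)
        tables["score_comparison"] = pd.concat(comparisons, ignore_index=True)

    ac_mask = cls.mask(gating.AC)
    groups = set(np.asarray(bundle.group)) if bundle.group is not None else set()
    if {config.reference_group, config.disease_group} <= groups:
        de = stage(
            "de",
            lambda: stats.de_screen(
                bundle,
                ac_mask,
                config.disease_group,
                config.reference_group,
                fc_threshold=config.de_fc_threshold,
                alpha=config.de_alpha,
            ),
        )
        tables["de_screen"] = de

    stage("report", lambda: save_results(tables, out, config=config.to_dict(), seed=config.seed))
    if write_bundle:
        stage("write_bundle", lambda: save_bundle(bundle, out / "bundle"))
    return out
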