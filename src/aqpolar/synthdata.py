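"""Synthetic Visium-like tissue bundles and fluorescence fields with ground truth.

The tissue generator emulates the study design of a three-group mouse
brain experiment (WT, APP/PS1, APP/PS1+MOX): a hex lattice of spots,
contiguous region bands, randomly placed vessel (BBB) spots expressing
Pecam1/Flt1, and perivascular astrocyte (AC) spots expressing Gfap/Aqp4
next to them.  For every *allocated* gene, each AC-vessel pair draws a
negative-binomial total transcript count which is then split
binomially: a fraction pi goes to the vessel spot (the endfoot side)
and 1 - pi stays in the AC spot.  Because the split is binomial given
the total, the expected observed gene ratio equals pi exactly for any
dispersion, and pair totals are invariant to pi by construction.
Disease/treatment act multiplicatively on pi (delta < 1 for APP/PS1,
delta < delta' <= 1 for the moxibustion group).

The fluorescence generator draws annular CD31 vessels and paints AQP4
signal on each vessel's perimeter such that, under the package's own
coating quantifier, the recovered coated fraction matches the request
to within one perimeter pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from . import hexgrid, vesselcoat
from .errors import ConfigurationError, GenerationError
from .spotio import SpotBundle

__all__ = [
    "SynthParams",
    "generate_tissue",
    "truth_summary",
    "generate_if_field",
    "generate_celltype_reference",
    "DEFAULT_AEG_GENES",
]

#: plausible astrocyte-endfoot candidate gene symbols used by default
DEFAULT_AEG_GENES = (
    "Slc1a2", "Slc1a3", "Mlc1", "Gja1", "Kcnj10", "Slc4a4", "Slc6a11",
    "Slc7a10", "Gpr37l1", "Fgfr3", "Ntsr2", "Plpp3", "Atp1a2", "Atp1b2",
    "Cldn10", "Mertk", "Ednrb", "Acsbg1", "Sparcl1", "Aass",
)

MARKERS = ("Gfap", "Aqp4", "Pecam1", "Flt1")


@dataclass
class SynthParams:
    """Conditions of a simulated three-group spatial experiment.

    ``pi`` maps each allocated gene to its wild-type endfoot share;
    ``group_effects`` maps each group to either a scalar multiplier on
    pi (applied to every allocated gene except ``unaffected_genes``) or
    a per-gene dict of multipliers.  Effective shares are clipped to
    [0, 1].
    """

    lattice_rows: int = 80
    lattice_cols: int = 64
    regions: tuple[str, ...] = (
        "cortex", "hippocampus", "thalamus", "hypothalamus", "ependyma", "choroid plexus",
    )
    vessel_density: float = 0.10
    aeg_genes: tuple[str, ...] = DEFAULT_AEG_GENES
    n_background_genes: int = 200
    baseline_mean: float = 20.0
    background_log_mean: float = 1.0
    background_log_sd: float = 1.0
    nb_dispersion: float = 10.0  # math.inf -> Poisson limit
    pi: dict[str, float] | None = None
    group_effects: dict[str, float | dict[str, float]] = field(
        default_factory=lambda: {"WT": 1.0, "APP/PS1": 0.66, "APP/PS1+MOX": 0.9}
    )
    unaffected_genes: tuple[str, ...] = ("Gfap",)
    shifted_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    single_neighbor_only: bool = True
    marker_floor: bool = True
    orphan_ac_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_rows <= 0 or self.lattice_cols <= 0:
            raise ConfigurationError("lattice dimensions must be positive")
        if not 0 < self.vessel_density < 1:
            raise ConfigurationError("vessel_density must lie in (0, 1)")
        if len(self.regions) > self.lattice_rows:
            raise ConfigurationError("more region bands than lattice rows")
        if self.pi is None:
            self.pi = {"Aqp4": 0.7, "Gfap": 0.3, **{g: 0.7 for g in self.aeg_genes}}
        for g, p in self.pi.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"pi[{g!r}] = {p} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive (math.inf = Poisson)")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_effects)

    def effective_pi(self, gene: str, group: str) -> float:
        eff = self.group_effects[group]
        if isinstance(eff, dict):
            factor = eff.get(gene, 1.0)
        else:
            factor = 1.0 if gene in self.unaffected_genes else float(eff)
        return float(np.clip(self.pi[gene] * factor, 0.0, 1.0))

    @property
    def gene_panel(self) -> list[str]:
        bg = [f"Bg{i:03d}" for i in range(self.n_background_genes)]
        extra = [g for g in self.pi if g not in MARKERS and g not in self.aeg_genes]
        return list(MARKERS) + list(self.aeg_genes) + extra + bg


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative-binomial counts with the given mean and size parameter."""
    mean = np.asarray(mean, dtype=float)
    if not np.isfinite(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_tissue(params: SynthParams) -> tuple[SpotBundle, pd.DataFrame]:
    """Simulate a multi-group bundle plus its ground-truth table.

    One section (sample) per group; identical background gene means
    across groups (drawn once from a lognormal) so between-group
    differential expression exists only where ``shifted_genes`` says so.
    Returns ``(bundle, truth)`` where ``truth`` has one row per
    allocated gene x group with columns gene, group, true_pi,
    expected_ratio.  The bundle additionally carries ``spot_roles``
    (vessel / ac / orphan / other per spot) and ``pair_map`` (AC
    barcode -> paired vessel barcode) as generation ground truth.
    """
    panel = params.gene_panel
    gene_index = {g: i for i, g in enumerate(panel)}
    allocated = list(params.pi)
    ss = np.random.SeedSequence(params.seed)
    panel_rng = np.random.default_rng(ss.spawn(1)[0])
    group_seeds = ss.spawn(1 + len(params.groups))[1:]

    bg_genes = [g for g in panel if g.startswith("Bg")]
    bg_means = np.exp(
        panel_rng.normal(params.background_log_mean, params.background_log_sd, len(bg_genes))
    )

    positions = hexgrid.valid_positions(params.lattice_rows, params.lattice_cols)
    n_spots = len(positions)
    band = positions[:, 0] * len(params.regions) // params.lattice_rows
    region = np.asarray(params.regions, dtype=object)[band]
    pos_index = {(int(r), int(c)): i for i, (r, c) in enumerate(positions)}

    per_group: list[dict] = []
    truth_rows = []
    for group, child in zip(params.groups, group_seeds):
        rng = np.random.default_rng(child)
        counts = np.zeros((len(panel), n_spots), dtype=np.int32)

        n_vessels = max(1, round(params.vessel_density * n_spots))
        vessel_idx = rng.choice(n_spots, size=n_vessels, replace=False)
        is_vessel = np.zeros(n_spots, dtype=bool)
        is_vessel[vessel_idx] = True

        # vessel-neighbour lists for every non-vessel spot
        vessel_nbrs: list[list[int]] = [[] for _ in range(n_spots)]
        for i, (r, c) in enumerate(positions):
            if is_vessel[i]:
                continue
            for pos in hexgrid.neighbors(int(r), int(c)):
                j = pos_index.get(pos)
                if j is not None and is_vessel[j]:
                    vessel_nbrs[i].append(j)

        # one-to-one pairing: each vessel claims at most one astrocyte
        # neighbour, so the vessel spot's allocated counts come from a
        # single pair and the observed ratio has expectation pi exactly
        ac_idx, pair_vessel = [], []
        claimed = np.zeros(n_spots, dtype=bool)
        for v in sorted(int(j) for j in vessel_idx):
            cands = []
            for pos in hexgrid.neighbors(*map(int, positions[v])):
                j = pos_index.get(pos)
                if j is None or is_vessel[j] or claimed[j]:
                    continue
                if params.single_neighbor_only and len(vessel_nbrs[j]) > 1:
                    continue
                cands.append(j)
            if not cands:
                continue
            pick = int(rng.choice(cands)) if len(cands) > 1 else cands[0]
            claimed[pick] = True
            ac_idx.append(pick)
            pair_vessel.append(v)
        ac_idx = np.asarray(ac_idx, dtype=int)
        pair_vessel = np.asarray(pair_vessel, dtype=int)
        if len(ac_idx) == 0:
            raise GenerationError("no AC-vessel pairs generated; increase lattice or density")

        # endfoot allocation: NB pair total, binomial split by effective pi
        for gene in allocated:
            gi = gene_index[gene]
            pi_eff = params.effective_pi(gene, group)
            total = _nb_draw(rng, params.baseline_mean, params.nb_dispersion, size=len(ac_idx))
            to_vessel = rng.binomial(total, pi_eff)
            counts[gi, ac_idx] += (total - to_vessel).astype(np.int32)
            np.add.at(counts[gi], pair_vessel, to_vessel.astype(np.int32))
            truth_rows.append(
                {"gene": gene, "group": group, "true_pi": pi_eff, "expected_ratio": pi_eff}
            )

        # endothelial markers at vessel spots
        for gene in ("Pecam1", "Flt1"):
            gi = gene_index[gene]
            counts[gi, vessel_idx] = _nb_draw(
                rng, params.baseline_mean, params.nb_dispersion, size=n_vessels
            )

        # orphan astrocyte-like spots away from any vessel (dropped by pairing)
        lonely = [i for i, nbrs in enumerate(vessel_nbrs) if not nbrs and not is_vessel[i]]
        n_orphan = round(params.orphan_ac_fraction * n_spots)
        if n_orphan and lonely:
            orphans = rng.choice(lonely, size=min(n_orphan, len(lonely)), replace=False)
            for gene in ("Gfap", "Aqp4"):
                gi = gene_index[gene]
                counts[gi, orphans] = _nb_draw(
                    rng, params.baseline_mean / 4.0, params.nb_dispersion, size=len(orphans)
                )

        # background genes everywhere, with optional per-group mean shifts
        if bg_genes:
            means = bg_means.copy()
            for gene, shifts in params.shifted_genes.items():
                if gene in gene_index and gene_index[gene] >= len(panel) - len(bg_genes):
                    means[gene_index[gene] - (len(panel) - len(bg_genes))] *= shifts.get(group, 1.0)
            bg0 = len(panel) - len(bg_genes)
            counts[bg0:, :] = _nb_draw(
                rng, means[:, None], params.nb_dispersion, size=(len(bg_genes), n_spots)
            )

        if params.marker_floor:
            for gene in ("Gfap", "Aqp4"):
                gi = gene_index[gene]
                sel = counts[gi, ac_idx]
                counts[gi, ac_idx] = np.maximum(sel, 1)
                if n_orphan and lonely:
                    counts[gi, orphans] = np.maximum(counts[gi, orphans], 1)
            for gene in ("Pecam1", "Flt1"):
                gi = gene_index[gene]
                counts[gi, vessel_idx] = np.maximum(counts[gi, vessel_idx], 1)

        roles = np.full(n_spots, "other", dtype=object)
        roles[vessel_idx] = "vessel"
        roles[ac_idx] = "ac"
        if n_orphan and lonely:
            roles[orphans] = "orphan"
        per_group.append(
            {"group": group, "counts": counts, "roles": roles,
             "pairs": list(zip(ac_idx.tolist(), pair_vessel.tolist()))}
        )

    # concatenate the per-group sections into one bundle
    pxl_row, pxl_col = hexgrid.pixel_coords(positions[:, 0], positions[:, 1])
    all_counts = sp.hstack([sp.csr_matrix(g["counts"]) for g in per_group], format="csr")
    barcodes, samples, groups_col = [], [], []
    for g in per_group:
        sample = g["group"]
        barcodes.extend(f"{sample}:{i:05d}" for i in range(n_spots))
        samples.extend([sample] * n_spots)
        groups_col.extend([g["group"]] * n_spots)
    n_rep = len(per_group)
    bundle = SpotBundle(
        counts=all_counts,
        gene_ids=np.asarray(panel, dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
        array_row=np.tile(positions[:, 0], n_rep),
        array_col=np.tile(positions[:, 1], n_rep),
        pxl_row=np.tile(pxl_row, n_rep),
        pxl_col=np.tile(pxl_col, n_rep),
        in_tissue=np.ones(n_spots * n_rep, dtype=bool),
        region=np.tile(region, n_rep),
        sample=np.asarray(samples, dtype=object),
        group=np.asarray(groups_col, dtype=object),
    )
    # generation ground truth, for parameter-recovery and consistency tests
    bundle.spot_roles = np.concatenate([g["roles"] for g in per_group])
    bundle.pair_map = {
        f"{g['group']}:{a:05d}": f"{g['group']}:{v:05d}"
        for g in per_group
        for a, v in g["pairs"]
    }
    truth = pd.DataFrame(truth_rows)
    return bundle, truth


def truth_summary(truth: pd.DataFrame, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-gene true-ratio fold change expected_ratio(a) / expected_ratio(b)."""
    for g in (group_a, group_b):
        if g not in set(truth["group"]):
            raise LookupError(f"group {g!r} not in the truth table")
    a = truth[truth["group"] == group_a].set_index("gene")["expected_ratio"]
    b = truth[truth["group"] == group_b].set_index("gene")["expected_ratio"]
    fc = (a / b).rename("true_fold_change")
    return fc.reset_index()


def generate_celltype_reference(
    marker_genes,
    nonmarker_genes,
    astro_marker_mean: float = 500.0,
    other_marker_mean: float = 2.0,
    shared_mean: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic stand-in for a vascular single-cell mean-expression table.

    Marker genes are astrocyte-specific (large astro/other fold); the
    rest are shared across the vascular cell types.  Columns are cell
    types, index is gene.
    """
    rng = np.random.default_rng(seed)
    cell_types = ["astrocyte", "endothelial", "pericyte", "smooth_muscle", "microglia"]
    genes = list(marker_genes) + list(nonmarker_genes)
    data = np.empty((len(genes), len(cell_types)))
    n_mark = len(list(marker_genes))
    for i in range(len(genes)):
        if i < n_mark:
            data[i, 0] = astro_marker_mean * rng.uniform(0.8, 1.2)
            data[i, 1:] = other_marker_mean * rng.uniform(0.5, 1.5, len(cell_types) - 1)
        else:
            data[i, :] = shared_mean * rng.uniform(0.5, 1.5, len(cell_types))
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=cell_types)


# --------------------------------------------------------------------------
# fluorescence fields


def generate_if_field(
    n_vessels: int,
    coated_fractions,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    vessel_radius: int = 12,
    ring_width: int = 3,
    pairing_radius_px: float = 3.0,
    intensity: int = 40000,
    um_per_px: float = 1.0,
    max_tries: int = 5000,
) -> vesselcoat.FluorescenceField:
    """A two-channel raster with annular vessels coated to known fractions.

    AQP4 signal is painted on each vessel's own perimeter pixels such
    that the set of perimeter pixels within ``pairing_radius_px`` of the
    signal covers the requested fraction to within one perimeter pixel
    (exact construction, verified against the package's quantifier
    geometry).  ``noise_sd`` adds Gaussian intensity noise to both
    channels.
    """
    coated_fractions = list(coated_fractions)
    if len(coated_fractions) != n_vessels:
        raise ConfigurationError("coated_fractions must have length n_vessels")
    if any(not 0 <= f <= 1 for f in coated_fractions):
        raise ConfigurationError("coated fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    margin = vessel_radius + int(math.ceil(pairing_radius_px)) + 2
    min_sep = 2 * margin

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_vessels:
        if tries >= max_tries:
            raise GenerationError("could not place non-overlapping vessels")
        tries += 1
        r = int(rng.integers(margin, shape[0] - margin))
        c = int(rng.integers(margin, shape[1] - margin))
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in centers):
            centers.append((r, c))

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cd31 = np.zeros(shape, dtype=float)
    for r, c in centers:
        dist = np.hypot(rr - r, cc - c)
        cd31[(dist <= vessel_radius) & (dist >= vessel_radius - ring_width)] = intensity
    if (cd31 > 0).sum() >= 0.01 * cd31.size:
        raise GenerationError("vessel area exceeds the 1% intensity threshold budget")

    # use the package's own detector so the painted arcs line up exactly
    # with the perimeter definition used at analysis time
    vessels = vesselcoat.detect_vessels(cd31, mask=cd31 > 0)
    if len(vessels) != n_vessels:
        raise GenerationError("vessel detection on the clean field failed")
    order = [
        int(np.argmin([np.hypot(v.centroid[0] - r, v.centroid[1] - c) for v in vessels]))
        for r, c in centers
    ]

    aqp4 = np.zeros(shape, dtype=float)
    annotations = []
    for (r, c), f in zip(centers, coated_fractions):
        v = vessels[order[centers.index((r, c))]]
        perim = v.perimeter
        ang = np.arctan2(perim[:, 0] - r, perim[:, 1] - c)
        perim = perim[np.argsort(ang, kind="stable")]
        n_perim = len(perim)
        k = int(round(f * n_perim))
        achieved = _paint_arc(aqp4, perim, k, pairing_radius_px, intensity)
        annotations.append(
            {
                "center": [r, c],
                "radius": vessel_radius,
                "requested_fraction": float(f),
                "achieved_fraction": achieved / n_perim,
                "n_perimeter": n_perim,
            }
        )
    if (aqp4 > 0).sum() >= 0.01 * aqp4.size:
        raise GenerationError("AQP4 area exceeds the 1% intensity threshold budget")

    if noise_sd > 0:
        cd31 = cd31 + rng.normal(0.0, noise_sd, shape)
        aqp4 = aqp4 + rng.normal(0.0, noise_sd, shape)
    cd31 = np.clip(cd31, 0, 65535).astype(np.uint16)
    aqp4 = np.clip(aqp4, 0, 65535).astype(np.uint16)
    return vesselcoat.FluorescenceField(
        cd31=cd31, aqp4=aqp4, um_per_px=um_per_px, annotations=annotations
    )


def _paint_arc(
    aqp4: np.ndarray,
    perim: np.ndarray,
    k: int,
    pairing_radius_px: float,
    intensity: float,
) -> int:
    """Paint a contiguous arc so ~k perimeter pixels end up within radius.

    Scans the arc end point until the number of covered perimeter
    pixels is as close to ``k`` as the pixel grid permits; returns the
    achieved count.
    """
    n = len(perim)
    if k <= 0:
        return 0
    if k >= n:
        aqp4[perim[:, 0], perim[:, 1]] = intensity
        return n
    D = cdist(perim, perim)
    start = max(1, int(math.ceil(pairing_radius_px)) + 1)  # keep clear of the angular cut
    covered = np.zeros(n, dtype=bool)
    best = (10**9, start)  # (|count - k|, end index)
    counts = []
    for end in range(start, n):
        covered |= D[:, end] <= pairing_radius_px
        cnt = int(covered.sum())
        counts.append(cnt)
        if abs(cnt - k) < best[0]:
            best = (abs(cnt - k), end)
        if cnt >= k:
            break
    end = best[1]
    sel = perim[start : end + 1]
    aqp4[sel[:, 0], sel[:, 1]] = intensity
    # recompute the achieved coverage for the annotation
    cov = (D[:, start : end + 1] <= pairing_radius_px).any(axis=1)
    return int(cov.sum())
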