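"""Marker gating of spots and AC-to-vessel spatial pairing.

Perivascular astrocyte (AC) spots are those expressing both astrocyte
markers (default Gfap > 0 and Aqp4 > 0) outside CSF-facing regions that
carry astrocyte markers without being perivascular (glia limitans,
ependyma, choroid plexus).  Blood-brain-barrier (BBB) spots express both
endothelial markers (default Pecam1 > 0 and Flt1 > 0) outside the
choroid plexus.  A spot passing both gates is resolved by
``overlap_policy``: by default it counts as BBB only, which avoids
counting the astrocyte soma of a mixed spot twice.

Pairing walks the hex lattice: an AC spot is *perivascular* if at least
one spot within ``max_steps`` lattice steps (default 1, i.e. the six
immediate neighbours) is BBB-labelled.  Pairing never crosses samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hexgrid
from .errors import ConfigurationError
from .spotio import SpotBundle

__all__ = ["GateConfig", "SpotClassification", "gate_spots", "find_adjacent_pairs"]

AC = "AC"
BBB = "BBB"
OTHER = "other"


@dataclass(frozen=True)
class GateConfig:
    """Thresholds and exclusions for the AC/BBB gates.

    Marker dicts map gene -> minimum count; a spot passes a gate when
    every marker count is strictly greater than its minimum.
    """

    ac_markers: dict[str, float] = field(default_factory=lambda: {"Gfap": 0, "Aqp4": 0})
    bbb_markers: dict[str, float] = field(default_factory=lambda: {"Pecam1": 0, "Flt1": 0})
    ac_excluded_regions: tuple[str, ...] = ("glia limitans", "ependyma", "choroid plexus")
    bbb_excluded_regions: tuple[str, ...] = ("choroid plexus",)
    overlap_policy: str = "bbb"  # "bbb" | "ac" | "drop"

    def __post_init__(self) -> None:
        if self.overlap_policy not in ("bbb", "ac", "drop"):
            raise ConfigurationError(f"unknown overlap_policy {self.overlap_policy!r}")
        for markers in (self.ac_markers, self.bbb_markers):
            for gene, thr in markers.items():
                if thr < 0:
                    raise ConfigurationError(f"negative threshold for marker {gene!r}")


@dataclass
class SpotClassification:
    """Exhaustive, exclusive per-spot labels: AC, BBB or other."""

    barcodes: np.ndarray
    labels: np.ndarray  # values in {AC, BBB, other}

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    @property
    def n_ac(self) -> int:
        return int((self.labels == AC).sum())

    @property
    def n_bbb(self) -> int:
        return int((self.labels == BBB).sum())


def _passes(bundle: SpotBundle, markers: dict[str, float]) -> np.ndarray:
    ok = np.ones(bundle.n_spots, dtype=bool)
    for gene, thr in markers.items():
        if gene not in bundle.gene_ids:
            raise ConfigurationError(f"marker gene {gene!r} not in the panel")
        ok &= bundle.gene_counts(gene) > thr
    return ok


def gate_spots(bundle: SpotBundle, config: GateConfig | None = None) -> SpotClassification:
    """Label every spot AC, BBB or other by raw-count marker gates.

    Gates use raw counts (detection, not normalised expression).  Spots
    in an excluded region never receive the corresponding label,
    whatever their markers.  Out-of-tissue spots are always ``other``.
    """
    config = config or GateConfig()
    ac = _passes(bundle, config.ac_markers)
    bbb = _passes(bundle, config.bbb_markers)
    if bundle.region is not None:
        region = np.asarray(bundle.region)
        ac &= ~np.isin(region, config.ac_excluded_regions)
        bbb &= ~np.isin(region, config.bbb_excluded_regions)
    in_tissue = np.asarray(bundle.in_tissue, dtype=bool)
    ac &= in_tissue
    bbb &= in_tissue

    both = ac & bbb
    if config.overlap_policy == "bbb":
        ac &= ~both
    elif config.overlap_policy == "ac":
        bbb &= ~both
    else:  # drop
        ac &= ~both
        bbb &= ~both

    labels = np.full(bundle.n_spots, OTHER, dtype=object)
    labels[bbb] = BBB
    labels[ac] = AC
    return SpotClassification(barcodes=np.asarray(bundle.barcodes), labels=labels)


def find_adjacent_pairs(
    cls: SpotClassification,
    bundle: SpotBundle,
    max_steps: int = 1,
) -> dict[str, tuple[str, ...]]:
    """Map each perivascular AC barcode to its adjacent BBB barcodes.

    Neighbours are the hex-lattice positions reachable in at most
    ``max_steps`` steps within the same sample, listed in ascending
    barcode order.  AC spots with no BBB neighbour are dropped.
    """
    if len(cls.barcodes) != bundle.n_spots or not np.array_equal(cls.barcodes, bundle.barcodes):
        raise ConfigurationError("classification is not aligned with the bundle")
    if max_steps < 1:
        raise ConfigurationError("max_steps must be >= 1")

    sample = (
        np.asarray(bundle.sample)
        if bundle.sample is not None
        else np.full(bundle.n_spots, "sample", dtype=object)
    )
    index: dict[tuple[str, int, int], int] = {
        (sample[i], int(r), int(c)): i
        for i, (r, c) in enumerate(zip(bundle.array_row, bundle.array_col))
    }
    bbb_mask = cls.mask(BBB)
    out: dict[str, tuple[str, ...]] = {}
    for i in np.flatnonzero(cls.mask(AC)):
        found: set[int] = set()
        frontier = {(int(bundle.array_row[i]), int(bundle.array_col[i]))}
        seen = set(frontier)
        for _ in range(max_steps):
            nxt = set()
            for r, c in frontier:
                for pos in hexgrid.neighbors(r, c):
                    if pos in seen:
                        continue
                    seen.add(pos)
                    nxt.add(pos)
                    j = index.get((sample[i], *pos))
                    if j is not None and bbb_mask[j]:
                        found.add(j)
            frontier = nxt
        if found:
            out[cls.barcodes[i]] = tuple(sorted(cls.barcodes[j] for j in found))
    return out
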