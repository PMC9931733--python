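import itertools

import numpy as np
import pytest

from aqpolar import hexgrid
from aqpolar.errors import ConfigurationError
from aqpolar.gating import AC, BBB, OTHER, GateConfig, find_adjacent_pairs, gate_spots

from conftest import make_bundle

GENES = ["Gfap", "Aqp4", "Pecam1", "Flt1"]


def _labels(bundle, config=None):
    cls = gate_spots(bundle, config)
    return dict(zip(cls.barcodes, cls.labels))


def test_marker_gate_requires_both_markers():
    """A spot with Gfap detected but Aqp4 absent is not an astrocyte spot."""
    spots = [
        {"barcode": "a", "row": 0, "col": 0, "counts": {"Gfap": 1}},
        {"barcode": "b", "row": 4, "col": 0, "counts": {}},  # all-zero spot
    ]
    labels = _labels(make_bundle(GENES, spots))
    assert labels == {"a": OTHER, "b": OTHER}


def test_five_spot_rule_enumeration():
    """Hand-built spots cover each gate rule and the overlap policy."""
    spots = [
        {"barcode": "A", "row": 0, "col": 0, "counts": {"Gfap": 1, "Aqp4": 2}},
        {"barcode": "B", "row": 0, "col": 4, "counts": {"Aqp4": 3}},
        {"barcode": "C", "row": 2, "col": 0, "region": "choroid plexus",
         "counts": {"Gfap": 1, "Aqp4": 1}},
        {"barcode": "D", "row": 2, "col": 4, "counts": {"Pecam1": 2, "Flt1": 1}},
        {"barcode": "E", "row": 4, "col": 0,
         "counts": {"Gfap": 1, "Aqp4": 1, "Pecam1": 1, "Flt1": 1}},
    ]
    bundle = make_bundle(GENES, spots)
    labels = _labels(bundle)
    assert labels == {"A": AC, "B": OTHER, "C": OTHER, "D": BBB, "E": BBB}
    # alternative overlap policies re-label only the double-positive spot
    labels_ac = _labels(bundle, GateConfig(overlap_policy="ac"))
    assert labels_ac["E"] == AC and labels_ac["A"] == AC and labels_ac["D"] == BBB
    labels_drop = _labels(bundle, GateConfig(overlap_policy="drop"))
    assert labels_drop["E"] == OTHER


def test_excluded_regions_beat_markers():
    spots = [
        {"barcode": "v", "row": 0, "col": 0, "region": "choroid plexus",
         "counts": {"Pecam1": 5, "Flt1": 5}},
        {"barcode": "a", "row": 2, "col": 0, "region": "ependyma",
         "counts": {"Gfap": 5, "Aqp4": 5}},
    ]
    labels = _labels(make_bundle(GENES, spots))
    assert labels == {"v": OTHER, "a": OTHER}


def test_missing_marker_gene_is_configuration_error():
    bundle = make_bundle(["Gfap", "Aqp4"], [{"barcode": "a", "row": 0, "col": 0}])
    with pytest.raises(ConfigurationError, match="Pecam1"):
        gate_spots(bundle)


def test_gating_partition_and_order_independence(small_tissue):
    _, bundle, _ = small_tissue
    cls = gate_spots(bundle)
    assert cls.n_ac + cls.n_bbb + int((cls.labels == OTHER).sum()) == bundle.n_spots
    # permuting the spots permutes the labels with them
    rng = np.random.default_rng(0)
    perm = rng.permutation(bundle.n_spots)
    permuted = gate_spots(bundle.subset_spots(perm))
    orig = dict(zip(cls.barcodes, cls.labels))
    assert all(orig[b] == l for b, l in zip(permuted.barcodes, permuted.labels))


def test_hex_neighbor_example():
    """An AC at (2,4) is adjacent to BBB spots at (2,6) and (3,5)."""
    spots = [
        {"barcode": "ac", "row": 2, "col": 4, "counts": {"Gfap": 1, "Aqp4": 1}},
        {"barcode": "b1", "row": 2, "col": 6, "counts": {"Pecam1": 1, "Flt1": 1}},
        {"barcode": "b2", "row": 3, "col": 5, "counts": {"Pecam1": 1, "Flt1": 1}},
        {"barcode": "far", "row": 6, "col": 4, "counts": {"Pecam1": 1, "Flt1": 1}},
    ]
    bundle = make_bundle(GENES, spots)
    adj = find_adjacent_pairs(gate_spots(bundle), bundle)
    assert adj == {"ac": ("b1", "b2")}


def test_lone_ac_yields_empty_map():
    spots = [{"barcode": "ac", "row": 0, "col": 0, "counts": {"Gfap": 1, "Aqp4": 1}}]
    bundle = make_bundle(GENES, spots)
    assert find_adjacent_pairs(gate_spots(bundle), bundle) == {}


def test_adjacency_never_crosses_samples():
    spots = [
        {"barcode": "s1:a", "row": 0, "col": 0, "sample": "s1",
         "counts": {"Gfap": 1, "Aqp4": 1}},
        {"barcode": "s2:b", "row": 0, "col": 2, "sample": "s2",
         "counts": {"Pecam1": 1, "Flt1": 1}},
    ]
    bundle = make_bundle(GENES, spots)
    assert find_adjacent_pairs(gate_spots(bundle), bundle) == {}


def test_max_steps_two_reaches_second_ring():
    spots = [
        {"barcode": "ac", "row": 0, "col": 0, "counts": {"Gfap": 1, "Aqp4": 1}},
        {"barcode": "b", "row": 0, "col": 4, "counts": {"Pecam1": 1, "Flt1": 1}},
    ]
    bundle = make_bundle(GENES, spots)
    cls = gate_spots(bundle)
    assert find_adjacent_pairs(cls, bundle, max_steps=1) == {}
    assert find_adjacent_pairs(cls, bundle, max_steps=2) == {"ac": ("b",)}


def test_hex_rule_matches_euclidean_oracle():
    """On a 6x6 block, lattice neighbours are exactly the pixel-distance-
    minimal pairs (centre-to-centre one pitch apart)."""
    positions = hexgrid.valid_positions(6, 6)
    py, px = hexgrid.pixel_coords(positions[:, 0], positions[:, 1])
    offsets = set(hexgrid.NEIGHBOR_OFFSETS)
    for i, j in itertools.combinations(range(len(positions)), 2):
        d = np.hypot(py[i] - py[j], px[i] - px[j])
        is_rule_neighbor = (
            (positions[j, 0] - positions[i, 0], positions[j, 1] - positions[i, 1]) in offsets
        )
        assert is_rule_neighbor == (d <= hexgrid.SPOT_PITCH_UM + 1e-9)


def test_lattice_adjacency_is_symmetric():
    for dr, dc in hexgrid.NEIGHBOR_OFFSETS:
        assert (-dr, -dc) in hexgrid.NEIGHBOR_OFFSETS
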