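import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqpolar import synthdata
from aqpolar.errors import InvalidInputError, UndefinedStatisticError
from aqpolar.gating import find_adjacent_pairs, gate_spots
from aqpolar.polarization import (
    build_ratio_table,
    gene_ratio,
    ratio_vs_ratio_fit,
    summarize_ratios,
)

from conftest import make_bundle

GENES = ["Gfap", "Aqp4", "Pecam1", "Flt1"]


@pytest.mark.parametrize(
    "ac,bbb,expected",
    [
        (0, [3], 1.0),  # all signal at the endfoot
        (5, [0], 0.0),
        (2, [2, 6], 0.75),  # max(2/4, 6/8)
        (1, [1], 0.5),
        (0, [0, 2], 1.0),  # undefined neighbour skipped, defined one wins
    ],
)
def test_gene_ratio_examples(ac, bbb, expected):
    assert gene_ratio(ac, bbb) == pytest.approx(expected)


def test_gene_ratio_zero_over_zero_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        gene_ratio(0, [0, 0])


counts = st.integers(min_value=0, max_value=1000)


@settings(derandomize=True, max_examples=200)
@given(ac=counts, bbb=st.lists(counts, min_size=1, max_size=6))
def test_gene_ratio_bounds_and_max_rule(ac, bbb):
    if ac == 0 and max(bbb) == 0:
        return
    r = gene_ratio(ac, bbb)
    assert 0.0 <= r <= 1.0
    # adding a neighbour never decreases the ratio
    assert gene_ratio(ac, bbb + [3]) >= r
    # ratio is non-decreasing in any bbb count, non-increasing in ac
    bumped = list(bbb)
    bumped[0] += 1
    assert gene_ratio(ac, bumped) >= r
    assert gene_ratio(ac + 1, bbb) <= r


@settings(derandomize=True, max_examples=100)
@given(ac=counts, bbb=st.lists(counts, min_size=1, max_size=6),
       scale=st.integers(min_value=1, max_value=50))
def test_gene_ratio_scale_invariance(ac, bbb, scale):
    if ac == 0 and max(bbb) == 0:
        return
    r = gene_ratio(ac, bbb)
    assert gene_ratio(ac * scale, [b * scale for b in bbb]) == pytest.approx(r)


def _paired_bundle():
    spots = [
        {"barcode": "ac1", "row": 0, "col": 0,
         "counts": {"Gfap": 2, "Aqp4": 1}},
        {"barcode": "v1", "row": 0, "col": 2,
         "counts": {"Pecam1": 1, "Flt1": 1, "Aqp4": 1, "Gfap": 2}},
        {"barcode": "v2", "row": 1, "col": 1,
         "counts": {"Pecam1": 1, "Flt1": 1, "Aqp4": 6, "Gfap": 0}},
    ]
    return make_bundle(GENES, spots)


def test_build_ratio_table_single_pair_and_argmax():
    bundle = _paired_bundle()
    adj = find_adjacent_pairs(gate_spots(bundle), bundle)
    table = build_ratio_table(bundle, adj, ["Aqp4", "Gfap"])
    aqp4 = table[table.gene == "Aqp4"].iloc[0]
    # max(1/2, 6/7) -> neighbour v2
    assert aqp4["ratio"] == pytest.approx(6 / 7)
    assert aqp4["neighbor"] == "v2"
    gfap = table[table.gene == "Gfap"].iloc[0]
    # max(2/4, 0/2) -> v1; ties and zeros resolved toward defined max
    assert gfap["ratio"] == pytest.approx(0.5)
    assert gfap["neighbor"] == "v1"
    assert table.attrs["qc"]["n_undefined"] == 0


def test_build_ratio_table_drops_undefined_pairs():
    spots = [
        {"barcode": "ac1", "row": 0, "col": 0, "counts": {"Gfap": 2, "Aqp4": 1}},
        {"barcode": "v1", "row": 0, "col": 2, "counts": {"Pecam1": 1, "Flt1": 1}},
    ]
    bundle = make_bundle(GENES, spots)
    adj = find_adjacent_pairs(gate_spots(bundle), bundle)
    table = build_ratio_table(bundle, adj, ["Aqp4", "Flt1"])
    # Flt1: AC has 0, vessel neighbour has 1 -> ratio 1; Aqp4: 1 vs 0 -> 0
    assert set(table.gene) == {"Aqp4", "Flt1"}
    # Gfap never requested; an absent-on-both-sides gene would be dropped
    spots[1]["counts"] = {"Pecam1": 1, "Flt1": 1}
    bundle2 = make_bundle(["Gfap", "Aqp4", "Pecam1", "Flt1", "Empty"], spots)
    adj2 = find_adjacent_pairs(gate_spots(bundle2), bundle2)
    table2 = build_ratio_table(bundle2, adj2, ["Empty"])
    assert len(table2) == 0
    assert table2.attrs["qc"]["n_undefined"] == 1


def test_build_ratio_table_unknown_gene_errors():
    bundle = _paired_bundle()
    adj = find_adjacent_pairs(gate_spots(bundle), bundle)
    from aqpolar.errors import ConfigurationError

    with pytest.raises(ConfigurationError, match="Nope"):
        build_ratio_table(bundle, adj, ["Nope"])


def test_pi_one_gives_all_ratios_one():
    """A gene fully allocated to the endfoot has zero AC counts and ratio 1."""
    params = synthdata.SynthParams(
        lattice_rows=20, lattice_cols=20, n_background_genes=0,
        pi={"Aqp4": 0.7, "Gfap": 0.3, "Slc1a2": 1.0},
        aeg_genes=("Slc1a2",),
        group_effects={"WT": 1.0},
        seed=4,
    )
    bundle, _ = synthdata.generate_tissue(params)
    ac_spots = bundle.spot_roles == "ac"
    assert (bundle.gene_counts("Slc1a2")[ac_spots] == 0).all()
    adj = find_adjacent_pairs(gate_spots(bundle), bundle)
    table = build_ratio_table(bundle, adj, ["Slc1a2"])
    assert (table["ratio"] == 1.0).all()


def test_summarize_ratios_hand_means():
    """Fold change is the ratio of group means: 0.4/0.7 for these values."""
    import pandas as pd

    table = pd.DataFrame({
        "barcode": [f"b{i}" for i in range(6)],
        "gene": "Aqp4",
        "ratio": [0.8, 0.6, 0.7, 0.4, 0.5, 0.3],
        "group": ["WT"] * 3 + ["APP/PS1"] * 3,
        "sample": ["s"] * 6,
    })
    out = summarize_ratios(table, reference_group="WT")
    ad = out[out.group == "APP/PS1"].iloc[0]
    assert ad["fold_change"] == pytest.approx(0.4 / 0.7)
    assert ad["n"] == 3


def test_summarize_identical_groups():
    import pandas as pd

    table = pd.DataFrame({
        "barcode": [f"b{i}" for i in range(6)],
        "gene": "Aqp4",
        "ratio": [0.5, 0.6, 0.7] * 2,
        "group": ["WT"] * 3 + ["APP/PS1"] * 3,
        "sample": ["s"] * 6,
    })
    out = summarize_ratios(table)
    assert np.allclose(out["fold_change"], 1.0)
    assert out["anova_F"].iloc[0] == pytest.approx(0.0)


def test_summarize_flags_undersized_stratum():
    import pandas as pd

    table = pd.DataFrame({
        "barcode": ["a", "b", "c"],
        "gene": "Aqp4",
        "ratio": [0.5, 0.6, 0.7],
        "group": ["WT", "WT", "APP/PS1"],
        "sample": "s",
    })
    out = summarize_ratios(table)
    assert (out["flag"] == "undersized_stratum").all()
    assert out["anova_p"].isna().all()


def test_ratio_vs_ratio_identical_vectors():
    import pandas as pd

    t = pd.DataFrame({"barcode": ["a", "b", "c"], "ratio": [0.1, 0.5, 0.9]})
    fit = ratio_vs_ratio_fit(t, t)
    assert fit.r == pytest.approx(1.0)
    assert fit.slope == pytest.approx(1.0)


def test_ratio_vs_ratio_closed_form():
    import pandas as pd

    ta = pd.DataFrame({"barcode": ["a", "b", "c"], "ratio": [0.0, 1.0, 2.0]})
    tb = pd.DataFrame({"barcode": ["a", "b", "c"], "ratio": [0.0, 2.0, 2.0]})
    fit = ratio_vs_ratio_fit(ta, tb)
    assert fit.r == pytest.approx(np.sqrt(3) / 2)
    assert fit.slope == pytest.approx(1.0)


def test_ratio_vs_ratio_independent_ratios_near_zero():
    rng = np.random.default_rng(11)
    import pandas as pd

    n = 5000
    bc = [f"b{i}" for i in range(n)]
    ta = pd.DataFrame({"barcode": bc, "ratio": rng.uniform(size=n)})
    tb = pd.DataFrame({"barcode": bc, "ratio": rng.uniform(size=n)})
    assert abs(ratio_vs_ratio_fit(ta, tb).r) < 0.05


def test_ratio_vs_ratio_needs_three_common_spots():
    import pandas as pd

    ta = pd.DataFrame({"barcode": ["a", "b"], "ratio": [0.1, 0.2]})
    with pytest.raises(InvalidInputError):
        ratio_vs_ratio_fit(ta, ta)
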