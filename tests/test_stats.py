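import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from aqpolar import synthdata
from aqpolar.errors import InvalidInputError, UndefinedStatisticError
from aqpolar.gating import gate_spots
from aqpolar.stats import anova_lsd, bh_adjust, ddct_fold_change, de_screen, pearson_fit


def test_anova_hand_computed_f():
    """Groups [1,2,3],[2,3,4],[6,7,8]: SSB=42 (df 2), SSW=6 (df 6) -> F=21."""
    res = anova_lsd({"a": [1, 2, 3], "b": [2, 3, 4], "c": [6, 7, 8]})
    assert res.F == pytest.approx(21.0)
    assert res.df_between == 2 and res.df_within == 6
    assert res.p == pytest.approx(scipy.stats.f.sf(21.0, 2, 6))


def test_anova_identical_groups_degenerate():
    res = anova_lsd({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
    assert res.F == 0.0 and res.p == 1.0
    assert all(p == 1.0 for p in res.pairwise.values())


def test_anova_undersized_group_rejected():
    with pytest.raises(InvalidInputError):
        anova_lsd({"a": [1.0], "b": [1.0, 2.0]})


def _brute_anova_lsd(groups):
    """Independent sums-of-squares oracle, with scipy cross-checks."""
    vals = [np.asarray(v, float) for v in groups.values()]
    names = list(groups)
    n = sum(len(v) for v in vals)
    k = len(vals)
    grand = np.concatenate(vals).mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in vals)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in vals)
    F = (ssb / (k - 1)) / (ssw / (n - k))
    p = scipy.stats.f.sf(F, k - 1, n - k)
    mse = ssw / (n - k)
    pw = {}
    for i in range(k):
        for j in range(i + 1, k):
            t = (vals[i].mean() - vals[j].mean()) / np.sqrt(
                mse * (1 / len(vals[i]) + 1 / len(vals[j]))
            )
            pw[(names[i], names[j])] = 2 * scipy.stats.t.sf(abs(t), n - k)
    return F, p, pw


def test_anova_lsd_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        k = rng.integers(2, 5)
        groups = {
            f"g{i}": rng.normal(rng.uniform(-2, 2), 1.0, rng.integers(2, 12))
            for i in range(k)
        }
        res = anova_lsd(groups)
        F, p, pw = _brute_anova_lsd(groups)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        # scipy's omnibus ANOVA agrees too
        sp = scipy.stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(sp.statistic, abs=1e-8)
        for pair, pval in pw.items():
            assert res.pairwise[pair] == pytest.approx(pval, abs=1e-10)


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 0.5], [1.0, 1.0]),
    ],
)
def test_bh_examples(p, expected):
    assert bh_adjust(p) == pytest.approx(expected)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 40))
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-10)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_properties(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)  # adjusted >= raw
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in rank


def test_bh_rejects_out_of_range():
    with pytest.raises(InvalidInputError):
        bh_adjust([0.5, 1.5])


def test_pearson_identity_line():
    fit = pearson_fit([0, 1, 2, 3], [0, 1, 2, 3])
    assert fit.r == pytest.approx(1.0) and fit.slope == pytest.approx(1.0)


def test_pearson_closed_form():
    """{(0,0),(1,2),(2,2)}: Sxy/sqrt(Sxx*Syy) = 2/sqrt(16/3) = sqrt(3)/2."""
    fit = pearson_fit([0, 1, 2], [0, 2, 2])
    assert fit.r == pytest.approx(np.sqrt(3) / 2)
    assert fit.slope == pytest.approx(1.0)
    # two-sided t-based p from r and n
    t = fit.r * np.sqrt(1) / np.sqrt(1 - fit.r**2)
    assert fit.p == pytest.approx(2 * scipy.stats.t.sf(t, 1))


def test_pearson_constant_input_undefined():
    with pytest.raises(UndefinedStatisticError):
        pearson_fit([1, 2, 3], [5, 5, 5])


def test_pearson_matches_scipy_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = rng.integers(3, 30)
        x, y = rng.normal(size=n), rng.normal(size=n)
        fit = pearson_fit(x, y)
        r_ref, p_ref = scipy.stats.pearsonr(x, y)
        assert fit.r == pytest.approx(r_ref, abs=1e-10)
        assert fit.p == pytest.approx(p_ref, abs=1e-10)


def test_ddct_fold_change():
    assert ddct_fold_change(0.0) == 1.0
    assert ddct_fold_change(1.0) == 0.5
    assert ddct_fold_change(-1.0) == 2.0


def test_de_screen_filter_rule_and_recovery():
    """Genes shifted 2x (up or down) on AC spots are recovered; the filter
    flag equals the |FC| > 1.5 and adjusted-p < 0.05 conjunction."""
    bg = [f"Bg{i:03d}" for i in range(80)]
    shifts = {g: {"APP/PS1": 2.0} for g in bg[:5]}
    shifts.update({g: {"APP/PS1": 0.5} for g in bg[5:10]})
    params = synthdata.SynthParams(
        lattice_rows=70, lattice_cols=64, n_background_genes=80,
        shifted_genes=shifts, aeg_genes=(), pi={"Aqp4": 0.7, "Gfap": 0.3},
        seed=9,
    )
    bundle, _ = synthdata.generate_tissue(params)
    cls = gate_spots(bundle)
    assert cls.n_ac >= 400  # ~200 usable AC spots per group
    res = de_screen(bundle, cls.mask("AC"), "APP/PS1", "WT")
    res = res.set_index("gene")
    hits = set(res.index[res.passes_filter])
    true = set(bg[:10])
    assert len(hits & true) >= 9
    assert len(hits - true) <= 2
    # flag consistency with the stated thresholds
    expected = (np.abs(res["log2_fc"]) > np.log2(1.5)) & (res["p_adj"] < 0.05)
    assert (res["passes_filter"] == expected).all()
    # adjusted p never below raw p
    assert (res["p_adj"] >= res["p"] - 1e-12).all()


def test_de_screen_needs_three_spots_per_group(small_tissue):
    _, bundle, _ = small_tissue
    mask = np.zeros(bundle.n_spots, dtype=bool)
    mask[:2] = True
    with pytest.raises(InvalidInputError):
        de_screen(bundle, mask, "APP/PS1", "WT")
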