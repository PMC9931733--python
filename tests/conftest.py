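import numpy as np
import pytest
import scipy.sparse as sp

from aqpolar import synthdata
from aqpolar.spotio import SpotBundle


def make_bundle(genes, spots, groups_map=None):
    """Hand-build a bundle from a list of spot dicts.

    Each spot dict: barcode, row, col, and optional region/sample/group
    plus a ``counts`` dict gene -> count.
    """
    n = len(spots)
    counts = np.zeros((len(genes), n), dtype=int)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for j, s in enumerate(spots):
        for g, v in s.get("counts", {}).items():
            counts[gene_idx[g], j] = v
    rows = np.array([s["row"] for s in spots])
    cols = np.array([s["col"] for s in spots])
    return SpotBundle(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(genes, dtype=object),
        barcodes=np.array([s["barcode"] for s in spots], dtype=object),
        array_row=rows,
        array_col=cols,
        pxl_row=rows * 86.60254037844386,
        pxl_col=cols * 50.0,
        in_tissue=np.ones(n, dtype=bool),
        region=np.array([s.get("region", "cortex") for s in spots], dtype=object),
        sample=np.array([s.get("sample", "s1") for s in spots], dtype=object),
        group=np.array([s.get("group", "WT") for s in spots], dtype=object),
    )


@pytest.fixture(scope="session")
def small_tissue():
    """A small three-group simulated bundle shared across read-only tests."""
    params = synthdata.SynthParams(
        lattice_rows=40, lattice_cols=40, n_background_genes=60, seed=101
    )
    bundle, truth = synthdata.generate_tissue(params)
    return params, bundle, truth
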