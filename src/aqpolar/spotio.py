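"""Readers and writers for the standard on-disk formats.

A tissue bundle on disk follows the 10x convention: ``matrix.mtx``
(MatrixMarket, genes x spots, 1-based indices), ``features.tsv``,
``barcodes.tsv``, and ``tissue_positions.csv`` with columns
``barcode,in_tissue,array_row,array_col,pxl_row,pxl_col``.  Two sidecar
tables carry annotation: ``regions.tsv`` (barcode -> region label) and
``groups.tsv`` (sample -> experimental group).  Barcodes are prefixed
``<sample>:`` so spots from different sections never collide.

Internal indices are 0-based everywhere; files keep their native
conventions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

__all__ = ["SpotBundle", "GeneSet", "load_bundle", "save_bundle", "read_gmt", "save_results"]


@dataclass
class SpotBundle:
    """A genes-by-spots count matrix plus per-spot lattice annotation."""

    counts: sp.csr_matrix  # genes x spots, non-negative integers
    gene_ids: np.ndarray
    barcodes: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    pxl_row: np.ndarray
    pxl_col: np.ndarray
    in_tissue: np.ndarray
    region: np.ndarray | None = None
    sample: np.ndarray | None = None
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.validate()
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError("gene id list does not match matrix rows")
        if len(self.barcodes) != n_spots:
            raise FormatError("barcode list does not match matrix columns")
        if len(set(self.barcodes)) != n_spots:
            raise FormatError("barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("count matrix has negative entries")
        for name in ("array_row", "array_col", "pxl_row", "pxl_col", "in_tissue"):
            if len(getattr(self, name)) != n_spots:
                raise FormatError(f"{name} does not match number of spots")
        for name in ("region", "sample", "group"):
            val = getattr(self, name)
            if val is not None and len(val) != n_spots:
                raise FormatError(f"{name} does not match number of spots")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in panel") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense count vector of one gene across all spots."""
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()

    def spots_meta(self) -> pd.DataFrame:
        """Per-spot annotation as a DataFrame indexed by barcode."""
        meta = pd.DataFrame(
            {
                "array_row": self.array_row,
                "array_col": self.array_col,
                "pxl_row": self.pxl_row,
                "pxl_col": self.pxl_col,
                "in_tissue": self.in_tissue,
            },
            index=pd.Index(self.barcodes, name="barcode"),
        )
        for name in ("region", "sample", "group"):
            val = getattr(self, name)
            if val is not None:
                meta[name] = val
        return meta

    def subset_spots(self, mask: np.ndarray) -> "SpotBundle":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        kw = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if f.name == "counts":
                kw[f.name] = val[:, idx]
            elif f.name == "gene_ids" or val is None:
                kw[f.name] = val
            else:
                kw[f.name] = np.asarray(val)[idx]
        return SpotBundle(**kw)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set, e.g. one GO term's member genes."""

    name: str
    source: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.name!r} has duplicate ids")


def save_bundle(bundle: SpotBundle, out_dir: str | Path) -> Path:
    """Write a bundle to ``out_dir`` in the 10x-style layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(bundle.counts))
    feat = pd.DataFrame(
        {"gene_id": bundle.gene_ids, "gene_name": bundle.gene_ids, "type": "Gene Expression"}
    )
    feat.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(bundle.barcodes).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    pos = pd.DataFrame(
        {
            "barcode": bundle.barcodes,
            "in_tissue": np.asarray(bundle.in_tissue, dtype=int),
            "array_row": bundle.array_row,
            "array_col": bundle.array_col,
            "pxl_row": bundle.pxl_row,
            "pxl_col": bundle.pxl_col,
        }
    )
    pos.to_csv(out / "tissue_positions.csv", index=False)
    if bundle.region is not None:
        pd.DataFrame({"barcode": bundle.barcodes, "region": bundle.region}).to_csv(
            out / "regions.tsv", sep="\t", index=False
        )
    if bundle.sample is not None and bundle.group is not None:
        pairs = pd.DataFrame({"sample": bundle.sample, "group": bundle.group}).drop_duplicates()
        pairs.to_csv(out / "groups.tsv", sep="\t", index=False)
    return out


def load_bundle(bundle_dir: str | Path) -> SpotBundle:
    """Load a bundle written by :func:`save_bundle` (or any 10x-style dir).

    MatrixMarket 1-based indices are converted to 0-based internal ones.
    Violated invariants raise :class:`FormatError` naming the offending
    file rather than being repaired silently.
    """
    d = Path(bundle_dir)
    mtx_path = d / "matrix.mtx"
    for required in ("matrix.mtx", "features.tsv", "barcodes.tsv", "tissue_positions.csv"):
        if not (d / required).exists():
            raise FormatError(f"missing required file: {d / required}")
    try:
        counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    except Exception as exc:  # noqa: BLE001 - rewrap with filename
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    if counts.nnz and counts.data.min() < 0:
        raise FormatError(f"negative entries in {mtx_path}")

    features = pd.read_csv(d / "features.tsv", sep="\t", header=None)
    gene_ids = features[0].to_numpy(dtype=object)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    if counts.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix {counts.shape} does not match features/barcodes "
            f"({len(gene_ids)} x {len(barcodes)}) in {d}"
        )

    pos = pd.read_csv(d / "tissue_positions.csv")
    missing = set(pos["barcode"]) - set(barcodes)
    if missing:
        raise FormatError(
            f"{d / 'tissue_positions.csv'} lists barcodes absent from the matrix: "
            f"{sorted(missing)[:5]}"
        )
    pos = pos.set_index("barcode").reindex(barcodes)
    if pos["in_tissue"].isna().any():
        raise FormatError(f"{d / 'tissue_positions.csv'} does not cover every barcode")

    region = None
    reg_path = d / "regions.tsv"
    if reg_path.exists():
        reg = pd.read_csv(reg_path, sep="\t").set_index("barcode")["region"].reindex(barcodes)
        if reg.isna().any():
            raise FormatError(f"{reg_path} does not cover every barcode")
        region = reg.to_numpy(dtype=object)

    sample = np.array([b.split(":", 1)[0] if ":" in b else "sample" for b in barcodes], dtype=object)
    group = None
    grp_path = d / "groups.tsv"
    if grp_path.exists():
        g = pd.read_csv(grp_path, sep="\t").set_index("sample")["group"]
        try:
            group = g.loc[sample].to_numpy(dtype=object)
        except KeyError as exc:
            raise FormatError(f"{grp_path} missing sample listed in barcodes: {exc}") from exc

    return SpotBundle(
        counts=counts,
        gene_ids=gene_ids,
        barcodes=barcodes,
        array_row=pos["array_row"].to_numpy(int),
        array_col=pos["array_col"].to_numpy(int),
        pxl_row=pos["pxl_row"].to_numpy(float),
        pxl_col=pos["pxl_col"].to_numpy(float),
        in_tissue=pos["in_tissue"].to_numpy(int).astype(bool),
        region=region,
        sample=sample,
        group=group,
    )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated ``name, description, genes...`` per line."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    seen.setdefault(g)
            sets.append(GeneSet(name=name, source=desc, genes=tuple(seen)))
    return sets


def save_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write result tables as TSV plus a JSON run-manifest.

    The manifest records the exact configuration, seed, package version and
    per-table row counts so a run can be audited and reproduced.
    """
    if not tables:
        raise ValueError("no tables to save")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "aqpolar",
        "version": _version(),
        "seed": seed,
        "config": config or {},
        "tables": {},
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        manifest["tables"][name] = {"rows": int(len(df)), "columns": list(map(str, df.columns))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("aqpolar")
    except PackageNotFoundError:
        return "unknown"
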