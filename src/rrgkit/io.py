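"""Plain-text I/O: 10x-convention Matrix Market triplets, gene sets, tables.

Count matrices are exchanged as the classic 10x triplet -- ``matrix.mtx``
(genes as rows, cells as columns), ``features.tsv`` (id, symbol, feature
type) and ``barcodes.tsv`` -- optionally accompanied by ``cell_metadata.csv``
holding the per-cell annotations (condition, timepoint, population, ...).
In memory the matrix is an :class:`anndata.AnnData` in the cells-by-genes
orientation, with integer UMI counts in ``X``.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "read_gene_set",
    "read_gmt",
    "write_gene_set",
]


def _find(path: Path, stem: str) -> Path:
    """Locate ``stem`` or ``stem.gz`` under ``path``."""
    for cand in (path / stem, path / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"{stem}[.gz] not found in {path}")


def read_10x_mtx(path: str | os.PathLike) -> ad.AnnData:
    """Read a 10x-style MTX triplet directory into an AnnData (cells x genes).

    ``features.tsv`` may have 1-3 columns (id [, symbol [, type]]); a boolean
    ``mito`` column is derived from the mouse ``mt-`` symbol prefix.  If a
    ``cell_metadata.csv`` sits next to the triplet it is joined onto ``obs``.
    """
    path = Path(path)
    mtx = scipy.io.mmread(_find(path, "matrix.mtx"))
    feat_file = _find(path, "features.tsv")
    opener = gzip.open if feat_file.suffix == ".gz" else open
    with opener(feat_file, "rt") as fh:
        features = pd.read_csv(fh, sep="\t", header=None)
    with (gzip.open if (bf := _find(path, "barcodes.tsv")).suffix == ".gz" else open)(bf, "rt") as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None)[0].astype(str)

    X = sp.csr_matrix(mtx.T)  # file is genes x cells
    var = pd.DataFrame(index=pd.Index(features.iloc[:, min(1, features.shape[1] - 1)].astype(str), name="symbol"))
    var["gene_ids"] = features.iloc[:, 0].astype(str).values
    var["mito"] = var.index.str.lower().str.startswith("mt-")
    adata = ad.AnnData(X=X, var=var, obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")))

    meta = path / "cell_metadata.csv"
    if meta.exists():
        md = pd.read_csv(meta, index_col=0)
        md.index = md.index.astype(str)
        adata.obs = adata.obs.join(md, how="left")
    return adata


def write_10x_mtx(adata: ad.AnnData, path: str | os.PathLike, *, write_metadata: bool = True) -> None:
    """Write an AnnData as a 10x MTX triplet (genes x cells on disk)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    if not np.issubdtype(X.dtype, np.integer):
        X = X.astype(np.int64)
    scipy.io.mmwrite(str(path / "matrix.mtx"), X, field="integer")
    gene_ids = adata.var["gene_ids"] if "gene_ids" in adata.var else adata.var_names
    feats = pd.DataFrame(
        {0: gene_ids, 1: adata.var_names, 2: "Gene Expression"}
    )
    feats.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    if write_metadata and adata.obs.shape[1]:
        adata.obs.to_csv(path / "cell_metadata.csv")


def read_gene_set(path: str | os.PathLike) -> list[str]:
    """Read a one-symbol-per-line gene list (blank lines and '#' comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gene_set(genes: list[str], path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + ("\n" if genes else ""))
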