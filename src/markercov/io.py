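"""Reading and writing UMI count matrices.

Two on-disk layouts are supported:

* the 10x triplet layout — a directory with ``matrix.mtx`` (Matrix Market
  coordinate, genes × cells), ``features.tsv`` and ``barcodes.tsv``;
* a dense TSV with genes as rows, cells as columns, gene ids in the first
  column and barcodes in the header.

In memory the package uses :class:`anndata.AnnData` in the cells × genes
orientation, with boolean ``var`` columns ``is_mito`` / ``is_hemoglobin``
derived from the "MT-"/"HB" identifier prefixes.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import check_nonnegative_integers, gene_flags_from_names

__all__ = ["FormatError", "read_counts", "write_counts", "make_anndata"]


class FormatError(ValueError):
    """Malformed or internally inconsistent count-matrix files."""


def make_anndata(counts, gene_ids, cell_barcodes) -> ad.AnnData:
    """Assemble an AnnData (cells × genes) from a genes × cells count matrix."""
    gene_ids = [str(g) for g in gene_ids]
    cell_barcodes = [str(b) for b in cell_barcodes]
    X = sp.csr_matrix(counts).T.tocsr()
    if X.shape != (len(cell_barcodes), len(gene_ids)):
        raise FormatError(
            f"matrix shape {counts.shape} (genes × cells) inconsistent with "
            f"{len(gene_ids)} gene ids and {len(cell_barcodes)} barcodes"
        )
    if not check_nonnegative_integers(X):
        raise FormatError("counts must be non-negative integers")
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError("gene ids are not unique")
    if len(set(cell_barcodes)) != len(cell_barcodes):
        raise FormatError("cell barcodes are not unique")
    is_mito, is_hb = gene_flags_from_names(gene_ids)
    var = pd.DataFrame(
        {"is_mito": is_mito, "is_hemoglobin": is_hb},
        index=pd.Index(gene_ids, name="gene"),
    )
    obs = pd.DataFrame(index=pd.Index(cell_barcodes, name="barcode"))
    return ad.AnnData(X=X.astype(np.int64), obs=obs, var=var)


def _infer_format(path) -> str:
    p = Path(path)
    if p.is_dir():
        return "mtx_triplet"
    return "dense_tsv"


def read_counts(path, format: str | None = None) -> ad.AnnData:
    """Read a count matrix from the 10x triplet layout or a dense TSV.

    Raises :class:`FormatError` when the Matrix Market header disagrees with
    the features/barcodes files or when entries are not non-negative
    integers.
    """
    fmt = format or _infer_format(path)
    if fmt == "mtx_triplet":
        d = Path(path)
        mtx = d / "matrix.mtx"
        feats = d / "features.tsv"
        bcs = d / "barcodes.tsv"
        for f in (mtx, feats, bcs):
            if not f.exists():
                raise FileNotFoundError(f)
        M = scipy.io.mmread(mtx)
        genes = pd.read_csv(feats, sep="\t", header=None)[0].astype(str).tolist()
        barcodes = pd.read_csv(bcs, sep="\t", header=None)[0].astype(str).tolist()
        if M.shape[0] != len(genes):
            raise FormatError(
                f"matrix.mtx declares {M.shape[0]} genes but features.tsv has {len(genes)} lines"
            )
        if M.shape[1] != len(barcodes):
            raise FormatError(
                f"matrix.mtx declares {M.shape[1]} cells but barcodes.tsv has {len(barcodes)} lines"
            )
        return make_anndata(sp.coo_matrix(M), genes, barcodes)
    if fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        return make_anndata(vals, df.index.tolist(), [str(c) for c in df.columns])
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(adata: ad.AnnData, path, format: str = "mtx_triplet") -> None:
    """Write a count matrix; round-trips exactly through :func:`read_counts`."""
    X_gc = sp.csr_matrix(adata.X).T.tocoo()  # genes × cells on disk
    if format == "mtx_triplet":
        d = Path(path)
        os.makedirs(d, exist_ok=True)
        scipy.io.mmwrite(d / "matrix.mtx", X_gc, field="integer")
        with open(d / "features.tsv", "w") as fh:
            for g in adata.var_names:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(d / "barcodes.tsv", "w") as fh:
            for b in adata.obs_names:
                fh.write(f"{b}\n")
    elif format == "dense_tsv":
        df = pd.DataFrame(
            np.asarray(sp.csr_matrix(adata.X).T.todense(), dtype=np.int64),
            index=pd.Index(adata.var_names, name="gene"),
            columns=adata.obs_names,
        )
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
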