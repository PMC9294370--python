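"""Packaged reference tables.

Two small published tables from a cavernous-hemangioma scRNA-seq study ship
with the package as worked-example inputs:

* a 16 cell-type composition table (cell counts, five-gene marker combination
  and UICC per type, 10,784 cells total), and
* the mesenchymal-stem-cell (MSC) expression signature — 64 genes with
  Avg_in, LFCio, PCTin, PCTout and the PCTin/PCTout ratio.

They let the selection rules and composition arithmetic be exercised on real
printed statistics without access to the underlying count matrix.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_celltype_table", "load_msc_signature", "IMMUNE_CELL_TYPES"]

#: the study's immune compartment (10 of the 16 cell types)
IMMUNE_CELL_TYPES = (
    "CD4+TC", "CD8+TC", "NKC", "BC", "Mast",
    "mDC", "pDC", "CLEC9A+DC", "m1Maph", "m2Maph",
)


def _read(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("markercov") / "data" / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_celltype_table() -> pd.DataFrame:
    """Cell-type composition: cell_type, n_cells, marker_genes, uicc."""
    df = _read("hemangioma_celltypes.tsv")
    df["marker_genes"] = df["marker_genes"].str.split(",")
    return df


def load_msc_signature() -> pd.DataFrame:
    """The 64-gene MSC signature with printed per-gene statistics.

    Columns: gene, avg_in, lfcio, pct_in, pct_out, ratio. Percentages are on
    the 0-100 scale; ratio is the printed PCTin/PCTout at 2 dp.
    """
    return _read("msc_signature.tsv")
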