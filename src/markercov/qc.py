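"""Quality-control filtering of UMI count matrices.

The filter applies four rules in a fixed single pass (no iteration to a
fixed point):

1. drop genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells;
2. drop cells with fewer than ``min_genes_per_cell`` detected genes, counted
   on the gene-filtered matrix;
3. drop cells whose mitochondrial UMI fraction exceeds ``max_mito_fraction``
   or whose hemoglobin fraction exceeds ``max_hemoglobin_fraction`` — both
   fractions computed on the original, pre-filter matrix over all genes;
4. drop cells named by an optional doublet hook (e.g. an external
   DoubletFinder run); the default hook removes nothing.

Boundary semantics are strict: "< 3 cells", "< 200 genes", "> 30%", "> 5%".
Each removed cell is tallied under the first rule it fails, in the order
above. Note that removing cells can newly strand genes below the gene rule;
the pass is deliberately not iterated.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable

import anndata as ad
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from ._utils import as_csr

__all__ = ["QCReport", "QCFilter", "qc_filter", "split_nuclear_mito", "EmptyResultError"]


class EmptyResultError(ValueError):
    """Raised when QC removes every cell instead of returning an empty matrix."""


@dataclasses.dataclass
class QCReport:
    n_genes_removed: int
    n_cells_removed_per_rule: dict[str, int]
    median_genes_per_cell: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def split_nuclear_mito(adata: ad.AnnData) -> tuple[ad.AnnData, ad.AnnData]:
    """Partition genes into nuclear and mitochondrial sub-matrices.

    The partition is exact (disjoint, union = input) and preserves cell
    order in both outputs.
    """
    if "is_mito" not in adata.var:
        raise ValueError("gene flag 'is_mito' missing from adata.var")
    mask = adata.var["is_mito"].to_numpy(dtype=bool)
    return adata[:, ~mask].copy(), adata[:, mask].copy()


class QCFilter(BaseEstimator):
    """Scikit-learn-style QC filter over an AnnData of raw counts.

    ``fit`` computes boolean gene/cell masks and a :class:`QCReport`;
    ``transform`` applies them. Unlike a classical sklearn transformer this
    reduces both axes, which is inherent to the operation.

    Parameters
    ----------
    min_cells_per_gene : genes detected in fewer cells are dropped (default 3).
    min_genes_per_cell : cells with fewer detected genes are dropped (default 200).
    max_mito_fraction : cells above this mitochondrial UMI fraction are dropped
        (default 0.30).
    max_hemoglobin_fraction : cells above this hemoglobin UMI fraction are
        dropped (default 0.05).
    doublet_hook : optional callable ``adata -> iterable of barcodes`` (or a
        plain iterable of barcodes) naming cells to exclude after the count
        rules.
    """

    def __init__(
        self,
        min_cells_per_gene: int = 3,
        min_genes_per_cell: int = 200,
        max_mito_fraction: float = 0.30,
        max_hemoglobin_fraction: float = 0.05,
        doublet_hook: Callable | Iterable[str] | None = None,
    ):
        self.min_cells_per_gene = min_cells_per_gene
        self.min_genes_per_cell = min_genes_per_cell
        self.max_mito_fraction = max_mito_fraction
        self.max_hemoglobin_fraction = max_hemoglobin_fraction
        self.doublet_hook = doublet_hook

    def _validate(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("count thresholds must be >= 0")
        for name in ("max_mito_fraction", "max_hemoglobin_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def fit(self, adata: ad.AnnData, y=None):
        self._validate()
        X = as_csr(adata.X)
        n_cells, n_genes = X.shape
        detected = X > 0

        cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
        gene_keep = cells_per_gene >= self.min_cells_per_gene

        # fractions on the full pre-filter matrix
        totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        mito = adata.var.get("is_mito")
        hb = adata.var.get("is_hemoglobin")
        mito_frac = (
            np.asarray(X[:, mito.to_numpy(dtype=bool)].sum(axis=1)).ravel() / safe
            if mito is not None else np.zeros(n_cells)
        )
        hb_frac = (
            np.asarray(X[:, hb.to_numpy(dtype=bool)].sum(axis=1)).ravel() / safe
            if hb is not None else np.zeros(n_cells)
        )

        genes_per_cell = np.asarray(detected[:, gene_keep].sum(axis=1)).ravel()
        fail_min_genes = genes_per_cell < self.min_genes_per_cell
        fail_mito = mito_frac > self.max_mito_fraction
        fail_hb = hb_frac > self.max_hemoglobin_fraction

        cell_keep = ~(fail_min_genes | fail_mito | fail_hb)

        hook = self.doublet_hook
        if hook is None:
            excluded: set[str] = set()
        elif callable(hook):
            excluded = set(map(str, hook(adata)))
        else:
            excluded = set(map(str, hook))
        is_doublet = np.array([b in excluded for b in adata.obs_names])

        # sequential attribution for the report
        n_min_genes = int(fail_min_genes.sum())
        n_mito = int((fail_mito & ~fail_min_genes).sum())
        n_hb = int((fail_hb & ~fail_min_genes & ~fail_mito).sum())
        n_doublet = int((is_doublet & cell_keep).sum())
        cell_keep &= ~is_doublet

        if not cell_keep.any():
            raise EmptyResultError(
                "QC removed all cells; relax thresholds or inspect the input"
            )

        self.gene_mask_ = gene_keep
        self.cell_mask_ = cell_keep
        out_detected = detected[cell_keep][:, gene_keep]
        self.report_ = QCReport(
            n_genes_removed=int((~gene_keep).sum()),
            n_cells_removed_per_rule={
                "min_genes_per_cell": n_min_genes,
                "mito_fraction": n_mito,
                "hemoglobin_fraction": n_hb,
                "doublet": n_doublet,
            },
            median_genes_per_cell=float(
                np.median(np.asarray(out_detected.sum(axis=1)).ravel())
            ),
        )
        return self

    def transform(self, adata: ad.AnnData) -> ad.AnnData:
        if not hasattr(self, "cell_mask_"):
            raise RuntimeError("QCFilter is not fitted")
        return adata[self.cell_mask_][:, self.gene_mask_].copy()

    def fit_transform(self, adata: ad.AnnData, y=None) -> ad.AnnData:
        return self.fit(adata).transform(adata)


def qc_filter(
    adata: ad.AnnData,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
    max_mito_fraction: float = 0.30,
    max_hemoglobin_fraction: float = 0.05,
    doublet_hook=None,
) -> tuple[ad.AnnData, QCReport]:
    """Functional wrapper over :class:`QCFilter`; returns (filtered, report)."""
    f = QCFilter(
        min_cells_per_gene=min_cells_per_gene,
        min_genes_per_cell=min_genes_per_cell,
        max_mito_fraction=max_mito_fraction,
        max_hemoglobin_fraction=max_hemoglobin_fraction,
        doublet_hook=doublet_hook,
    )
    out = f.fit_transform(adata)
    return out, f.report_
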