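"""Marker-combination selection and UCC/ICC/UICC coverage metrics.

A cluster's marker combination is chosen from its expression signature by
two rules: the gene must be expressed in more than 60% of in-cluster cells
(PCTin > 60), and among those candidates the five with the largest
PCTin/PCTout ratio are taken.

Because a single gene's fold change or ratio cannot describe how well a
*panel* covers a cluster, the panel is scored with coverage metrics over
the in-cluster cells (a cell "expresses" a gene when its raw count is > 0):

* UCC — fraction of cells expressing at least one panel gene (union),
* ICC — fraction expressing every panel gene (intersection),
* UICC = UCC × ICC, balancing breadth against co-expression.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from ._utils import as_csr
from .stats import ClusterSignature, _in_mask

__all__ = [
    "MarkerCombo",
    "select_marker_combo",
    "coverage_metrics",
    "rough_identify",
    "load_marker_reference",
    "MarkerSelector",
]


@dataclasses.dataclass
class MarkerCombo:
    cluster: str
    genes: list[str]
    ucc: float
    icc: float
    uicc: float


def select_marker_combo(
    stats: pd.DataFrame, pct_in_min: float = 60.0, k: int = 5
) -> list[str]:
    """Pick up to ``k`` marker genes from one cluster's signature statistics.

    Candidates are rows with ``pct_in > pct_in_min`` (strict); they are
    ranked by ``ratio`` descending (ties: higher ``lfcio``, then gene id).
    +∞ ratios (PCTout = 0) rank first. Fewer than ``k`` candidates returns
    them all with a warning.
    """
    cand = stats[stats["pct_in"] > pct_in_min]
    cand = cand.sort_values(
        ["ratio", "lfcio", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    genes = cand["gene"].tolist()[:k]
    if len(genes) < k:
        warnings.warn(
            f"only {len(genes)} candidate genes with pct_in > {pct_in_min}; "
            f"returning all of them"
        )
    return genes


def coverage_metrics(
    adata: ad.AnnData, labels, cluster: str, genes: Iterable[str]
) -> tuple[float, float, float]:
    """UCC, ICC and UICC of a gene panel over one cluster's cells."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    mask = _in_mask(adata, labels, cluster)
    X = as_csr(adata.X)
    cols = [adata.var_names.get_loc(g) for g in genes]
    expressed = np.asarray((X[mask][:, cols] > 0).todense())
    ucc = float(expressed.any(axis=1).mean())
    icc = float(expressed.all(axis=1).mean())
    return ucc, icc, ucc * icc


def load_marker_reference(path) -> dict[str, set[str]]:
    """Read a two-column TSV (cell_type, gene) into a type → gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "gene"], dtype=str)
    ref = {t: set(g["gene"]) for t, g in df.groupby("cell_type")}
    if any(len(s) == 0 for s in ref.values()):
        raise ValueError("reference contains an empty gene set")
    return ref


def rough_identify(
    signature_genes: Iterable[str],
    reference: Mapping[str, Iterable[str]],
    universe: int | Iterable[str],
) -> pd.DataFrame:
    """Rank reference cell types by hypergeometric enrichment of the signature.

    For each type, the upper-tail probability P(X ≥ overlap) of the overlap
    between the signature genes and the reference set, drawn from a universe
    of ``universe`` genes. ``universe`` may be a size or the gene list
    itself; with a list, reference genes outside it are dropped (warning).
    Sorted by p ascending, ties broken by larger overlap.
    """
    sig = set(signature_genes)
    if not sig or not reference:
        raise ValueError("signature and reference must be non-empty")
    if isinstance(universe, int):
        M, universe_set = universe, None
    else:
        universe_set = set(universe)
        M = len(universe_set)
    rows = []
    for cell_type, genes in reference.items():
        gs = set(genes)
        if universe_set is not None:
            dropped = gs - universe_set
            if dropped:
                warnings.warn(
                    f"{len(dropped)} reference genes for {cell_type!r} absent "
                    f"from universe; dropped"
                )
            gs &= universe_set
        overlap = len(sig & gs)
        # P(X >= overlap); overlap 0 gives p = 1 by convention
        p = float(scipy.stats.hypergeom.sf(overlap - 1, M, len(gs), len(sig)))
        rows.append({"cell_type": cell_type, "overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    df["_neg"] = -df["overlap"]
    df = df.sort_values(["p", "_neg", "cell_type"], kind="mergesort").drop(columns="_neg")
    return df.reset_index(drop=True)


class MarkerSelector(BaseEstimator):
    """End-to-end marker selection per cluster, sklearn-style.

    ``fit(adata, labels)`` builds (or reuses) per-cluster signatures and
    selects each cluster's marker combination with its coverage metrics.
    Fitted attribute ``combos_`` maps cluster → :class:`MarkerCombo`.
    """

    def __init__(self, pct_in_min: float = 60.0, k: int = 5,
                 padj_max: float = 0.01, lfc_min: float = 2.0,
                 prefilter_pct: float = 10.0, test=None,
                 clusters: list[str] | None = None):
        self.pct_in_min = pct_in_min
        self.k = k
        self.padj_max = padj_max
        self.lfc_min = lfc_min
        self.prefilter_pct = prefilter_pct
        self.test = test
        self.clusters = clusters

    def fit(self, adata: ad.AnnData, labels, signatures: Mapping[str, pd.DataFrame] | None = None):
        if signatures is None:
            cs = ClusterSignature(
                padj_max=self.padj_max, lfc_min=self.lfc_min,
                prefilter_pct=self.prefilter_pct, test=self.test,
                clusters=self.clusters,
            ).fit(adata, labels)
            signatures = cs.signatures_
            self.signature_model_ = cs
        self.combos_: dict[str, MarkerCombo] = {}
        for cl, sig in signatures.items():
            genes = select_marker_combo(sig, pct_in_min=self.pct_in_min, k=self.k)
            if genes:
                ucc, icc, uicc = coverage_metrics(adata, labels, cl, genes)
            else:
                ucc = icc = uicc = 0.0
            self.combos_[cl] = MarkerCombo(cluster=cl, genes=genes, ucc=ucc,
                                           icc=icc, uicc=uicc)
        return self
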