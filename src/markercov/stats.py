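"""Per-cluster inside/outside gene statistics and expression signatures.

For one cluster versus all other cells, each gene gets:

* ``avg_in`` / ``avg_out`` — arithmetic means of depth-normalized expression
  (counts per 10,000, *not* log-transformed) inside/outside the cluster;
* ``lfcio`` — log2((avg_in + ε) / (avg_out + ε)), ε = 1e-9, capped at ±25;
* ``pct_in`` / ``pct_out`` — percentage of cells with a nonzero raw count
  inside/outside, on the 0–100 scale;
* ``ratio`` — pct_in / pct_out (+∞ when pct_out = 0 and pct_in > 0);
* ``p`` / ``padj`` — two-group test p-value and its Benjamini–Hochberg
  adjustment over all tested genes.

Genes expressed in fewer than 10% of cells in *both* groups are excluded
before testing. A cluster's expression signature is the set of genes with
padj ≤ 0.01 and LFCio ≥ 2, sorted by ratio descending.

The two-group test is pluggable. The default is a two-sided Wilcoxon
rank-sum on normalized values; the study from which the thresholds are
drawn used a negative-binomial likelihood-ratio test (DESeq2 with scran sum
factors) instead, so p-values here are not expected to reproduce published
ones — the deterministic columns (means, percentages, ratios) are.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._utils import as_csr

__all__ = [
    "cluster_gene_stats",
    "de_test",
    "rank_sum_test",
    "prefilter_genes",
    "build_signature",
    "BandScheme",
    "band_expression",
    "compute_band_scheme",
    "gene_ratio",
    "ClusterSignature",
]

EPS = 1e-9
LFC_CAP = 25.0
STAT_COLUMNS = ["gene", "avg_in", "avg_out", "lfcio", "pct_in", "pct_out", "ratio"]


def _labels_array(adata: ad.AnnData, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        aligned = labels.reindex(adata.obs_names)
        if aligned.isna().any():
            missing = list(adata.obs_names[aligned.isna()][:5])
            raise ValueError(f"labels missing for barcodes: {missing}")
        return aligned.to_numpy(dtype=object)
    arr = np.asarray(labels, dtype=object)
    if arr.shape[0] != adata.n_obs:
        raise ValueError("labels length does not match number of cells")
    return arr


def _in_mask(adata: ad.AnnData, labels, cluster: str) -> np.ndarray:
    arr = _labels_array(adata, labels)
    mask = arr == cluster
    if not mask.any():
        raise ValueError(f"cluster {cluster!r} has no cells")
    if mask.all():
        raise ValueError(f"cluster {cluster!r} contains all cells; no outside group")
    return mask


def _norm10k(X: sp.csr_matrix, scale: float = 1e4) -> sp.csr_matrix:
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = 1.0  # zero-total cells contribute zeros
    return sp.diags(scale / totals) @ X


def cluster_gene_stats(adata: ad.AnnData, labels, cluster: str) -> pd.DataFrame:
    """Inside/outside statistics for every gene of one cluster (no p-values)."""
    mask = _in_mask(adata, labels, cluster)
    X = as_csr(adata.X)
    N = _norm10k(X.astype(float))
    detected = X > 0

    avg_in = np.asarray(N[mask].mean(axis=0)).ravel()
    avg_out = np.asarray(N[~mask].mean(axis=0)).ravel()
    # integer detection counts divided last, so percentages are exact k/n
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    pct_in = 100.0 * (np.asarray(detected[mask].sum(axis=0)).ravel() / n_in)
    pct_out = 100.0 * (np.asarray(detected[~mask].sum(axis=0)).ravel() / n_out)

    lfcio = np.clip(np.log2((avg_in + EPS) / (avg_out + EPS)), -LFC_CAP, LFC_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            pct_out > 0, pct_in / np.where(pct_out > 0, pct_out, 1.0),
            np.where(pct_in > 0, np.inf, 0.0),
        )
    return pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "avg_in": avg_in,
            "avg_out": avg_out,
            "lfcio": lfcio,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "ratio": ratio,
        }
    )


def prefilter_genes(stats: pd.DataFrame, min_pct: float = 10.0) -> pd.Series:
    """Boolean keep-mask: a gene survives iff expressed in ≥ ``min_pct`` % of
    cells in at least one of the two groups ("below 10% in both" is dropped)."""
    return (stats["pct_in"] >= min_pct) | (stats["pct_out"] >= min_pct)


def rank_sum_test(X_in: np.ndarray, X_out: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum per gene (columns); constant genes get p = 1."""
    p = np.ones(X_in.shape[1])
    varying = ~(
        (np.ptp(X_in, axis=0) == 0)
        & (np.ptp(X_out, axis=0) == 0)
        & (X_in[0] == X_out[0])
    )
    if varying.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = scipy.stats.mannwhitneyu(
                X_in[:, varying], X_out[:, varying], axis=0, alternative="two-sided"
            )
        p[varying] = np.nan_to_num(res.pvalue, nan=1.0)
    return p


def de_test(
    adata: ad.AnnData,
    labels,
    cluster: str,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    prefilter_pct: float = 10.0,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-group test per gene with BH adjustment over tested genes.

    Genes failing the expression prefilter are never tested and carry NaN in
    both columns. Returns a frame indexed like ``stats`` with columns
    ``gene``, ``p``, ``padj``.
    """
    mask = _in_mask(adata, labels, cluster)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both groups need at least 2 cells for testing")
    if stats is None:
        stats = cluster_gene_stats(adata, labels, cluster)
    keep = prefilter_genes(stats, min_pct=prefilter_pct).to_numpy()

    X = as_csr(adata.X)
    N = _norm10k(X.astype(float))
    test = test or rank_sum_test
    p = np.full(adata.n_vars, np.nan)
    padj = np.full(adata.n_vars, np.nan)
    if keep.any():
        dense_in = np.asarray(N[mask][:, keep].todense())
        dense_out = np.asarray(N[~mask][:, keep].todense())
        p_kept = np.clip(np.asarray(test(dense_in, dense_out), dtype=float), 0.0, 1.0)
        p[keep] = p_kept
        padj[keep] = multipletests(p_kept, method="fdr_bh")[1]
    return pd.DataFrame({"gene": list(adata.var_names), "p": p, "padj": padj})


def build_signature(
    stats: pd.DataFrame,
    cluster: str | None = None,
    padj_max: float = 0.01,
    lfc_min: float = 2.0,
) -> pd.DataFrame:
    """Filter to the cluster's expression signature and sort it.

    Keeps rows with ``padj <= padj_max`` and ``lfcio >= lfc_min`` (a missing
    padj column is treated as all-passing, for pre-tested inputs), sorted by
    ratio descending with ties broken by higher lfcio then gene id. An empty
    signature is a valid result.
    """
    df = stats.copy()
    if "padj" in df.columns:
        df = df[df["padj"].notna() & (df["padj"] <= padj_max)]
    df = df[df["lfcio"] >= lfc_min]
    df = df.sort_values(
        ["ratio", "lfcio", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    if cluster is not None:
        df.insert(0, "cluster", cluster)
    return df


@dataclasses.dataclass
class BandScheme:
    """Relative-expression banding anchored at the LFCio distribution.

    ``mu``/``sigma`` are the mean and standard deviation of LFCio over the
    evaluated genes of one cluster comparison. ``sigma`` must exceed 0.5 or
    the similar/low bands would overlap.
    """

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0.5:
            raise ValueError(
                f"sigma={self.sigma} must be > 0.5: with a smaller spread the "
                "'similar' band (|LFCio-mu|<=0.5) overlaps the mu±sigma bands"
            )


def compute_band_scheme(lfcio_values) -> BandScheme:
    """Band scheme from the LFCio values of one comparison (sample sd)."""
    v = np.asarray(lfcio_values, dtype=float)
    return BandScheme(mu=float(v.mean()), sigma=float(v.std(ddof=1)))


def band_expression(lfcio: float, scheme: BandScheme, avg_in: float) -> str:
    """Classify a gene's relative expression into a named band.

    Checked in order: ``barely_detected`` (avg_in ≤ 0.05, before everything),
    then ``very_low`` (LFCio ≤ μ−σ, clamping anything below μ−2σ),
    ``low`` (μ−σ < LFCio ≤ −0.5), ``similar`` (|LFCio−μ| ≤ 0.5),
    ``high`` (0.5 < LFCio ≤ μ+σ) and ``very_high`` (LFCio > μ+σ). For μ far
    from 0 the literal rules can leave uncovered points; those fall back to
    ``low`` below μ and ``high`` above, keeping the scheme a total partition
    for any σ > 0.5.
    """
    mu, sigma = scheme.mu, scheme.sigma
    if avg_in <= 0.05:
        return "barely_detected"
    if lfcio <= mu - sigma:
        return "very_low"
    if lfcio <= -0.5:
        return "low"
    if abs(lfcio - mu) <= 0.5:
        return "similar"
    if 0.5 < lfcio <= mu + sigma:
        return "high"
    if lfcio > mu + sigma:
        return "very_high"
    return "low" if lfcio < mu else "high"


def gene_ratio(adata: ad.AnnData, labels, cluster: str, gene_a: str, gene_b: str,
               eps: float = EPS) -> float:
    """Ratio of two genes' mean in-cluster expression, avg_in(a)/(avg_in(b)+ε).

    Used for comparisons such as the pro-/anti-apoptotic BAX/BCL2 balance of
    a cluster. Warns when the denominator is effectively zero.
    """
    for g in (gene_a, gene_b):
        if g not in adata.var_names:
            raise KeyError(f"gene {g!r} not in matrix")
    mask = _in_mask(adata, labels, cluster)
    N = _norm10k(as_csr(adata.X).astype(float))
    ia = adata.var_names.get_loc(gene_a)
    ib = adata.var_names.get_loc(gene_b)
    a = float(np.asarray(N[mask, ia].todense()).mean())
    b = float(np.asarray(N[mask, ib].todense()).mean())
    if b < 1e-6:
        warnings.warn(f"denominator ~0 for {gene_b!r} in cluster {cluster!r}")
    return a / (b + eps)


class ClusterSignature(BaseEstimator):
    """Per-cluster inside/outside statistics and signatures, sklearn-style.

    ``fit(adata, labels)`` computes, for every cluster (or the subset in
    ``clusters``), the full statistics table with p/padj and the filtered
    signature. Fitted attributes: ``stats_`` and ``signatures_`` (dicts
    cluster → DataFrame), ``band_schemes_`` (cluster → BandScheme or None
    when the LFCio spread is too small to band).
    """

    def __init__(self, padj_max: float = 0.01, lfc_min: float = 2.0,
                 prefilter_pct: float = 10.0, test: Callable | None = None,
                 clusters: list[str] | None = None):
        self.padj_max = padj_max
        self.lfc_min = lfc_min
        self.prefilter_pct = prefilter_pct
        self.test = test
        self.clusters = clusters

    def fit(self, adata: ad.AnnData, labels):
        arr = _labels_array(adata, labels)
        names = self.clusters or sorted(set(arr))
        self.stats_: dict[str, pd.DataFrame] = {}
        self.signatures_: dict[str, pd.DataFrame] = {}
        self.band_schemes_: dict[str, BandScheme | None] = {}
        for cl in names:
            stats = cluster_gene_stats(adata, arr, cl)
            pv = de_test(adata, arr, cl, test=self.test,
                         prefilter_pct=self.prefilter_pct, stats=stats)
            stats = stats.merge(pv, on="gene")
            self.stats_[cl] = stats
            self.signatures_[cl] = build_signature(
                stats, cluster=cl, padj_max=self.padj_max, lfc_min=self.lfc_min
            )
            tested = stats[stats["p"].notna()]
            try:
                self.band_schemes_[cl] = compute_band_scheme(tested["lfcio"])
            except ValueError:
                self.band_schemes_[cl] = None
        return self
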