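"""Normalization, highly-variable-gene selection and PCA.

All three steps are scikit-learn-style transformers operating on
cells × genes matrices (dense or sparse), with thin AnnData wrappers.

* :class:`LogNormalizer` — per-cell depth normalization to a fixed scale
  (default 10,000 counts) followed by natural-log(1 + x). Invertible.
* :class:`DispersionHVG` — mean-binned standardized dispersion: genes are
  binned into equal-frequency mean-expression bins and their var/mean
  dispersion is z-scored within each bin; the top-n genes by standardized
  dispersion are kept.
* :class:`ScaledPCA` — per-gene centering and unit scaling with values
  clipped at ±10, then PCA; component signs are fixed by making the
  largest-magnitude loading of each component positive, so embeddings are
  reproducible across runs.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._utils import as_csr

__all__ = [
    "LogNormalizer",
    "DispersionHVG",
    "ScaledPCA",
    "normalize_log",
    "select_hvg",
    "pca_embed",
]


class ZeroTotalError(ValueError):
    """A cell with zero total UMI cannot be depth-normalized."""


def _dense(M) -> np.ndarray:
    if sp.issparse(M):
        return np.asarray(M.todense(), dtype=float)
    return np.asarray(M, dtype=float)


class LogNormalizer(TransformerMixin, BaseEstimator):
    """ln(1 + count / cell_total × scale), the standard log-CP10k transform."""

    def __init__(self, scale: float = 1e4):
        self.scale = scale

    def fit(self, X, y=None):
        self.size_factors_ = self._totals(X, names=getattr(X, "obs_names", None))
        return self

    @staticmethod
    def _totals(X, names=None) -> np.ndarray:
        M = as_csr(getattr(X, "X", X))
        totals = np.asarray(M.sum(axis=1)).ravel().astype(float)
        if np.any(totals == 0):
            bad = np.flatnonzero(totals == 0)
            label = (
                ", ".join(str(names[i]) for i in bad[:5])
                if names is not None
                else ", ".join(map(str, bad[:5]))
            )
            raise ZeroTotalError(f"cells with zero total UMI: {label}")
        return totals

    def transform(self, X) -> np.ndarray:
        M = as_csr(getattr(X, "X", X)).astype(float)
        totals = self._totals(X, names=getattr(X, "obs_names", None))
        M = sp.diags(self.scale / totals) @ M
        M.data = np.log1p(M.data)
        return np.asarray(M.todense())

    def inverse_transform(self, values, size_factors) -> np.ndarray:
        """Recover raw counts from log-normalized values and cell totals."""
        return np.expm1(np.asarray(values)) * np.asarray(size_factors)[:, None] / self.scale


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Return a copy with ``X`` log-normalized; totals in ``obs["size_factor"]``."""
    norm = LogNormalizer(scale=scale).fit(adata)
    out = adata.copy()
    out.X = norm.transform(adata)
    out.obs["size_factor"] = norm.size_factors_
    out.uns["normalize"] = {"scale": scale}
    return out


class DispersionHVG(TransformerMixin, BaseEstimator):
    """Select highly variable genes by mean-binned standardized dispersion.

    Operates on log-normalized input; means and var/mean dispersions are
    computed on the de-logged (per-scale) values, genes are cut into
    ``n_bins`` equal-frequency bins of mean expression, and dispersion is
    z-scored within each bin. Genes with zero variance are never selected.
    """

    def __init__(self, n_top: int = 2000, n_bins: int = 20):
        self.n_top = n_top
        self.n_bins = n_bins

    def fit(self, X, y=None):
        V = _dense(getattr(X, "X", X))
        E = np.expm1(V)
        n_genes = E.shape[1]
        if self.n_top > n_genes:
            raise ValueError(f"n_top={self.n_top} exceeds {n_genes} genes")
        means = E.mean(axis=0)
        var = E.var(axis=0, ddof=1) if E.shape[0] > 1 else np.zeros(n_genes)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(means > 0, var / means, 0.0)

        df = pd.DataFrame({"mean": means, "disp": disp})
        bins = min(self.n_bins, n_genes)
        df["bin"] = pd.qcut(df["mean"].rank(method="first"), bins, labels=False)
        grp = df.groupby("bin")["disp"]
        mu, sd = grp.transform("mean"), grp.transform("std")
        z = (df["disp"] - mu) / sd.replace(0.0, np.nan)
        z = z.fillna(0.0).to_numpy()

        self.means_ = means
        self.dispersions_ = disp
        self.dispersions_norm_ = z
        # relative tolerance absorbs rounding noise in exactly-constant genes
        var_floor = 1e-20 * (np.abs(E).max(axis=0) ** 2 + 1e-300)
        eligible = np.flatnonzero(var > var_floor)
        if len(eligible) < self.n_top:
            warnings.warn(
                f"only {len(eligible)} genes with nonzero variance; "
                f"returning all of them instead of n_top={self.n_top}"
            )
            chosen = eligible
        else:
            order = np.lexsort((np.arange(n_genes)[eligible], -z[eligible]))
            chosen = eligible[order[: self.n_top]]
        self.selected_idx_ = np.sort(chosen)
        mask = np.zeros(n_genes, dtype=bool)
        mask[self.selected_idx_] = True
        self.support_ = mask
        return self

    def transform(self, X):
        return _dense(getattr(X, "X", X))[:, self.selected_idx_]


def select_hvg(adata: ad.AnnData, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Names of the ``n`` most variable genes of a log-normalized AnnData."""
    hvg = DispersionHVG(n_top=n, n_bins=n_bins).fit(adata)
    return [adata.var_names[i] for i in hvg.selected_idx_]


class ScaledPCA(TransformerMixin, BaseEstimator):
    """PCA on per-gene standardized values clipped at ±``clip``.

    ``n_compute`` components are calculated and the first ``n_use`` are
    returned, mirroring the common practice of over-computing components and
    using a smaller working dimension.
    """

    def __init__(self, n_compute: int = 100, n_use: int = 50, clip: float = 10.0,
                 random_state: int = 0):
        self.n_compute = n_compute
        self.n_use = n_use
        self.clip = clip
        self.random_state = random_state

    def _scale(self, V: np.ndarray) -> np.ndarray:
        Z = (V - self.center_) / self.scale_
        return np.clip(Z, -self.clip, self.clip)

    def fit(self, X, y=None):
        if self.n_use > self.n_compute:
            raise ValueError("n_use must be <= n_compute")
        V = _dense(getattr(X, "X", X))
        n_comp = self.n_compute
        limit = min(V.shape)
        if n_comp > limit:
            warnings.warn(f"n_compute={n_comp} reduced to {limit} (matrix rank limit)")
            n_comp = limit
        self.center_ = V.mean(axis=0)
        sd = V.std(axis=0, ddof=1) if V.shape[0] > 1 else np.ones(V.shape[1])
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = self._scale(V)
        solver = "full" if max(V.shape) < 1000 else "randomized"
        self._pca = PCA(n_components=n_comp, svd_solver=solver,
                        random_state=self.random_state)
        self._pca.fit(Z)
        comps = self._pca.components_
        signs = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
        signs[signs == 0] = 1.0
        self.sign_ = signs
        self.components_ = comps * signs[:, None]
        self.explained_variance_ = self._pca.explained_variance_
        self.n_components_ = n_comp
        return self

    def transform(self, X) -> np.ndarray:
        V = _dense(getattr(X, "X", X))
        scores = self._pca.transform(self._scale(V)) * self.sign_[None, :]
        return scores[:, : min(self.n_use, self.n_components_)]


def pca_embed(
    adata: ad.AnnData,
    genes: list[str] | None = None,
    n_compute: int = 100,
    n_use: int = 50,
    clip: float = 10.0,
    random_state: int = 0,
) -> np.ndarray:
    """Embed cells with :class:`ScaledPCA` on the given gene subset."""
    sub = adata[:, genes] if genes is not None else adata
    V = np.asarray(sub.X, dtype=float)
    return ScaledPCA(
        n_compute=n_compute, n_use=n_use, clip=clip, random_state=random_state
    ).fit(V).transform(V)
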