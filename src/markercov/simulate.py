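"""Synthetic UMI count matrices with planted cluster/marker structure.

The generator emulates the structure of a droplet scRNA-seq experiment after
cell calling: a sparse cells × genes matrix of UMI counts with

* a fixed number of clusters of unequal size,
* per-cluster planted marker genes whose mean is inflated by a fold change
  inside their own cluster,
* mitochondrial ("MT-") and hemoglobin ("HB") gene families keyed on by QC,
* low-quality cells with a guaranteed >30% mitochondrial UMI fraction, and
* doublets formed as unscaled sums of two parent cells.

Counts follow a gamma-Poisson (negative binomial) law with a single global
dispersion φ, variance m + φ·m², and per-cell library-size factors drawn
log-normal(0, 0.3) so that normalization is non-trivial. Everything is
driven by one integer seed and is bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["SimConfig", "SyntheticTruth", "generate_counts", "write_truth"]

# Cluster sizes default to the 16-type composition of the hemangioma study
# scaled down 5x (unequal sizes spanning two orders of magnitude).
_DEFAULT_CLUSTER_SIZES = (407, 122, 176, 206, 455, 8, 119, 61, 40, 24, 27, 53, 7, 9, 184, 257)


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    ``dispersion`` is the negative-binomial overdispersion φ in the
    mean-variance relation var = m + φ·m²; φ → 0 recovers Poisson.
    """

    n_clusters: int = 16
    cells_per_cluster: Sequence[int] = _DEFAULT_CLUSTER_SIZES
    n_genes: int = 2000
    n_marker_genes_per_cluster: int = 5
    marker_fold_change: float = 8.0
    baseline_mean: float = 1.0
    dispersion: float = 0.5
    frac_mito_genes: float = 0.0065
    frac_hemoglobin_genes: float = 0.005
    n_low_quality_cells: int = 50
    n_doublets: int = 20
    seed: int = 0
    library_size_sigma: float = 0.3
    gene_mean_sigma: float = 0.0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if len(self.cells_per_cluster) != self.n_clusters:
            raise ValueError(
                f"cells_per_cluster has {len(self.cells_per_cluster)} entries "
                f"for n_clusters={self.n_clusters}"
            )
        if any(c < 0 for c in self.cells_per_cluster):
            raise ValueError("cells_per_cluster entries must be >= 0")
        for name in ("n_genes", "n_marker_genes_per_cluster", "n_low_quality_cells", "n_doublets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        for name in ("frac_mito_genes", "frac_hemoglobin_genes"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_marker_genes_per_cluster * self.n_clusters > self._n_regular_genes():
            raise ValueError(
                "not enough non-mito/non-hemoglobin genes for disjoint marker sets: "
                f"need {self.n_marker_genes_per_cluster * self.n_clusters}, "
                f"have {self._n_regular_genes()}"
            )
        if self.n_low_quality_cells > 0 and self._n_mito_genes() == 0:
            raise ValueError("n_low_quality_cells > 0 requires at least one mito gene")
        if self.n_doublets > 0 and sum(self.cells_per_cluster) < 2:
            raise ValueError("doublets need at least two parent cells")

    def _n_mito_genes(self) -> int:
        return int(round(self.frac_mito_genes * self.n_genes))

    def _n_hb_genes(self) -> int:
        return int(round(self.frac_hemoglobin_genes * self.n_genes))

    def _n_regular_genes(self) -> int:
        return self.n_genes - self._n_mito_genes() - self._n_hb_genes()

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["cells_per_cluster"] = list(self.cells_per_cluster)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a simulated matrix.

    ``labels`` covers only genuine single cells; contaminant barcodes are
    listed separately so QC tests can check they are removed.
    """

    labels: pd.Series
    planted_markers: dict[str, list[str]]
    config: SimConfig
    low_quality_barcodes: list[str] = dataclasses.field(default_factory=list)
    doublet_barcodes: list[str] = dataclasses.field(default_factory=list)


def _gene_names(config: SimConfig) -> tuple[list[str], np.ndarray]:
    n_mito, n_hb = config._n_mito_genes(), config._n_hb_genes()
    n_reg = config.n_genes - n_mito - n_hb
    names = [f"G{i + 1}" for i in range(n_reg)]
    names += [f"MT-{i + 1}" for i in range(n_mito)]
    names += [f"HB{i + 1}" for i in range(n_hb)]
    regular_idx = np.arange(n_reg)
    return names, regular_idx


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with var = m + phi*m^2 (size r = 1/phi)."""
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_counts(
    config: SimConfig,
    planted_markers: Mapping[str, Sequence[str]] | None = None,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw a synthetic count matrix and its ground truth.

    Parameters
    ----------
    config
        Validated simulation parameters.
    planted_markers
        Optional explicit cluster → marker-gene assignment. Sets must be
        disjoint across clusters and name existing genes; by default
        ``n_marker_genes_per_cluster`` regular genes are drawn per cluster.

    Returns
    -------
    ``(adata, truth)`` where ``adata`` is cells × genes with boolean var
    columns ``is_mito``/``is_hemoglobin`` and an obs column ``truth``
    (cluster label, ``"low_quality"`` or ``"doublet"``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_names, regular_idx = _gene_names(config)
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    cluster_names = [f"C{i + 1}" for i in range(config.n_clusters)]

    k = config.n_marker_genes_per_cluster
    if planted_markers is None:
        chosen = rng.choice(regular_idx, size=k * config.n_clusters, replace=False)
        markers = {
            cl: sorted(gene_names[j] for j in chosen[i * k:(i + 1) * k])
            for i, cl in enumerate(cluster_names)
        }
    else:
        markers = {cl: list(gs) for cl, gs in planted_markers.items()}
        flat = [g for gs in markers.values() for g in gs]
        if len(flat) != len(set(flat)):
            raise ValueError("planted marker sets overlap across clusters")
        unknown = [g for g in flat if g not in gene_pos]
        if unknown:
            raise ValueError(f"planted markers not in gene list: {unknown}")
        missing = [cl for cl in markers if cl not in cluster_names]
        if missing:
            raise ValueError(f"unknown clusters in planted_markers: {missing}")

    phi = config.dispersion
    # optional spread of per-gene baseline means (log-normal, unit median);
    # 0 keeps every gene's expected count at exactly baseline_mean
    base_means = config.baseline_mean * np.exp(
        rng.normal(0.0, config.gene_mean_sigma, size=config.n_genes)
        if config.gene_mean_sigma > 0 else np.zeros(config.n_genes)
    )
    blocks: list[sp.csr_matrix] = []
    labels: list[str] = []
    for cl, n_cells in zip(cluster_names, config.cells_per_cluster):
        mean_g = base_means.copy()
        for g in markers.get(cl, ()):
            mean_g[gene_pos[g]] *= config.marker_fold_change
        sf = rng.lognormal(0.0, config.library_size_sigma, size=n_cells)
        m = sf[:, None] * mean_g[None, :]
        blocks.append(sp.csr_matrix(_nb_sample(rng, m, phi)))
        labels += [cl] * n_cells

    n_real = sum(config.cells_per_cluster)
    X_real = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, config.n_genes))

    # Low-quality cells: a normal draw plus extra mito UMIs equal to the
    # cell's total, forcing a mitochondrial fraction >= 1/2 > 0.30.
    lowq_rows = []
    mito_idx = np.array([i for i, g in enumerate(gene_names) if g.startswith("MT-")])
    for _ in range(config.n_low_quality_cells):
        sf = rng.lognormal(0.0, config.library_size_sigma)
        row = _nb_sample(rng, sf * base_means, phi)
        if row.sum() == 0:
            row[rng.integers(0, config.n_genes)] = 1
        extra = int(row.sum())
        add = rng.multinomial(extra, np.full(len(mito_idx), 1.0 / len(mito_idx)))
        row[mito_idx] += add
        lowq_rows.append(row)

    doublet_rows = []
    for _ in range(config.n_doublets):
        i, j = rng.choice(n_real, size=2, replace=False)
        doublet_rows.append(
            np.asarray(X_real[i].todense()).ravel() + np.asarray(X_real[j].todense()).ravel()
        )

    parts = [X_real]
    if lowq_rows:
        parts.append(sp.csr_matrix(np.array(lowq_rows)))
    if doublet_rows:
        parts.append(sp.csr_matrix(np.array(doublet_rows)))
    X = sp.vstack(parts, format="csr").astype(np.int64)

    n_total = n_real + config.n_low_quality_cells + config.n_doublets
    barcodes = [f"cell{i + 1:06d}" for i in range(n_total)]
    lowq_bc = barcodes[n_real:n_real + config.n_low_quality_cells]
    dbl_bc = barcodes[n_real + config.n_low_quality_cells:]

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["truth"] = labels + ["low_quality"] * len(lowq_bc) + ["doublet"] * len(dbl_bc)
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    var["is_mito"] = [g.startswith("MT-") for g in gene_names]
    var["is_hemoglobin"] = [g.startswith("HB") for g in gene_names]
    adata = ad.AnnData(X=X, obs=obs, var=var)

    truth = SyntheticTruth(
        labels=pd.Series(labels, index=barcodes[:n_real], name="label"),
        planted_markers=markers,
        config=config,
        low_quality_barcodes=list(lowq_bc),
        doublet_barcodes=list(dbl_bc),
    )
    return adata, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write ground-truth labels (TSV: barcode, label) next to the matrix."""
    df = truth.labels.rename_axis("barcode").reset_index()
    extra = pd.DataFrame(
        {
            "barcode": truth.low_quality_barcodes + truth.doublet_barcodes,
            "label": ["low_quality"] * len(truth.low_quality_barcodes)
            + ["doublet"] * len(truth.doublet_barcodes),
        }
    )
    pd.concat([df, extra], ignore_index=True).to_csv(path, sep="\t", index=False)
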