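"""Graph-based cell clustering and label import.

Clustering follows the standard scRNA-seq recipe: a k-nearest-neighbour
graph (k = 20) on the PCA embedding, then modularity-style community
detection (Leiden, RBConfiguration quality) at a given resolution. The
community-detection backend is pluggable, and externally supplied labels
are first class — every downstream statistic only needs a per-cell label,
so any clustering (or a published one) can be loaded from a two-column TSV.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

__all__ = ["GraphClusterer", "cluster_cells", "load_labels", "write_labels"]


def _leiden_backend(edges: list[tuple[int, int]], n_nodes: int,
                    resolution: float, seed: int) -> list[int]:
    try:
        import igraph
        import leidenalg
    except ImportError as e:  # pragma: no cover
        raise ImportError(
            "no community-detection backend available; install igraph+leidenalg "
            "or supply labels via load_labels()"
        ) from e
    g = igraph.Graph(n=n_nodes, edges=edges, directed=False)
    g.simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return list(part.membership)


class GraphClusterer(ClusterMixin, BaseEstimator):
    """kNN-graph community detection over an embedding.

    Parameters
    ----------
    resolution : community-detection resolution (default 0.4). Smaller values
        merge communities; resolution → 0 yields a single cluster on
        connected data.
    n_neighbors : k of the kNN graph (default 20).
    seed : backend seed; identical input + seed gives identical labels.
    backend : ``"leiden"`` or a callable ``(edges, n_nodes, resolution, seed)
        -> membership list``.
    """

    def __init__(self, resolution: float = 0.4, n_neighbors: int = 20,
                 seed: int = 0, backend: str | Callable = "leiden"):
        self.resolution = resolution
        self.n_neighbors = n_neighbors
        self.seed = seed
        self.backend = backend

    def fit(self, X, y=None):
        E = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(E)):
            raise ValueError("embedding contains non-finite values")
        n = E.shape[0]
        k = min(self.n_neighbors, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
        _, idx = nn.kneighbors(E)
        edges = [(i, int(j)) for i in range(n) for j in idx[i, 1:]]
        backend = self.backend if callable(self.backend) else _leiden_backend
        membership = backend(edges, n, self.resolution, self.seed)
        # relabel communities by first appearance for deterministic names
        remap: dict[int, int] = {}
        labels = []
        for m in membership:
            if m not in remap:
                remap[m] = len(remap)
            labels.append(f"C{remap[m] + 1}")
        self.labels_ = np.array(labels, dtype=object)
        self.n_clusters_ = len(remap)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_cells(
    embedding,
    resolution: float = 0.4,
    n_neighbors: int = 20,
    seed: int = 0,
    backend="leiden",
    index=None,
) -> pd.Series:
    """Cluster an embedding; returns per-cell string labels as a Series."""
    gc = GraphClusterer(
        resolution=resolution, n_neighbors=n_neighbors, seed=seed, backend=backend
    ).fit(embedding)
    return pd.Series(gc.labels_, index=index, name="label")


def load_labels(path, barcodes) -> pd.Series:
    """Read a two-column TSV (barcode, label) covering exactly ``barcodes``.

    Unknown barcodes in the file and barcodes missing from it are both hard
    errors listing the offenders.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "label"],
                     dtype=str, comment=None)
    if list(df.iloc[0]) == ["barcode", "label"]:  # tolerate a header line
        df = df.iloc[1:]
    expected = pd.Index([str(b) for b in barcodes])
    got = pd.Index(df["barcode"])
    unknown = got.difference(expected)
    if len(unknown):
        raise ValueError(f"labels file names unknown barcodes: {sorted(unknown)[:10]}")
    missing = expected.difference(got)
    if len(missing):
        raise ValueError(f"labels file is missing barcodes: {sorted(missing)[:10]}")
    if got.has_duplicates:
        raise ValueError("labels file contains duplicate barcodes")
    s = df.set_index("barcode")["label"].reindex(expected)
    s.index.name = "barcode"
    return s.rename("label")


def write_labels(labels: pd.Series, path) -> None:
    labels.rename_axis("barcode").rename("label").reset_index().to_csv(
        path, sep="\t", index=False, header=False
    )
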