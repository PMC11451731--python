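"""Cell-state clustering from metaprogram activities.

Cells are placed in metaprogram-activity space (z-scored per program), a
k-nearest-neighbor graph is built under the Mahalanobis metric — which
whitens away correlation between program scores — and Louvain community
detection is repeated with independent seeds, keeping the run with the
highest mean silhouette under the same Mahalanobis distances.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.metrics import pairwise_distances, silhouette_score
from sklearn.neighbors import NearestNeighbors

from ._seeds import derive_seed
from .scoring import ActivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CellStateClustering",
    "zscore_activities",
    "whitening_transform",
    "mahalanobis_knn_graph",
    "consensus_louvain",
    "embed_umap",
    "cluster_cell_states",
]


@dataclass
class CellStateClustering:
    """Cluster labels per cell plus the silhouette of the winning run."""

    labels: pd.Series
    silhouette: float  # NaN when every run collapsed to one cluster
    z_activities: pd.DataFrame
    embedding: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def mean_activity_by_cluster(self) -> pd.DataFrame:
        """Mean z-scored activity per (cluster, program) — heatmap summary."""
        return self.z_activities.groupby(self.labels).mean()


def zscore_activities(activities: ActivityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per program: (activity − mean) / sd over all cells (sample sd).

    Zero-variance programs become all-zero columns with a warning.
    """
    df = activities.scores if isinstance(activities, ActivityMatrix) else activities
    if len(df) < 2:
        raise ValueError("need at least 2 cells to z-score")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    zero = pd.Series(
        np.all(df.values == df.values[0:1, :], axis=0), index=df.columns
    )
    if zero.any():
        warnings.warn(
            f"programs with constant activity z-scored to 0: {list(df.columns[zero])}"
        )
    sd[zero] = np.inf
    return (df - mean) / sd


def whitening_transform(z: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Matrix A with ||A(a−b)|| equal to the Mahalanobis distance.

    The covariance is estimated from the data; when ill-conditioned a
    ridge of ``ridge · trace(Σ)/p`` is added (program activities can be
    near-collinear).
    """
    z = np.asarray(z, dtype=float)
    cov = np.cov(z, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    p = cov.shape[0]
    if np.linalg.cond(cov) > 1e8:
        cov = cov + ridge * (np.trace(cov) / p) * np.eye(p)
    try:
        L = scipy.linalg.cholesky(cov, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("covariance singular even after regularization") from exc
    # d(a,b)^2 = (a-b)^T Σ^{-1} (a-b) = ||L^{-1}(a-b)||^2
    return scipy.linalg.solve_triangular(L, np.eye(p), lower=True)


def mahalanobis_knn_graph(z: np.ndarray | pd.DataFrame, k: int) -> igraph.Graph:
    """Undirected, unweighted kNN graph under the Mahalanobis metric.

    Each cell connects to its k nearest others; the union of directed
    edges is symmetrized. With identity covariance this is exactly the
    Euclidean kNN graph.
    """
    zv = z.values if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    n = zv.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    white = zv @ whitening_transform(zv).T
    nn = NearestNeighbors(n_neighbors=k + 1).fit(white)
    _, idx = nn.kneighbors(white)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def consensus_louvain(
    graph: igraph.Graph,
    distances: np.ndarray,
    resolution: float = 0.4,
    n_runs: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Best-of-``n_runs`` Louvain clustering by Mahalanobis silhouette.

    Each run uses a distinct derived seed; the run with the highest mean
    silhouette (precomputed ``distances``) wins, ties to the smaller run
    index. If every run yields a single cluster the trivial clustering is
    returned with silhouette NaN.
    """
    n = graph.vcount()
    best_labels, best_sil, found = None, -np.inf, False
    trivial = None
    state = random.Random()
    for i in range(n_runs):
        state.seed(derive_seed(seed, "louvain-run", i))
        old_state = random.getstate()
        random.setstate(state.getstate())
        try:
            part = graph.community_multilevel(resolution=resolution)
        finally:
            random.setstate(old_state)
        labels = np.asarray(part.membership)
        if len(np.unique(labels)) < 2:
            trivial = labels
            continue
        sil = float(silhouette_score(distances, labels, metric="precomputed"))
        if sil > best_sil:
            best_sil, best_labels, found = sil, labels, True
    if not found:
        logger.warning("every Louvain run collapsed to one cluster")
        return (trivial if trivial is not None else np.zeros(n, dtype=int)), float("nan")
    return best_labels, best_sil


def embed_umap(z: np.ndarray | pd.DataFrame, seed: int = 0) -> np.ndarray:
    """2-D UMAP of the activity space (visualization only)."""
    import umap  # deferred: numba compilation is slow to import

    zv = z.values if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    if zv.shape[0] < 10:
        raise ValueError("need at least 10 cells to embed")
    reducer = umap.UMAP(n_components=2, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(zv))


def cluster_cell_states(
    activities: ActivityMatrix | pd.DataFrame,
    k: int = 30,
    resolution: float = 0.4,
    n_runs: int = 100,
    seed: int = 0,
    compute_embedding: bool = False,
) -> CellStateClustering:
    """Full cell-state pipeline: z-score → Mahalanobis kNN → consensus Louvain."""
    z = zscore_activities(activities)
    graph = mahalanobis_knn_graph(z, k)
    white = z.values @ whitening_transform(z.values).T
    distances = pairwise_distances(white)
    labels, sil = consensus_louvain(
        graph, distances, resolution=resolution, n_runs=n_runs, seed=seed
    )
    emb = None
    if compute_embedding:
        coords = embed_umap(z, seed=derive_seed(seed, "umap"))
        emb = pd.DataFrame(coords, index=z.index, columns=["umap1", "umap2"])
    return CellStateClustering(
        labels=pd.Series(labels, index=z.index, name="cluster"),
        silhouette=sil,
        z_activities=z,
        embedding=emb,
    )
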