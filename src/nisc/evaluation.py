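"""Clustering-accuracy metrics and the embed-then-cluster scoring pipeline.

Partition agreement is scored by three chance-corrected indices (AMI, ARI,
FMI), cluster tightness by the silhouette score on the 2-D embedding, and —
when ground truth exists — reconstruction accuracy by RMSE in log1p space.
The pipeline mirrors common scRNA-seq practice: log-transform, embed the
cells into two dimensions (PCA natively; t-SNE/UMAP via the standard
implementations), cluster the embedding with k-means or Ward-linkage
hierarchical clustering at the known number of cell types, then score the
predicted partition against the true labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm
from sklearn.cluster import AgglomerativeClustering, KMeans

from .data_model import ExpressionMatrix

__all__ = [
    "EvalReport",
    "rmse",
    "adjusted_rand_index",
    "adjusted_mutual_information",
    "fowlkes_mallows",
    "silhouette_score",
    "pca_embed",
    "cluster_and_score",
]


@dataclass
class EvalReport:
    """Metric bundle for one imputed matrix."""

    ami: float
    ari: float
    fmi: float
    silhouette: float
    rmse: float | None
    k_used: int
    embedding_method: str
    clustering_method: str
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=float)


def rmse(truth, other, scale: str = "log1p") -> float:
    """Root mean square error over all entries, by default in log1p space."""
    a, b = _values(truth), _values(other)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if scale == "log1p":
        a, b = np.log1p(a), np.log1p(b)
    elif scale != "raw":
        raise ValueError("scale must be 'log1p' or 'raw'")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _check_labels(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label sequences must be 1-D and equal length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 labelled items")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Permutation-model adjusted Rand index between two labelings."""
    a, b = _check_labels(a, b)
    return float(_skm.adjusted_rand_score(a, b))


def adjusted_mutual_information(a, b) -> float:
    """AMI with arithmetic-mean normalization and natural-log entropies.

    A constant labeling against a non-constant one scores 0 (degenerate
    denominator convention).
    """
    a, b = _check_labels(a, b)
    return float(_skm.adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def fowlkes_mallows(a, b) -> float:
    """Fowlkes-Mallows index TP/sqrt((TP+FP)(TP+FN)) over same-cluster pairs."""
    a, b = _check_labels(a, b)
    return float(_skm.fowlkes_mallows_score(a, b))


def silhouette_score(points, labels) -> float:
    """Mean silhouette over points with Euclidean distances."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(_skm.silhouette_score(points, labels, metric="euclidean"))


def pca_embed(Z: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Top principal components of a centered (cells x genes) matrix.

    Deterministic: component signs are fixed so each component's largest
    absolute loading is positive.
    """
    Zc = Z - Z.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    comp = U[:, :n_components] * s[:n_components]
    for c in range(comp.shape[1]):
        v = Vt[c]
        if v[np.argmax(np.abs(v))] < 0:
            comp[:, c] *= -1
    return comp


def _embed(Z: np.ndarray, method: str, seed: int) -> np.ndarray:
    if method == "pca":
        return pca_embed(Z)
    if method == "tsne":
        from sklearn.manifold import TSNE

        per = min(30.0, max(5.0, (Z.shape[0] - 1) / 3))
        return TSNE(n_components=2, random_state=seed, init="pca", perplexity=per).fit_transform(Z)
    if method == "umap":
        import umap

        return umap.UMAP(n_components=2, random_state=seed).fit_transform(Z)
    raise ValueError(f"unknown embedding {method!r}; choose pca, tsne or umap")


def _cluster(emb: np.ndarray, method: str, k: int, seed: int) -> np.ndarray:
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
    if method == "hierarchical":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(emb)
    if method == "leiden":
        # optional hook: community detection on a kNN graph of the embedding;
        # the number of communities is data-driven, k is not enforced
        import igraph
        import leidenalg
        from sklearn.neighbors import kneighbors_graph

        A = kneighbors_graph(emb, n_neighbors=min(15, emb.shape[0] - 1), mode="connectivity")
        sources, targets = A.nonzero()
        g = igraph.Graph(n=emb.shape[0], edges=list(zip(sources.tolist(), targets.tolist())))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, seed=seed
        )
        return np.asarray(part.membership)
    raise ValueError(f"unknown clustering {method!r}; choose kmeans, hierarchical or leiden")


def cluster_and_score(
    matrix,
    true_labels,
    k: int,
    embedding: str = "pca",
    clustering: str = "kmeans",
    seed: int = 0,
    truth=None,
) -> EvalReport:
    """Normalize -> log1p -> 2-D embedding -> k clusters -> partition metrics.

    Cells are first scaled to a common total count (the median library size),
    the standard normalization step that stops library-size variation from
    dominating the leading components; the log1p matrix is then embedded and
    clustered. Silhouette is computed on the embedding with the *predicted*
    labels, measuring how tight the found clusters look in the visualization;
    AMI, ARI and FMI score the predicted partition against ``true_labels``.
    When ``truth`` is given, log1p RMSE against it is included.
    """
    v = _values(matrix)
    true_labels = np.asarray(true_labels)
    if v.shape[1] != true_labels.size:
        raise ValueError(f"{true_labels.size} labels for {v.shape[1]} cells")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > v.shape[1]:
        raise ValueError(f"k={k} exceeds the number of cells {v.shape[1]}")

    totals = v.sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    scaled = v / totals * np.median(totals)
    Z = np.log1p(scaled).T  # cells x genes
    emb = _embed(Z, embedding, seed)
    pred = _cluster(emb, clustering, k, seed)
    return EvalReport(
        ami=adjusted_mutual_information(true_labels, pred),
        ari=adjusted_rand_index(true_labels, pred),
        fmi=fowlkes_mallows(true_labels, pred),
        silhouette=silhouette_score(emb, pred) if len(np.unique(pred)) > 1 else 0.0,
        rmse=rmse(truth, matrix) if truth is not None else None,
        k_used=int(k),
        embedding_method=embedding,
        clustering_method=clustering,
        seed=int(seed),
    )
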