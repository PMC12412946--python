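"""Phenotype discovery: discretization, spectral clustering and representatives.

Subjects are embedded in the ternary co-expression space of the network
proteins, split into two groups by spectral clustering, the split is scored
with the Calinski-Harabasz index against a permutation null, and each group
is summarized by the real subject nearest its centroid.  Those two
representative ternary profiles are the steady-state constraints handed to
the inference stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import SpectralClustering

from .data_model_io import AbundanceMatrix, DiscreteProfile

__all__ = [
    "ClusterResult",
    "discretize_ternary",
    "spectral_cluster",
    "calinski_harabasz",
    "permutation_null_ch",
    "representative_profiles",
    "phenotype_clusters",
]


def discretize_ternary(matrix: AbundanceMatrix, method: str = "equal-width") -> np.ndarray:
    """Map unit-range values onto the ordinal scale Low=0 / Nominal=1 / High=2.

    equal-width: thirds of [0,1] with half-open bands, top band closed
    ([0,1/3) -> 0, [1/3,2/3) -> 1, [2/3,1] -> 2), applied per protein.
    tertiles: equal-count bands from within-column ranks.
    """
    vals = matrix.values
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("discretization expects unit-range normalized values")
    if method == "equal-width":
        return np.minimum((vals * 3).astype(int), 2)
    if method == "tertiles":
        n = vals.shape[0]
        out = np.empty_like(vals, dtype=int)
        for j in range(vals.shape[1]):
            ranks = np.argsort(np.argsort(vals[:, j], kind="stable"), kind="stable")
            out[:, j] = np.minimum(ranks * 3 // n, 2)
        return out
    raise ValueError(f"unknown discretization method {method!r}")


def _rbf_affinity(X: np.ndarray) -> np.ndarray:
    """RBF affinity with the median-heuristic bandwidth."""
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    off = d2[np.triu_indices_from(d2, k=1)]
    med = np.median(off[off > 0]) if np.any(off > 0) else 0.0
    if med <= 0:
        raise ValueError("degenerate affinity: all subjects identical")
    return np.exp(-d2 / (2.0 * med))


def _knn_affinity(X: np.ndarray, k: int = 10) -> np.ndarray:
    from sklearn.neighbors import kneighbors_graph

    a = kneighbors_graph(X, min(k, X.shape[0] - 1), include_self=False).toarray()
    return np.maximum(a, a.T)


def spectral_cluster(
    X: np.ndarray,
    k: int = 2,
    n_components: int = 2,
    seed: int = 0,
    affinity: str = "rbf",
) -> np.ndarray:
    """Two-way spectral clustering in a 2-eigenvector latent space.

    The subject affinity matrix (RBF with median-heuristic bandwidth by
    default, symmetrized kNN connectivity as an alternative) is embedded via
    the graph Laplacian and k-means is run in the leading eigenvector space.
    Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k:
        raise ValueError("need at least k subjects")
    A = _rbf_affinity(X) if affinity == "rbf" else _knn_affinity(X)
    sc = SpectralClustering(
        n_clusters=k,
        n_components=n_components,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    return sc.fit_predict(A)


def calinski_harabasz(X: np.ndarray, labels) -> float:
    """Calinski-Harabasz index: [B/(k-1)] / [W/(n-k)].

    B is the between-cluster sum of squared distances of cluster means to the
    grand mean (weighted by cluster size); W the pooled within-cluster sum of
    squares.  Returns +inf when W == 0 with k > 1 (perfectly tight clusters).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n == k:
        raise ValueError("as many clusters as points: index undefined")
    grand = X.mean(axis=0)
    b = 0.0
    w = 0.0
    for c in uniq:
        xc = X[labels == c]
        mu = xc.mean(axis=0)
        b += xc.shape[0] * float(((mu - grand) ** 2).sum())
        w += float(((xc - mu) ** 2).sum())
    if w == 0.0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def permutation_null_ch(
    X: np.ndarray, labels, n_perm: int = 100, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Permutation null of the CH score, preserving cluster sizes.

    Returns the null scores and the empirical p-value
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    observed = calinski_harabasz(X, labels)
    rng = np.random.default_rng(seed)
    null = np.array(
        [calinski_harabasz(X, rng.permutation(labels)) for _ in range(n_perm)]
    )
    p = (1.0 + int((null >= observed).sum())) / (1.0 + n_perm)
    return null, p


def representative_profiles(
    discrete: np.ndarray, labels, subject_ids, node_ids
) -> list[tuple[str, DiscreteProfile]]:
    """Per cluster: the subject whose discrete profile is nearest the centroid.

    The centroid is the per-protein mean of discrete states within the
    cluster; distance is Euclidean; ties break by input order.  Returns one
    ``(subject_id, profile)`` per cluster, in cluster-label order.
    """
    discrete = np.asarray(discrete)
    labels = np.asarray(labels)
    out = []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        centroid = discrete[idx].mean(axis=0)
        d = ((discrete[idx] - centroid) ** 2).sum(axis=1)
        best = idx[int(np.argmin(d))]
        out.append((subject_ids[best], DiscreteProfile(node_ids, discrete[best])))
    return out


@dataclass
class ClusterResult:
    """Two-group phenotype split with quality scores and representatives.

    Cluster 0 is the group with the higher mean clinical covariate (the
    high-frequency phenotype), for stable output ordering.
    """

    labels: np.ndarray
    ch_score: float
    null_scores: np.ndarray
    p_value: float
    representative_subjects: list
    representative_profiles: list

    def __post_init__(self):
        if len(np.unique(self.labels)) != 2:
            raise ValueError("expected exactly 2 non-empty clusters")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def phenotype_clusters(
    matrix: AbundanceMatrix,
    node_ids,
    method: str = "equal-width",
    n_perm: int = 100,
    seed: int = 0,
    affinity: str = "rbf",
) -> ClusterResult:
    """Discretize, cluster, score and summarize in one call.

    ``matrix`` must already be unit-range normalized; ``node_ids`` selects the
    network proteins used as the co-expression space.
    """
    sub = matrix.restrict_proteins(node_ids)
    disc = discretize_ternary(sub, method)
    labels = spectral_cluster(disc, k=2, n_components=2, seed=seed, affinity=affinity)
    # stable label semantics: cluster 0 = higher mean exacerbation frequency
    means = [sub.clinical[labels == c].mean() for c in (0, 1)]
    if means[1] > means[0]:
        labels = 1 - labels
    ch = calinski_harabasz(disc, labels)
    null, p = permutation_null_ch(disc, labels, n_perm=n_perm, seed=seed)
    reps = representative_profiles(disc, labels, list(sub.subject_ids), list(node_ids))
    return ClusterResult(
        labels=labels,
        ch_score=ch,
        null_scores=null,
        p_value=p,
        representative_subjects=[s for s, _ in reps],
        representative_profiles=[pr for _, pr in reps],
    )
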