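"""Assembly of the phenotype-relevant protein interaction subnetwork.

Seven steps take a continuous abundance matrix to a closed-loop undirected
subnetwork of proteins tied to the clinical phenotype:

1. unit-range normalization per protein;
2. pairwise mutual information (MI) on an equal-width binned grid, for all
   protein pairs and between each protein and the clinical covariate
   (attached as a dedicated phenotype node), together with a pooled null
   distribution from per-column shuffles;
3. Otsu foreground thresholding of the observed MI distribution;
4. Bonferroni-corrected empirical significance of the foreground edges
   against the pooled null;
5. a signal-to-noise filter (MI at least twice the mean null MI);
6. restriction to nodes within two steps of the phenotype node;
7. iterative removal of nodes of degree < 2 (the 2-core), leaving only
   nodes able to take part in closed regulatory loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data_model_io import AbundanceMatrix

__all__ = [
    "PHENOTYPE_NODE",
    "AssemblyConfig",
    "NullDistribution",
    "normalize_unit_range",
    "binned_mi",
    "knn_mi",
    "pairwise_mi",
    "shuffle_null",
    "otsu_threshold",
    "foreground_filter",
    "significance_filter",
    "snr_filter",
    "prune_to_phenotype",
    "prune_min_degree",
    "assemble",
]

PHENOTYPE_NODE = "exacerbation"


@dataclass
class AssemblyConfig:
    """Settings for the assembly pipeline.

    ``n_bins=None`` selects ceil(sqrt(n_subjects)), a standard bias/variance
    compromise for the plug-in MI estimator.
    """

    n_bins: int | None = None
    log_base: float = math.e
    estimator: str = "binned"  # "binned" | "knn"
    n_shuffles: int = 50
    alpha: float = 0.01
    snr: float = 2.0
    max_path: int = 2
    min_degree: int = 2
    iterative: bool = True
    otsu_bins: int = 256
    seed: int = 0


@dataclass
class NullDistribution:
    """Pooled MI values obtained from per-column shuffles of the data."""

    values: np.ndarray
    n_shuffles: int
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.values.size and self.values.min() < 0:
            raise ValueError("MI values must be nonnegative")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def normalize_unit_range(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Rescale each protein column to span [0, 1] exactly (order-preserving)."""
    vals = matrix.values
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    flat = np.where(hi <= lo)[0]
    if flat.size:
        raise ValueError(
            f"constant abundance column cannot be unit-range normalized: "
            f"{matrix.protein_ids[flat[0]]!r}"
        )
    scaled = (vals - lo) / (hi - lo)
    return AbundanceMatrix(
        list(matrix.subject_ids), list(matrix.protein_ids), scaled, matrix.clinical
    )


def _unit_range(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("cannot unit-range a constant vector")
    return (x - lo) / (hi - lo)


def binned_mi(x, y, n_bins: int, log_base: float = math.e) -> float:
    """Plug-in mutual information on an equal-width n_bins x n_bins grid on [0,1].

    MI = sum_ab p(a,b) log[ p(a,b) / (p(a) p(b)) ], zero-count cells skipped.
    Symmetric in its arguments and nonnegative by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    joint, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    n = joint.sum()
    pj = joint / n
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    nz = pj > 0
    outer = np.outer(px, py)
    mi = float(np.sum(pj[nz] * np.log(pj[nz] / outer[nz])))
    if log_base != math.e:
        mi /= math.log(log_base)
    return max(mi, 0.0)


def knn_mi(x, y, n_neighbors: int = 3, seed: int = 0) -> float:
    """k-nearest-neighbor MI estimate (scikit-learn), offered as an alternative."""
    from sklearn.feature_selection import mutual_info_regression

    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float)
    return float(
        mutual_info_regression(x, y, n_neighbors=n_neighbors, random_state=seed)[0]
    )


def _mi_func(config: AssemblyConfig, n_subjects: int):
    if config.estimator == "binned":
        bins = config.n_bins or math.ceil(math.sqrt(n_subjects))
        return lambda a, b: binned_mi(a, b, bins, config.log_base)
    if config.estimator == "knn":
        return lambda a, b: knn_mi(a, b, seed=config.seed)
    raise ValueError(f"unknown MI estimator {config.estimator!r}")


def _columns_with_phenotype(matrix: AbundanceMatrix):
    """Protein columns plus the unit-ranged clinical covariate as a final column."""
    cols = {p: matrix.values[:, j] for j, p in enumerate(matrix.protein_ids)}
    cols[PHENOTYPE_NODE] = _unit_range(matrix.clinical)
    return cols


def pairwise_mi(matrix: AbundanceMatrix, config: AssemblyConfig | None = None) -> nx.Graph:
    """Complete MI-weighted graph over proteins plus the phenotype node.

    Every unordered protein pair gets an edge with attribute ``mi``; each
    protein is additionally linked to the phenotype node by the MI between its
    abundance and the unit-ranged clinical covariate.
    """
    config = config or AssemblyConfig()
    cols = _columns_with_phenotype(matrix)
    mi = _mi_func(config, matrix.n_subjects)
    names = list(cols)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            g.add_edge(names[i], names[j], mi=mi(cols[names[i]], cols[names[j]]))
    return g


def shuffle_null(
    matrix: AbundanceMatrix,
    n_shuffles: int = 50,
    seed: int = 0,
    config: AssemblyConfig | None = None,
) -> NullDistribution:
    """Pooled null MI distribution from per-column independent shuffles.

    Each iteration permutes every column (proteins and clinical covariate)
    independently, destroying all dependence, and records all pairwise MI
    values; the pool across iterations is the background for significance
    testing.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    config = config or AssemblyConfig()
    rng = np.random.default_rng(seed)
    cols = _columns_with_phenotype(matrix)
    names = list(cols)
    mi = _mi_func(config, matrix.n_subjects)
    pool = []
    for _ in range(n_shuffles):
        shuffled = {n: rng.permutation(cols[n]) for n in names}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pool.append(mi(shuffled[names[i]], shuffled[names[j]]))
    return NullDistribution(np.array(pool), n_shuffles, seed)


def otsu_threshold(values, n_hist_bins: int = 256) -> float:
    """Otsu's foreground/background threshold on a 1-D sample.

    Builds an equal-width histogram over the observed range and returns the
    bin boundary maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2``; equivalent to exhaustive search over all
    candidate boundaries.
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for fewer than 2 distinct values")
    counts, edges = np.histogram(values, bins=n_hist_bins)
    counts = counts.astype(float)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    cum_mass = np.cumsum(counts * centers)[:-1]
    tot_mass = (counts * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_mass / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (tot_mass - cum_mass) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = int(np.argmax(between))
    return float(edges[best + 1])


def foreground_filter(graph: nx.Graph, n_hist_bins: int = 256) -> tuple[nx.Graph, float]:
    """Keep edges with MI at or above the Otsu threshold of all edge MI values."""
    mis = [d["mi"] for _, _, d in graph.edges(data=True)]
    thr = otsu_threshold(mis, n_hist_bins)
    out = graph.edge_subgraph(
        [(u, v) for u, v, d in graph.edges(data=True) if d["mi"] >= thr]
    ).copy()
    return out, thr


def significance_filter(graph: nx.Graph, null: NullDistribution, alpha: float = 0.01) -> nx.Graph:
    """Bonferroni-corrected empirical significance against the pooled null.

    The empirical p-value of an edge is ``(1 + #{null >= mi}) / (1 + |null|)``;
    an edge survives if p <= alpha / M with M the number of edges tested.
    """
    if null.values.size == 0:
        raise ValueError("null distribution is empty")
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("no edges to test")
    sorted_null = np.sort(null.values)
    n = sorted_null.size
    keep = []
    for u, v, d in graph.edges(data=True):
        ge = n - np.searchsorted(sorted_null, d["mi"], side="left")
        p = (1.0 + ge) / (1.0 + n)
        if p <= alpha / m:
            keep.append((u, v))
    return graph.edge_subgraph(keep).copy()


def snr_filter(graph: nx.Graph, null: NullDistribution) -> nx.Graph:
    """Keep edges whose MI is at least twice the mean null MI (inclusive)."""
    if null.values.size == 0:
        raise ValueError("null distribution is empty")
    cut = 2.0 * null.mean
    keep = [(u, v) for u, v, d in graph.edges(data=True) if d["mi"] >= cut]
    return graph.edge_subgraph(keep).copy()


def prune_to_phenotype(
    graph: nx.Graph, phenotype_node: str = PHENOTYPE_NODE, max_path: int = 2
) -> nx.Graph:
    """Keep proteins within ``max_path`` steps of the phenotype node, then drop it.

    The returned graph is the induced protein-only subgraph on the retained
    nodes (first- and second-degree neighbours of the phenotype by default).
    """
    if phenotype_node not in graph:
        raise ValueError(f"phenotype node {phenotype_node!r} not in graph")
    dist = nx.single_source_shortest_path_length(graph, phenotype_node, cutoff=max_path)
    keep = [n for n, d in dist.items() if n != phenotype_node]
    return graph.subgraph(keep).copy()


def prune_min_degree(graph: nx.Graph, k: int = 2, iterative: bool = True) -> nx.Graph:
    """Remove nodes of degree < k; iteratively by default (yielding the k-core)."""
    if iterative:
        return nx.k_core(graph, k)
    keep = [n for n in graph if graph.degree(n) >= k]
    return graph.subgraph(keep).copy()


@dataclass
class AssemblyResult:
    """Final subnetwork plus per-step provenance counts."""

    graph: nx.Graph
    otsu_threshold: float
    null: NullDistribution
    provenance: list = field(default_factory=list)


def assemble(matrix: AbundanceMatrix, config: AssemblyConfig | None = None) -> AssemblyResult:
    """Run the full seven-step pipeline; bit-reproducible under a fixed seed."""
    config = config or AssemblyConfig()
    prov = []

    def log(step_name, g):
        prov.append((step_name, g.number_of_nodes(), g.number_of_edges()))

    norm = normalize_unit_range(matrix)
    g = pairwise_mi(norm, config)
    log("pairwise_mi", g)
    null = shuffle_null(norm, config.n_shuffles, config.seed, config)
    g, thr = foreground_filter(g, config.otsu_bins)
    log("otsu_foreground", g)
    g = significance_filter(g, null, config.alpha)
    log("bonferroni", g)
    g = snr_filter(g, null)
    log("snr", g)
    g = prune_to_phenotype(g, PHENOTYPE_NODE, config.max_path)
    log("phenotype_proximity", g)
    g = prune_min_degree(g, config.min_degree, config.iterative)
    log("min_degree", g)
    return AssemblyResult(graph=g, otsu_threshold=thr, null=null, provenance=prov)
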