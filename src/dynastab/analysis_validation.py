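"""Graph metrics and literature-based scoring of inferred regulatory networks.

The ensemble's per-edge polarity votes are tabulated and compared against a
table of relationships documented in the literature.  A documented directed
relationship counts as recovered by majority vote when the modal polarity
across models is nonzero and, for a documented positive or negative effect,
matches its sign; relationships of unknown effect are credited for any
nonzero modal polarity.  The worst-case positive predictive value assumes
that every near-unanimously voted but undocumented edge is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .data_model_io import ReferenceRelationship, TernaryNetworkModel
from .csp_inference import SolutionEnsemble

__all__ = [
    "ValidationReport",
    "connection_density",
    "node_metrics",
    "vote_table",
    "validate",
]


def connection_density(n_nodes: int, n_edges: int) -> float:
    """Edge count as a percentage of ordered node pairs: 100 * E / (n (n-1))."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 100.0 * n_edges / (n_nodes * (n_nodes - 1))


def node_metrics(model: TernaryNetworkModel) -> pd.DataFrame:
    """Centrality table for the directed active-edge graph.

    Betweenness and closeness use unweighted shortest paths with the standard
    (n-1)(n-2) directed normalization; eigenvector centrality is computed on
    the directed graph and reported as NaN when the power iteration fails
    (e.g. graphs without a suitable dominant eigenvector).
    """
    g = nx.DiGraph()
    g.add_nodes_from(model.node_ids)
    g.add_edges_from((e.source, e.target) for e in model.active_edges)
    if g.number_of_nodes() == 0:
        raise ValueError("empty model")
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g)
    try:
        eigen = nx.eigenvector_centrality_numpy(g)
    except Exception:
        eigen = {n: float("nan") for n in g}
    rows = []
    for n in model.node_ids:
        rows.append(
            {
                "node": n,
                "in_degree": g.in_degree(n),
                "out_degree": g.out_degree(n),
                "betweenness": betweenness[n],
                "closeness": closeness[n],
                "eigenvector": eigen[n],
            }
        )
    return pd.DataFrame(rows).set_index("node")


def vote_table(ensemble: SolutionEnsemble, pairs=None) -> pd.DataFrame:
    """Per directed pair, counts of polarity -1 / 0 / +1 across the ensemble.

    ``pairs`` defaults to every candidate in the skeleton; rows always sum to
    the ensemble size.
    """
    cand_index = {pair: i for i, pair in enumerate(ensemble.skeleton.candidates)}
    if pairs is None:
        pairs = list(ensemble.skeleton.candidates)
    rows = []
    for pair in pairs:
        pair = tuple(pair)
        if pair not in cand_index:
            raise KeyError(f"directed pair {pair} not in skeleton")
        kx = cand_index[pair]
        pol = [m[kx][0] for m in ensemble.models]
        rows.append(
            {
                "source": pair[0],
                "target": pair[1],
                "neg": sum(1 for p in pol if p == -1),
                "zero": sum(1 for p in pol if p == 0),
                "pos": sum(1 for p in pol if p == 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Scoring of ensemble votes against documented relationships."""

    vote_table: pd.DataFrame
    majority_agreement: dict  # (source, target) -> bool
    any_model_agreement: dict
    recall_majority: float
    recall_any_model: float
    worst_case_ppv: float
    unanimity_threshold: float
    n_documented: int
    n_recovered_majority: int
    n_undocumented_near_unanimous: int


def _modal_polarity(row) -> int:
    counts = {-1: row["neg"], 0: row["zero"], 1: row["pos"]}
    best = 0  # ties resolve toward 0 (conservative: no call), then -1, then +1
    for cand in (-1, 1):
        if counts[cand] > counts[best]:
            best = cand
    return best


def _sign_matches(effect: str, polarity: int) -> bool:
    if polarity == 0:
        return False
    if effect == "unknown":
        return True
    return polarity == (1 if effect == "positive" else -1)


def validate(
    votes: pd.DataFrame,
    reference: list,
    unanimity_threshold: float = 0.98,
) -> ValidationReport:
    """Score a full vote table against literature reference relationships.

    ``votes`` must carry one row per directed candidate pair with columns
    source, target, neg, zero, pos (as produced by :func:`vote_table` over the
    whole skeleton).  Recall is the fraction of documented relationships
    recovered; the worst-case PPV treats every undocumented pair whose
    same-polarity vote share reaches ``unanimity_threshold`` as a false
    positive: recovered / (recovered + near-unanimous undocumented).
    """
    if not reference:
        raise ValueError("reference table is empty")
    for rel in reference:
        if not isinstance(rel, ReferenceRelationship):
            raise TypeError("reference entries must be ReferenceRelationship")
    votes = votes.reset_index(drop=True)
    n_models = int((votes["neg"] + votes["zero"] + votes["pos"]).iloc[0])
    if not ((votes["neg"] + votes["zero"] + votes["pos"]) == n_models).all():
        raise ValueError("vote rows must all sum to the ensemble size")

    by_pair = {(r["source"], r["target"]): r for _, r in votes.iterrows()}
    documented = {(rel.source, rel.target): rel for rel in reference}

    majority_agreement, any_model_agreement = {}, {}
    for pair, rel in documented.items():
        row = by_pair.get(pair)
        if row is None:
            majority_agreement[pair] = False
            any_model_agreement[pair] = False
            continue
        mode = _modal_polarity(row)
        majority_agreement[pair] = _sign_matches(rel.effect, mode)
        any_neg = row["neg"] > 0
        any_pos = row["pos"] > 0
        if rel.effect == "unknown":
            any_model_agreement[pair] = any_neg or any_pos
        elif rel.effect == "positive":
            any_model_agreement[pair] = any_pos
        else:
            any_model_agreement[pair] = any_neg

    n_doc = len(documented)
    n_rec = sum(majority_agreement.values())
    recall_majority = n_rec / n_doc
    recall_any = sum(any_model_agreement.values()) / n_doc

    n_near_unanimous = 0
    for _, row in votes.iterrows():
        pair = (row["source"], row["target"])
        if pair in documented:
            continue
        share_neg = row["neg"] / n_models
        share_pos = row["pos"] / n_models
        if share_neg >= unanimity_threshold or share_pos >= unanimity_threshold:
            n_near_unanimous += 1
    denom = n_rec + n_near_unanimous
    ppv = n_rec / denom if denom else float("nan")

    return ValidationReport(
        vote_table=votes,
        majority_agreement=majority_agreement,
        any_model_agreement=any_model_agreement,
        recall_majority=recall_majority,
        recall_any_model=recall_any,
        worst_case_ppv=ppv,
        unanimity_threshold=unanimity_threshold,
        n_documented=n_doc,
        n_recovered_majority=n_rec,
        n_undocumented_near_unanimous=n_near_unanimous,
    )
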