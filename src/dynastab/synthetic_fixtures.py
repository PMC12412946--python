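"""Ground-truth scenario generation for end-to-end testing of the pipeline.

A scenario is a known directed ternary regulatory network satisfying all
structural constraints (closed loops, no sources/sinks, at least one
activator per node), two of its exhaustively verified fixed points, and a
continuous abundance matrix in which each subject's per-protein value sits
at the band center of their cluster's fixed-point state plus Gaussian noise.
With noise below one sixth of the unit range the default equal-width
discretizer recovers the fixed points exactly, so every downstream stage has
a known correct answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model_io import (
    AbundanceMatrix,
    CandidateEdge,
    DiscreteProfile,
    SteadyStateConstraintSet,
    TernaryNetworkModel,
)
from . import csp_inference, ternary_dynamics

__all__ = [
    "SyntheticScenario",
    "generate_truth",
    "generate_abundance",
    "generate_scenario",
    "recovery_harness",
]

# cluster-mean exacerbation frequencies (episodes/year) for the high- and
# low-vulnerability phenotypes; chosen to mirror a typical frequent- vs
# infrequent-exacerbator contrast in stable COPD cohorts
DEFAULT_CLINICAL_MEANS = (2.5, 1.5)
CLINICAL_SD = 0.5


@dataclass
class SyntheticScenario:
    """A ground-truth model, two fixed points and a noisy abundance matrix."""

    truth: TernaryNetworkModel
    fixed_points: list
    abundance: AbundanceMatrix
    cluster_assignment: np.ndarray
    noise_sd: float
    cluster_clinical_means: tuple
    seed: int


def _random_skeleton(n_nodes: int, n_edges: int, rng: np.random.Generator):
    """Undirected skeleton with min degree 2: a Hamiltonian cycle plus chords."""
    names = [f"N{i:02d}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = {frozenset((names[order[i]], names[order[(i + 1) % n_nodes]])) for i in range(n_nodes)}
    all_pairs = [
        frozenset((names[i], names[j]))
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
    ]
    rng.shuffle(all_pairs)
    for pair in all_pairs:
        if len(edges) >= n_edges:
            break
        edges.add(pair)
    if len(edges) < n_edges:
        raise ValueError(f"cannot place {n_edges} edges on {n_nodes} nodes")
    cycle = [(names[order[i]], names[order[(i + 1) % n_nodes]]) for i in range(n_nodes)]
    cycle_keys = {frozenset(c) for c in cycle}
    # sort for hash-seed-independent reproducibility before any iteration
    extras = sorted(tuple(sorted(e)) for e in edges if e not in cycle_keys)
    return names, cycle, extras


def generate_truth(
    n_nodes: int,
    n_edges: int,
    seed: int = 0,
    max_tries: int = 500,
) -> tuple[TernaryNetworkModel, list]:
    """Rejection-sample a structurally valid model with >= 2 distinct fixed points.

    A random Hamiltonian cycle is directed consistently with positive
    polarity (guaranteeing every node an activator, an active in-edge and an
    active out-edge); remaining skeleton edges receive random orientation and
    parameters.  Candidates are kept only if exhaustive attractor search
    finds at least two distinct fixed points.  Returns ``(model,
    fixed_points)`` with fixed points sorted by decreasing pairwise
    distinctiveness (the two most dissimilar first).
    """
    if n_edges < n_nodes:
        raise ValueError("need n_edges >= n_nodes for closed-loop feasibility")
    if n_nodes > ternary_dynamics.EXHAUSTIVE_NODE_LIMIT:
        raise ValueError(
            f"exhaustive fixed-point verification limited to "
            f"{ternary_dynamics.EXHAUSTIVE_NODE_LIMIT} nodes"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        names, cycle, extras = _random_skeleton(n_nodes, n_edges, rng)
        edges = [CandidateEdge(u, v, 1, 1, 1) for u, v in cycle]
        for u, v in extras:
            if rng.random() < 0.5:
                u, v = v, u
            p = int(rng.choice([-1, 1]))
            w = int(rng.choice([1, 2]))
            t = int(rng.choice([1, 2]))
            edges.append(CandidateEdge(u, v, p, w, t))
        model = TernaryNetworkModel(names, edges)
        found = ternary_dynamics.find_attractors(model, mode="exhaustive")
        fps = [fp for fp, _ in found["fixed_points"]]
        if len(fps) < 2:
            continue
        # pick the most mutually distant pair first, for well-separated phenotypes
        best, best_d = None, -1
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                d = sum(a != b for a, b in zip(fps[i].states, fps[j].states))
                if d > best_d:
                    best, best_d = (fps[i], fps[j]), d
        ordered = list(best) + [f for f in fps if f not in best]
        return model, ordered
    raise RuntimeError(f"no valid model with >=2 fixed points after {max_tries} tries")


def generate_abundance(
    truth: TernaryNetworkModel,
    fixed_points,
    n_per_cluster: int = 30,
    noise_sd: float = 0.05,
    seed: int = 0,
    cluster_clinical_means: tuple = DEFAULT_CLINICAL_MEANS,
    n_noise_proteins: int = 0,
) -> tuple[AbundanceMatrix, np.ndarray]:
    """Continuous abundances around the band centers of two fixed points.

    Subject value for protein i in cluster l is ``(c_il + 0.5) / 3`` plus
    Gaussian noise, clipped to [0, 1]; the clinical covariate is drawn from a
    normal around the cluster mean (sd 0.5), truncated at zero.

    ``n_noise_proteins`` appends that many phenotype-unrelated uniform(0,1)
    columns (named ``X..``), emulating the background proteome against which
    the assembly pipeline must isolate the planted subnetwork.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    fps = list(fixed_points)[:2]
    nodes = list(fps[0].node_ids)
    rows, clin, labels, subjects = [], [], [], []
    for l, fp in enumerate(fps):
        centers = (np.array(fp.states, dtype=float) + 0.5) / 3.0
        for s in range(n_per_cluster):
            noise = rng.normal(0.0, noise_sd, size=len(nodes)) if noise_sd > 0 else 0.0
            rows.append(np.clip(centers + noise, 0.0, 1.0))
            clin.append(max(0.0, rng.normal(cluster_clinical_means[l], CLINICAL_SD)))
            labels.append(l)
            subjects.append(f"S{l}{s:03d}")
    values = np.array(rows)
    if n_noise_proteins:
        bg = rng.random((values.shape[0], n_noise_proteins))
        values = np.hstack([values, bg])
        nodes = nodes + [f"X{j:02d}" for j in range(n_noise_proteins)]
    return (
        AbundanceMatrix(subjects, nodes, values, np.array(clin)),
        np.array(labels),
    )


def generate_scenario(
    n_nodes: int = 8,
    n_edges: int = 12,
    n_per_cluster: int = 30,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_noise_proteins: int = 0,
) -> SyntheticScenario:
    """Convenience wrapper: truth network + two fixed points + abundance matrix."""
    truth, fps = generate_truth(n_nodes, n_edges, seed=seed)
    abundance, labels = generate_abundance(
        truth, fps[:2], n_per_cluster=n_per_cluster, noise_sd=noise_sd, seed=seed + 1,
        n_noise_proteins=n_noise_proteins,
    )
    return SyntheticScenario(
        truth=truth,
        fixed_points=fps[:2],
        abundance=abundance,
        cluster_assignment=labels,
        noise_sd=noise_sd,
        cluster_clinical_means=DEFAULT_CLINICAL_MEANS,
        seed=seed,
    )


def truth_assignment(truth: TernaryNetworkModel, skeleton) -> list:
    """The truth parameterization expressed over a candidate skeleton."""
    by_pair = {(e.source, e.target): (e.polarity, e.weight, e.threshold) for e in truth.edges}
    return [by_pair.get(pair, csp_inference.INACTIVE) for pair in skeleton.candidates]


def recovery_harness(scenario: SyntheticScenario, n_models: int = 100, seed: int = 0) -> dict:
    """Solve the inference problem posed by a scenario and score it against truth.

    Asserts that (a) the problem is satisfiable, (b) the generating
    parameterization satisfies the encoded constraints, and (c) every sampled
    model makes both fixed points fixed points of its dynamics (the solver
    re-verifies this internally).  Reports edge-level precision/recall of the
    majority-vote network against the truth's active edges.
    """
    truth = scenario.truth
    undirected = sorted({tuple(sorted((e.source, e.target))) for e in truth.active_edges})
    skeleton = csp_inference.build_skeleton(undirected)
    profiles = [
        DiscreteProfile(skeleton.node_ids, [fp.state_of(n) for n in skeleton.node_ids])
        for fp in scenario.fixed_points
    ]
    problem = csp_inference.encode(skeleton, SteadyStateConstraintSet(profiles))
    assignment = truth_assignment(truth, skeleton)
    truth_ok = csp_inference.satisfies(problem, assignment)
    ensemble = csp_inference.solve_ensemble(problem, n_models=n_models, seed=seed)
    if ensemble.status != "SAT":
        raise AssertionError("scenario problem unexpectedly UNSAT")
    if not truth_ok:
        raise AssertionError("generating parameterization violates encoded constraints")

    majority, any_active = csp_inference.majority_vote_network(ensemble)
    truth_edges = {(e.source, e.target) for e in truth.active_edges}
    predicted = set(majority)
    tp = len(predicted & truth_edges)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth_edges)
    return {
        "status": ensemble.status,
        "truth_satisfies": truth_ok,
        "n_models": ensemble.n_models,
        "majority_edges": len(predicted),
        "any_active_edges": len(any_active),
        "edge_precision": precision,
        "edge_recall": recall,
        "ensemble": ensemble,
    }
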