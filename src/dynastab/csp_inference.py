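"""Constraint-satisfaction inference of directed, signed, threshold-gated edges.

Every undirected interaction is expanded into two opposing directed
candidates, each carrying three free integer parameters: polarity
p in {-1,0,+1}, decisional weight w in {0,1,2} and perception threshold
t in {1,2}.  An assignment of all parameters is a valid regulatory model
when

* p == 0 exactly when w == 0 (an absent edge has no weight, and vice versa);
* every observed steady-state profile is a fixed point of the ternary
  dynamics: with raw drive ``raw = sum w * p * (c_source // t)`` over active
  incoming candidates, a node observed Low needs raw <= 0, Nominal needs
  raw == 1, High needs raw >= 2 (i.e. clamp(raw) equals the observed state);
* no source or sink nodes: every node keeps at least one active incoming
  and one active outgoing candidate;
* no purely repressed nodes: every node keeps at least one incoming
  candidate with positive polarity.

The solution space is explored with a randomized backtracking enumerator
using interval propagation on the per-node drives; distinct solutions are
sampled by re-randomizing the search order and blocking previously found
assignments, yielding an ensemble of competing models whose per-parameter
consensus, centroid-representative model and majority-vote network are then
summarized.  Inactive candidates are canonicalized to threshold 1 so the
dangling threshold of an absent edge cannot inflate the count of distinct
solutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_model_io import (
    CandidateEdge,
    DiscreteProfile,
    SteadyStateConstraintSet,
    TernaryNetworkModel,
)
from . import ternary_dynamics

__all__ = [
    "CandidateSkeleton",
    "ConstraintProblem",
    "SolutionEnsemble",
    "CANONICAL_DOMAIN",
    "build_skeleton",
    "count_parameter_space",
    "encode",
    "satisfies",
    "enumerate_solutions",
    "solve_ensemble",
    "model_from_assignment",
    "consensus",
    "representative_model",
    "majority_vote_network",
    "write_ensemble",
    "read_ensemble",
]

# admissible (p, w, t) triples with the coupling p==0 <=> w==0 and inactive
# candidates pinned to t=1: 1 inactive + 2*2*2 active = 9 values
CANONICAL_DOMAIN: tuple = ((0, 0, 1),) + tuple(
    (p, w, t) for p in (-1, 1) for w in (1, 2) for t in (1, 2)
)

INACTIVE = (0, 0, 1)


@dataclass
class CandidateSkeleton:
    """Both orientations of every undirected edge, parameters still free."""

    node_ids: list
    candidates: list  # ordered (source, target) pairs; 2 per undirected edge

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_parameters(self) -> int:
        return 3 * len(self.candidates)


def build_skeleton(undirected_edges) -> CandidateSkeleton:
    """Expand undirected pairs into opposing directed candidates."""
    seen = set()
    nodes: list = []
    node_set = set()
    candidates = []
    for u, v in undirected_edges:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        key = frozenset((u, v))
        if key in seen:
            raise ValueError(f"duplicate undirected pair {u}-{v}")
        seen.add(key)
        for n in (u, v):
            if n not in node_set:
                node_set.add(n)
                nodes.append(n)
        candidates.append((u, v))
        candidates.append((v, u))
    return CandidateSkeleton(node_ids=nodes, candidates=candidates)


def count_parameter_space(skeleton: CandidateSkeleton, mode: str = "coupled") -> int:
    """Exact size of the parameter space as a big integer.

    raw: 3*3*2 = 18 per candidate, ignoring the polarity/weight coupling;
    coupled: 10 per candidate (coupling enforced, threshold free);
    canonical: 9 per candidate (coupling enforced, inactive pinned to t=1).
    """
    per = {"raw": 18, "coupled": 10, "canonical": 9}
    if mode not in per:
        raise ValueError(f"mode must be one of {sorted(per)}")
    return per[mode] ** skeleton.n_candidates


# source-state -> attainable contributions p*w*(s // t) over the active domain
_CONTRIB_RANGE = {0: (0, 0), 1: (-2, 2), 2: (-4, 4)}


@dataclass
class ConstraintProblem:
    """Encoded problem: skeleton, profiles, and per-candidate contribution tables."""

    skeleton: CandidateSkeleton
    constraints: SteadyStateConstraintSet
    semantics: str = "clamp"  # "clamp" | "equality"
    # contrib[k][l][d] = drive contribution of candidate k to its target in
    # profile l when assigned CANONICAL_DOMAIN[d]
    contrib: list = field(init=False, repr=False)
    node_index: dict = field(init=False, repr=False)
    targets: np.ndarray = field(init=False, repr=False)  # observed states, (K, L)

    def __post_init__(self):
        if self.semantics not in ("clamp", "equality"):
            raise ValueError(f"unknown steady-state semantics {self.semantics!r}")
        cset = set(self.constraints.node_ids)
        missing = [n for n in self.skeleton.node_ids if n not in cset]
        if missing:
            raise ValueError(f"profiles missing states for skeleton nodes: {missing}")
        self.node_index = {n: i for i, n in enumerate(self.skeleton.node_ids)}
        profs = self.constraints.profiles
        k = len(self.skeleton.node_ids)
        self.targets = np.array(
            [[p.state_of(n) for p in profs] for n in self.skeleton.node_ids], dtype=int
        )
        self.contrib = []
        for (src, _tgt) in self.skeleton.candidates:
            per_profile = []
            for p in profs:
                c = p.state_of(src)
                per_profile.append(tuple(pp * w * (c // t) for (pp, w, t) in CANONICAL_DOMAIN))
            self.contrib.append(per_profile)

    @property
    def n_profiles(self) -> int:
        return self.constraints.n_profiles


def encode(
    skeleton: CandidateSkeleton,
    constraints: SteadyStateConstraintSet,
    semantics: str = "clamp",
) -> ConstraintProblem:
    """Build the constraint problem over the skeleton's free parameters."""
    return ConstraintProblem(skeleton=skeleton, constraints=constraints, semantics=semantics)


def _drive_ok(problem: ConstraintProblem, c: int, lo: int, hi: int) -> bool:
    """Can a final drive in [lo, hi] still satisfy the steady-state condition?"""
    if problem.semantics == "equality":
        return lo <= c <= hi
    if c == 0:
        return lo <= 0
    if c == 1:
        return lo <= 1 <= hi
    return hi >= 2


def satisfies(problem: ConstraintProblem, assignment) -> bool:
    """Check a complete assignment (one (p,w,t) triple per candidate) directly.

    Independent of the backtracking search; used to test ground-truth
    parameterizations and returned solutions.
    """
    triples = _as_triples(problem, assignment)
    k = len(problem.skeleton.node_ids)
    L = problem.n_profiles
    drive = np.zeros((k, L), dtype=int)
    active_in = np.zeros(k, dtype=int)
    active_out = np.zeros(k, dtype=int)
    pos_in = np.zeros(k, dtype=int)
    for (src, tgt), (p, w, t) in zip(problem.skeleton.candidates, triples):
        if (p == 0) != (w == 0):
            return False
        si, ti = problem.node_index[src], problem.node_index[tgt]
        if w >= 1:
            active_in[ti] += 1
            active_out[si] += 1
            if p > 0:
                pos_in[ti] += 1
            for l, prof in enumerate(problem.constraints.profiles):
                drive[ti, l] += p * w * (prof.state_of(src) // t)
    if active_in.min() < 1 or active_out.min() < 1 or pos_in.min() < 1:
        return False
    for i in range(k):
        for l in range(L):
            if not _drive_ok(problem, int(problem.targets[i, l]), drive[i, l], drive[i, l]):
                return False
    return True


def _as_triples(problem: ConstraintProblem, assignment) -> list:
    """Accept a dict keyed by (source, target) or a sequence in candidate order."""
    if isinstance(assignment, dict):
        return [tuple(assignment[c]) for c in problem.skeleton.candidates]
    triples = [tuple(v) for v in assignment]
    if len(triples) != problem.skeleton.n_candidates:
        raise ValueError("assignment length does not match candidate count")
    return triples


class _Search:
    """Randomized backtracking enumerator with interval propagation.

    Candidates are assigned grouped by target node so each node's
    steady-state interval collapses early; per-node drive bounds, active
    in/out-degree reachability and activator reachability are maintained
    incrementally and prune the search.  A set of blocked complete
    assignments supports distinct-solution sampling.
    """

    def __init__(self, problem: ConstraintProblem, rng: np.random.Generator | None):
        self.p = problem
        sk = problem.skeleton
        self.m = sk.n_candidates
        self.k = len(sk.node_ids)
        self.L = problem.n_profiles
        self.src = np.array([problem.node_index[s] for s, _ in sk.candidates])
        self.tgt = np.array([problem.node_index[t] for _, t in sk.candidates])

        # variable order: nodes (shuffled), incoming candidates of each node
        node_order = list(range(self.k))
        cand_of_tgt = {i: [] for i in range(self.k)}
        for kx in range(self.m):
            cand_of_tgt[int(self.tgt[kx])].append(kx)
        if rng is not None:
            rng.shuffle(node_order)
            for i in cand_of_tgt:
                rng.shuffle(cand_of_tgt[i])
        self.order = [kx for i in node_order for kx in cand_of_tgt[i]]

        # per-variable value order
        nd = len(CANONICAL_DOMAIN)
        if rng is None:
            self.value_order = [list(range(nd))] * self.m
        else:
            self.value_order = [list(rng.permutation(nd)) for _ in range(self.m)]

        # contribution bounds per candidate/profile
        self.cmin = np.zeros((self.m, self.L), dtype=int)
        self.cmax = np.zeros((self.m, self.L), dtype=int)
        for kx in range(self.m):
            for l in range(self.L):
                vals = problem.contrib[kx][l]
                self.cmin[kx, l] = min(vals)
                self.cmax[kx, l] = max(vals)

        # search state
        self.sum = np.zeros((self.k, self.L), dtype=int)
        self.rem_lo = np.zeros((self.k, self.L), dtype=int)
        self.rem_hi = np.zeros((self.k, self.L), dtype=int)
        for kx in range(self.m):
            ti = int(self.tgt[kx])
            self.rem_lo[ti] += self.cmin[kx]
            self.rem_hi[ti] += self.cmax[kx]
        self.active_in = np.zeros(self.k, dtype=int)
        self.active_out = np.zeros(self.k, dtype=int)
        self.pos_in = np.zeros(self.k, dtype=int)
        self.rem_in = np.bincount(self.tgt, minlength=self.k)
        self.rem_out = np.bincount(self.src, minlength=self.k)
        self.assign = [None] * self.m

    # -- incremental state updates ------------------------------------------

    def _apply(self, kx: int, d: int) -> None:
        p, w, _t = CANONICAL_DOMAIN[d]
        si, ti = int(self.src[kx]), int(self.tgt[kx])
        contrib = self.p.contrib[kx]
        for l in range(self.L):
            self.sum[ti, l] += contrib[l][d]
            self.rem_lo[ti, l] -= self.cmin[kx, l]
            self.rem_hi[ti, l] -= self.cmax[kx, l]
        self.rem_in[ti] -= 1
        self.rem_out[si] -= 1
        if w >= 1:
            self.active_in[ti] += 1
            self.active_out[si] += 1
            if p > 0:
                self.pos_in[ti] += 1
        self.assign[kx] = d

    def _undo(self, kx: int, d: int) -> None:
        p, w, _t = CANONICAL_DOMAIN[d]
        si, ti = int(self.src[kx]), int(self.tgt[kx])
        contrib = self.p.contrib[kx]
        for l in range(self.L):
            self.sum[ti, l] -= contrib[l][d]
            self.rem_lo[ti, l] += self.cmin[kx, l]
            self.rem_hi[ti, l] += self.cmax[kx, l]
        self.rem_in[ti] += 1
        self.rem_out[si] += 1
        if w >= 1:
            self.active_in[ti] -= 1
            self.active_out[si] -= 1
            if p > 0:
                self.pos_in[ti] -= 1
        self.assign[kx] = None

    def _feasible_after(self, kx: int) -> bool:
        si, ti = int(self.src[kx]), int(self.tgt[kx])
        for l in range(self.L):
            c = int(self.p.targets[ti, l])
            lo = int(self.sum[ti, l] + self.rem_lo[ti, l])
            hi = int(self.sum[ti, l] + self.rem_hi[ti, l])
            if not _drive_ok(self.p, c, lo, hi):
                return False
        if self.active_in[ti] == 0 and self.rem_in[ti] == 0:
            return False
        if self.pos_in[ti] == 0 and self.rem_in[ti] == 0:
            return False
        if self.active_out[si] == 0 and self.rem_out[si] == 0:
            return False
        return True

    # -- enumeration --------------------------------------------------------

    def solutions(self, blocked: set | None = None):
        """Yield complete satisfying assignments not in ``blocked``."""
        blocked = blocked if blocked is not None else set()
        m = self.m
        order = self.order

        def rec(depth: int):
            if depth == m:
                sol = tuple(CANONICAL_DOMAIN[d] for d in self.assign)
                if sol not in blocked:
                    yield sol
                return
            kx = order[depth]
            for d in self.value_order[kx]:
                self._apply(kx, d)
                if self._feasible_after(kx):
                    yield from rec(depth + 1)
                self._undo(kx, d)

        yield from rec(0)


def enumerate_solutions(problem: ConstraintProblem, limit: int | None = None):
    """Deterministically enumerate all satisfying assignments (up to ``limit``).

    Each yielded solution is a tuple of (p, w, t) triples in skeleton
    candidate order, with inactive candidates canonicalized to (0, 0, 1).
    """
    out = []
    for sol in _Search(problem, rng=None).solutions():
        out.append(sol)
        if limit is not None and len(out) >= limit:
            break
    return out


@dataclass
class SolutionEnsemble:
    """Distinct satisfying models over a shared candidate skeleton."""

    skeleton: CandidateSkeleton
    constraints: SteadyStateConstraintSet
    models: list  # tuples of (p,w,t) triples in candidate order
    seed: int
    status: str  # "SAT" | "UNSAT"
    semantics: str = "clamp"

    @property
    def n_models(self) -> int:
        return len(self.models)

    def parameter_matrix(self) -> np.ndarray:
        """models x (3 * candidates) integer matrix, columns p,w,t per candidate."""
        return np.array([[v for triple in m for v in triple] for m in self.models], int)

    def parameter_names(self) -> list:
        names = []
        for (s, t) in self.skeleton.candidates:
            names += [f"p[{s}->{t}]", f"w[{s}->{t}]", f"t[{s}->{t}]"]
        return names


def model_from_assignment(
    skeleton: CandidateSkeleton, assignment, drop_inactive: bool = False
) -> TernaryNetworkModel:
    """Materialize an assignment as a :class:`TernaryNetworkModel`."""
    edges = []
    for (src, tgt), (p, w, t) in zip(skeleton.candidates, assignment):
        if drop_inactive and w == 0:
            continue
        edges.append(CandidateEdge(src, tgt, p, w, t))
    return TernaryNetworkModel(list(skeleton.node_ids), edges)


def solve_ensemble(
    problem: ConstraintProblem,
    n_models: int = 100,
    seed: int = 0,
    verify: bool = True,
) -> SolutionEnsemble:
    """Sample up to ``n_models`` distinct solutions of the constraint problem.

    Each model is found by a fresh randomized-order backtracking run with all
    previously found assignments blocked, so repeated runs walk different
    corners of the solution space; when fewer than ``n_models`` solutions
    exist, all of them are returned.  Every model is re-verified against the
    discrete dynamics: each constraint profile must be a fixed point of the
    materialized network (an independent check of the encoding).
    """
    rng = np.random.default_rng(seed)
    blocked: set = set()
    models: list = []
    while len(models) < n_models:
        search = _Search(problem, rng=rng)
        sol = next(search.solutions(blocked=blocked), None)
        if sol is None:
            break
        blocked.add(sol)
        if verify:
            model = model_from_assignment(problem.skeleton, sol)
            for prof in problem.constraints.profiles:
                aligned = DiscreteProfile(
                    model.node_ids, [prof.state_of(n) for n in model.node_ids]
                )
                if not ternary_dynamics.is_fixed_point(model, aligned):
                    raise AssertionError(
                        "solver produced an assignment whose constraint profile "
                        "is not a fixed point of the dynamics"
                    )
        models.append(sol)
    status = "SAT" if models else "UNSAT"
    return SolutionEnsemble(
        skeleton=problem.skeleton,
        constraints=problem.constraints,
        models=models,
        seed=seed,
        status=status,
        semantics=problem.semantics,
    )


@dataclass
class ConsensusSummary:
    """Per-parameter modal agreement across an ensemble."""

    parameter_names: list
    modal_values: np.ndarray
    modal_counts: np.ndarray
    n_models: int
    threshold: float
    n_at_threshold: int
    n_unanimous: int

    @property
    def agreement(self) -> np.ndarray:
        return self.modal_counts / self.n_models


def consensus(ensemble: SolutionEnsemble, threshold: float = 0.80) -> ConsensusSummary:
    """Modal value and agreement for each of the 3 x candidates parameters."""
    if not ensemble.models:
        raise ValueError("empty ensemble")
    mat = ensemble.parameter_matrix()
    modal_vals = np.empty(mat.shape[1], dtype=int)
    modal_counts = np.empty(mat.shape[1], dtype=int)
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        best = int(np.argmax(counts))  # ties: smallest value (np.unique is sorted)
        modal_vals[j] = vals[best]
        modal_counts[j] = counts[best]
    n = ensemble.n_models
    frac = modal_counts / n
    return ConsensusSummary(
        parameter_names=ensemble.parameter_names(),
        modal_values=modal_vals,
        modal_counts=modal_counts,
        n_models=n,
        threshold=threshold,
        n_at_threshold=int((frac >= threshold).sum()),
        n_unanimous=int((modal_counts == n).sum()),
    )


def representative_model(
    ensemble: SolutionEnsemble, metric: str = "euclidean"
) -> TernaryNetworkModel:
    """The ensemble member nearest the per-parameter centroid.

    Distance is Euclidean over the integer parameter vector by default
    (Hamming as an option); ties break by ensemble order.  Inactive
    candidates are dropped from the returned model.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    mat = ensemble.parameter_matrix().astype(float)
    centroid = mat.mean(axis=0)
    if metric == "euclidean":
        d = ((mat - centroid) ** 2).sum(axis=1)
    elif metric == "hamming":
        d = (mat != np.round(centroid)).sum(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    best = int(np.argmin(d))
    return model_from_assignment(ensemble.skeleton, ensemble.models[best], drop_inactive=True)


def majority_vote_network(ensemble: SolutionEnsemble):
    """Directed signed edges by modal polarity, plus the any-model-active set.

    Returns ``(majority, any_active)``: ``majority`` maps (source, target) to
    the modal polarity for candidates whose mode is nonzero; ``any_active``
    is the set of candidates active (w >= 1) in at least one model.
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    majority = {}
    any_active = set()
    for kx, pair in enumerate(ensemble.skeleton.candidates):
        pol = [m[kx][0] for m in ensemble.models]
        vals, counts = np.unique(pol, return_counts=True)
        mode = int(vals[np.argmax(counts)])
        if mode != 0:
            majority[pair] = mode
        if any(m[kx][1] >= 1 for m in ensemble.models):
            any_active.add(pair)
    return majority, any_active


# ---------------------------------------------------------------------------
# Ensemble serialization
# ---------------------------------------------------------------------------


def write_ensemble(path, ensemble: SolutionEnsemble, threshold: float = 0.80) -> None:
    obj = {
        "node_ids": list(ensemble.skeleton.node_ids),
        "candidates": [list(c) for c in ensemble.skeleton.candidates],
        "profiles": [list(p.states) for p in ensemble.constraints.profiles],
        "profile_nodes": list(ensemble.constraints.node_ids),
        "seed": ensemble.seed,
        "status": ensemble.status,
        "semantics": ensemble.semantics,
        "models": [[list(t) for t in m] for m in ensemble.models],
    }
    if ensemble.models:
        c = consensus(ensemble, threshold)
        obj["consensus"] = {
            "parameter_names": c.parameter_names,
            "modal_values": c.modal_values.tolist(),
            "modal_counts": c.modal_counts.tolist(),
            "threshold": c.threshold,
            "n_at_threshold": c.n_at_threshold,
            "n_unanimous": c.n_unanimous,
        }
    with open(path, "w") as fh:
        json.dump(obj, fh)
        fh.write("\n")


def read_ensemble(path) -> SolutionEnsemble:
    with open(path) as fh:
        obj = json.load(fh)
    skeleton = CandidateSkeleton(
        node_ids=list(obj["node_ids"]),
        candidates=[tuple(c) for c in obj["candidates"]],
    )
    profiles = [
        DiscreteProfile(obj["profile_nodes"], states) for states in obj["profiles"]
    ]
    return SolutionEnsemble(
        skeleton=skeleton,
        constraints=SteadyStateConstraintSet(profiles),
        models=[tuple(tuple(t) for t in m) for m in obj["models"]],
        seed=obj["seed"],
        status=obj["status"],
        semantics=obj.get("semantics", "clamp"),
    )
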