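"""Discrete ternary regulatory dynamics.

Each node holds a state in {0,1,2} (Low/Nominal/High).  The drive on a node
is the signed, weighted sum of its active regulators, each gated by a
perception threshold via floor division of the source state:

    drive_i = sum over active edges j->i of  w * p * (s_j // t)

The node's image (target state) is the drive clamped to [0, 2] — a piecewise
linear response with an implicit decay to zero when all activators are off.
Each update moves a state toward its image by at most ``max_step`` levels.
A profile in which every node already sits at its image is a fixed point;
these fixed points are the persistent phenotypes the inference machinery
constrains.
"""

from __future__ import annotations

import itertools

import numpy as np

from .data_model_io import (
    DiscreteProfile,
    SimulationSettings,
    TernaryNetworkModel,
)

__all__ = [
    "node_raw_drive",
    "node_image",
    "step",
    "is_fixed_point",
    "iterate",
    "find_attractors",
    "EXHAUSTIVE_NODE_LIMIT",
]

EXHAUSTIVE_NODE_LIMIT = 12  # 3^12 = 531441 states


def node_raw_drive(model: TernaryNetworkModel, states: DiscreteProfile, node) -> int:
    """Signed weighted drive on ``node`` from its active incoming edges."""
    if node not in model.in_neighbors:
        raise KeyError(f"node {node!r} not in model")
    total = 0
    for e in model.in_neighbors[node]:
        s = states.state_of(e.source)
        total += e.weight * e.polarity * (s // e.threshold)
    return total


def node_image(model: TernaryNetworkModel, states: DiscreteProfile, node) -> int:
    """Target state for ``node``: raw drive clamped to {0,1,2}."""
    return min(2, max(0, node_raw_drive(model, states, node)))


def _images(model: TernaryNetworkModel, states: DiscreteProfile) -> tuple:
    return tuple(node_image(model, states, n) for n in states.node_ids)


def _move(s: int, image: int, max_step: int) -> int:
    delta = image - s
    if delta > 0:
        return s + min(delta, max_step)
    if delta < 0:
        return s - min(-delta, max_step)
    return s


def step(
    model: TernaryNetworkModel,
    states: DiscreteProfile,
    settings: SimulationSettings | None = None,
    rng: np.random.Generator | None = None,
) -> DiscreteProfile:
    """Advance the system one update.

    Synchronous scheme: every node moves toward its image (computed from the
    current state) by at most ``max_step``.  Asynchronous random-order scheme:
    nodes update one at a time in a random order, each seeing the partially
    updated state; pass an ``rng`` for reproducible orders.
    """
    if settings is None:
        settings = SimulationSettings()
    nodes = states.node_ids
    if settings.scheme == "synchronous":
        images = _images(model, states)
        new = [_move(s, im, settings.max_step) for s, im in zip(states.states, images)]
        return DiscreteProfile(nodes, new)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    current = list(states.states)
    for i in rng.permutation(len(nodes)):
        prof = DiscreteProfile(nodes, current)
        im = node_image(model, prof, nodes[i])
        current[i] = _move(current[i], im, settings.max_step)
    return DiscreteProfile(nodes, current)


def is_fixed_point(model: TernaryNetworkModel, states: DiscreteProfile) -> bool:
    """True iff every node's image equals its current state."""
    return _images(model, states) == states.states


def iterate(
    model: TernaryNetworkModel,
    states: DiscreteProfile,
    settings: SimulationSettings | None = None,
):
    """Iterate ``step`` until revisit or ``max_iters``; return the trajectory."""
    if settings is None:
        settings = SimulationSettings()
    rng = np.random.default_rng(settings.seed)
    traj = [states]
    seen = {states.states: 0}
    for _ in range(settings.max_iters):
        nxt = step(model, traj[-1], settings, rng=rng)
        if nxt.states in seen:
            traj.append(nxt)
            return traj
        seen[nxt.states] = len(traj)
        traj.append(nxt)
    return traj


def find_attractors(
    model: TernaryNetworkModel,
    settings: SimulationSettings | None = None,
    mode: str = "exhaustive",
    n_starts: int = 1000,
    seed: int = 0,
) -> dict:
    """Locate attractors of the synchronous dynamics.

    Exhaustive mode classifies all 3^K states (limited to K <= 12) by
    following the deterministic synchronous map until a previously classified
    state or a new cycle is met; sampled mode follows trajectories from
    ``n_starts`` random initial states.

    Returns a dict with ``fixed_points`` (list of (profile, basin_size)) and
    ``cycles`` (list of (tuple-of-profiles, basin_size)); basin sizes are
    exact state counts in exhaustive mode and hit counts in sampled mode.
    """
    if settings is None:
        settings = SimulationSettings()
    if settings.scheme != "synchronous":
        raise ValueError("attractor search requires the deterministic synchronous scheme")
    nodes = tuple(model.node_ids)
    k = len(nodes)

    def successor(s: tuple) -> tuple:
        prof = DiscreteProfile(nodes, s)
        images = _images(model, prof)
        return tuple(_move(x, im, settings.max_step) for x, im in zip(s, images))

    if mode == "exhaustive":
        if k > EXHAUSTIVE_NODE_LIMIT:
            raise ValueError(
                f"exhaustive attractor search limited to {EXHAUSTIVE_NODE_LIMIT} nodes, got {k}"
            )
        starts = itertools.product((0, 1, 2), repeat=k)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        starts = [tuple(rng.integers(0, 3, size=k).tolist()) for _ in range(n_starts)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    succ_cache: dict = {}
    attractor_of: dict = {}  # state -> attractor id
    attractors: list = []  # list of tuple-of-states (cycle; length 1 == fixed point)
    hits: dict = {}  # sampled mode: trajectories landing on each attractor

    for s0 in starts:
        path = []
        seen_on_path = set()
        s = s0
        while True:
            if s in attractor_of:
                aid = attractor_of[s]
                break
            if s in seen_on_path:
                # new cycle discovered on this walk; canonical rotation
                i = path.index(s)
                cycle = tuple(path[i:])
                j = cycle.index(min(cycle))
                cycle = cycle[j:] + cycle[:j]
                aid = len(attractors)
                attractors.append(cycle)
                for c in cycle:
                    attractor_of[c] = aid
                break
            path.append(s)
            seen_on_path.add(s)
            if s not in succ_cache:
                succ_cache[s] = successor(s)
            s = succ_cache[s]
        for p in path:
            if p not in attractor_of:
                attractor_of[p] = aid
        hits[aid] = hits.get(aid, 0) + 1

    if mode == "exhaustive":
        # exact basin sizes: states classified to each attractor
        basin: dict = {}
        for s, aid in attractor_of.items():
            basin[aid] = basin.get(aid, 0) + 1
    else:
        basin = hits

    fixed_points, cycles = [], []
    for aid, cyc in enumerate(attractors):
        if len(cyc) == 1:
            fixed_points.append((DiscreteProfile(nodes, cyc[0]), basin.get(aid, 0)))
        else:
            cycles.append((tuple(DiscreteProfile(nodes, c) for c in cyc), basin.get(aid, 0)))
    return {"fixed_points": fixed_points, "cycles": cycles}
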