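"""Domain types and file I/O for the regulatory-network inference pipeline.

The pipeline moves between four kinds of objects: continuous abundance
matrices (subjects x proteins plus one clinical covariate), undirected
interaction networks, ternary (0/1/2) expression profiles, and directed
parameterized network models.  Everything here is plain delimited text or
JSON so files stay diffable and bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "DiscreteProfile",
    "CandidateEdge",
    "TernaryNetworkModel",
    "SteadyStateConstraintSet",
    "SimulationSettings",
    "ReferenceRelationship",
    "read_abundance",
    "read_network_definition",
    "write_network_definition",
    "read_model",
    "write_model",
    "read_reference_table",
    "xlsx_to_csv",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class AbundanceMatrix:
    """Continuous subjects x proteins abundance table with a clinical covariate.

    Parameters
    ----------
    subject_ids : list of str
        Opaque subject identifiers, one per row.
    protein_ids : list of str
        Protein accessions (UniProt-style), one per column.
    values : ndarray of shape (n_subjects, n_proteins)
        Positive abundance values in arbitrary units.
    clinical : ndarray of shape (n_subjects,)
        Per-subject clinical covariate (exacerbation episodes per year).
    """

    subject_ids: list
    protein_ids: list
    values: np.ndarray
    clinical: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.clinical = np.asarray(self.clinical, dtype=float)
        _check_unique(self.subject_ids, "subject")
        _check_unique(self.protein_ids, "protein")
        if self.values.shape != (len(self.subject_ids), len(self.protein_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.protein_ids)} proteins"
            )
        if self.clinical.shape != (len(self.subject_ids),):
            raise ValueError("clinical covariate length does not match subject count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance values must be finite (impute or drop first)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def drop_subjects(self, subject_ids) -> "AbundanceMatrix":
        """Return a copy without the given subjects (e.g. outlier removal)."""
        drop = set(subject_ids)
        keep = [i for i, s in enumerate(self.subject_ids) if s not in drop]
        return AbundanceMatrix(
            [self.subject_ids[i] for i in keep],
            list(self.protein_ids),
            self.values[keep],
            self.clinical[keep],
        )

    def restrict_proteins(self, protein_ids) -> "AbundanceMatrix":
        """Return a copy restricted to the given proteins, in the given order."""
        index = {p: j for j, p in enumerate(self.protein_ids)}
        cols = [index[p] for p in protein_ids]
        return AbundanceMatrix(
            list(self.subject_ids), list(protein_ids), self.values[:, cols], self.clinical
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subject_ids, columns=self.protein_ids)
        df.index.name = "subject"
        return df


@dataclass(frozen=True)
class DiscreteProfile:
    """Ternary expression profile: one state in {0,1,2} (Low/Nominal/High) per node."""

    node_ids: tuple
    states: tuple

    def __init__(self, node_ids, states):
        node_ids = tuple(node_ids)
        states = tuple(int(s) for s in states)
        if len(node_ids) != len(states):
            raise ValueError("node_ids and states must have the same length")
        bad = [s for s in states if s not in (0, 1, 2)]
        if bad:
            raise ValueError(f"states must be in {{0,1,2}}; got {bad[0]}")
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "states", states)

    def state_of(self, node) -> int:
        return self.states[self.node_ids.index(node)]

    def __len__(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class CandidateEdge:
    """Directed parameterized edge: polarity p, weight w, perception threshold t.

    Polarity +1 activates the target, -1 inactivates it, 0 means the edge is
    absent; absence is coupled to zero weight.  The threshold gates the source
    state: a source contributes ``w * p * (s_source // t)``, so t=2 edges only
    respond to a fully High (state 2) source.
    """

    source: str
    target: str
    polarity: int
    weight: int
    threshold: int

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r} not allowed")
        if self.polarity not in (-1, 0, 1):
            raise ValueError(f"polarity must be in {{-1,0,1}}, got {self.polarity}")
        if self.weight not in (0, 1, 2):
            raise ValueError(f"weight must be in {{0,1,2}}, got {self.weight}")
        if self.threshold not in (1, 2):
            raise ValueError(f"threshold must be in {{1,2}}, got {self.threshold}")
        if (self.polarity == 0) != (self.weight == 0):
            raise ValueError(
                f"polarity==0 iff weight==0 violated on "
                f"{self.source}->{self.target} (p={self.polarity}, w={self.weight})"
            )

    @property
    def active(self) -> bool:
        return self.weight >= 1


@dataclass
class TernaryNetworkModel:
    """Directed network over a node set with per-edge (polarity, weight, threshold).

    ``in_neighbors`` maps each node to the list of active edges feeding it
    (the regulator set of that node).
    """

    node_ids: list
    edges: list
    in_neighbors: dict = field(init=False, repr=False)

    def __post_init__(self):
        _check_unique(self.node_ids, "node")
        nodes = set(self.node_ids)
        seen_pairs = set()
        for e in self.edges:
            if e.source not in nodes or e.target not in nodes:
                raise ValueError(f"edge {e.source}->{e.target} has endpoint outside node set")
            if (e.source, e.target) in seen_pairs:
                raise ValueError(f"duplicate directed edge {e.source}->{e.target}")
            seen_pairs.add((e.source, e.target))
        self.in_neighbors = {n: [] for n in self.node_ids}
        for e in self.edges:
            if e.active:
                self.in_neighbors[e.target].append(e)

    @property
    def active_edges(self) -> list:
        return [e for e in self.edges if e.active]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TernaryNetworkModel):
            return NotImplemented
        return list(self.node_ids) == list(other.node_ids) and sorted(
            (e.source, e.target, e.polarity, e.weight, e.threshold) for e in self.edges
        ) == sorted(
            (e.source, e.target, e.polarity, e.weight, e.threshold) for e in other.edges
        )


@dataclass
class SteadyStateConstraintSet:
    """L observed ternary steady-state profiles over a shared ordered node set."""

    profiles: list

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("need at least one steady-state profile")
        first = self.profiles[0].node_ids
        for p in self.profiles[1:]:
            if p.node_ids != first:
                raise ValueError("all profiles must share the same node ordering")

    @property
    def node_ids(self) -> tuple:
        return self.profiles[0].node_ids

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)


@dataclass
class SimulationSettings:
    """Update-scheme settings for the discrete dynamics.

    max_step is the largest per-iteration change of any node state (the rate
    limit of the update rule); scheme selects synchronous or random-order
    asynchronous updating.
    """

    max_step: int = 1
    scheme: str = "synchronous"
    max_iters: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.max_step not in (1, 2):
            raise ValueError("max_step must be 1 or 2")
        if self.scheme not in ("synchronous", "asynchronous-random-order"):
            raise ValueError(f"unknown update scheme {self.scheme!r}")
        if self.max_iters < 1:
            raise ValueError("max_iters must be positive")


@dataclass(frozen=True)
class ReferenceRelationship:
    """One literature-documented directed relationship between two proteins."""

    source: str
    target: str
    effect: str  # "positive" | "negative" | "unknown"
    category: str = ""
    n_refs: int = 0

    def __post_init__(self):
        if self.effect not in ("positive", "negative", "unknown"):
            raise ValueError(f"effect must be positive/negative/unknown, got {self.effect!r}")
        if self.n_refs < 0:
            raise ValueError("n_refs must be nonnegative")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_abundance(
    path,
    clinical_column: str,
    subject_column: str | None = None,
    sep: str | None = None,
    impute_median: bool = False,
) -> AbundanceMatrix:
    """Read a delimited subjects x proteins table into an :class:`AbundanceMatrix`.

    The table has one row per subject, one column per protein, a subject
    identifier column (the first column by default) and one clinical column.
    Missing abundance values are rejected unless ``impute_median`` is set, in
    which case they are replaced by the per-protein median.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if subject_column is None:
        subject_column = df.columns[0]
    if clinical_column not in df.columns:
        raise ValueError(f"clinical column {clinical_column!r} not found in {path}")
    subjects = df[subject_column].astype(str).tolist()
    clinical = pd.to_numeric(df[clinical_column], errors="raise").to_numpy(float)
    prot_cols = [c for c in df.columns if c not in (subject_column, clinical_column)]
    try:
        values = df[prot_cols].apply(pd.to_numeric, errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric abundance cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        if not impute_median:
            raise ValueError(
                "abundance table contains missing values; pass impute_median=True "
                "to fill them with per-protein medians"
            )
        med = np.nanmedian(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = med[idx[1]]
    return AbundanceMatrix(subjects, prot_cols, values, clinical)


_EDGES_HEADER = "[edges]"
_PROFILES_HEADER = "[profiles]"


def read_network_definition(path, sep: str = "\t"):
    """Read a two-section network-and-profiles definition file.

    The format has an ``[edges]`` section (two node-id columns per line) and a
    ``[profiles]`` section (node id followed by one ternary state per profile)::

        [edges]
        source<TAB>target
        A<TAB>B
        ...
        [profiles]
        node<TAB>profile_0<TAB>profile_1
        A<TAB>1<TAB>2
        ...

    Returns ``(edges, constraints)`` where ``edges`` is a list of undirected
    ``(u, v)`` pairs and ``constraints`` a :class:`SteadyStateConstraintSet`.
    Profiles must cover every node appearing in the edge list; profile rows for
    nodes absent from the edges are ignored with a warning.
    """
    import warnings

    section = None
    edge_rows, profile_rows = [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            low = line.lower()
            if low == _EDGES_HEADER:
                section = "edges"
                continue
            if low == _PROFILES_HEADER:
                section = "profiles"
                continue
            if section == "edges":
                edge_rows.append(line.split(sep))
            elif section == "profiles":
                profile_rows.append(line.split(sep))
            else:
                raise ValueError(f"{path}: content before any section header: {line!r}")
    if not edge_rows or not profile_rows:
        raise ValueError(f"{path}: both [edges] and [profiles] sections are required")

    # optional header lines
    if edge_rows and edge_rows[0][:2] == ["source", "target"]:
        edge_rows = edge_rows[1:]
    if profile_rows and profile_rows[0][0] == "node":
        profile_rows = profile_rows[1:]

    edges = []
    seen = set()
    for row in edge_rows:
        if len(row) < 2:
            raise ValueError(f"{path}: edge row needs two columns: {row}")
        u, v = row[0], row[1]
        if u == v:
            raise ValueError(f"{path}: self-loop on {u!r}")
        key = frozenset((u, v))
        if key in seen:
            raise ValueError(f"{path}: duplicate undirected pair {u}-{v}")
        seen.add(key)
        edges.append((u, v))

    edge_nodes = sorted({n for e in edges for n in e})
    states_by_node = {}
    n_profiles = None
    for row in profile_rows:
        node, vals = row[0], row[1:]
        if n_profiles is None:
            n_profiles = len(vals)
        elif len(vals) != n_profiles:
            raise ValueError(f"{path}: inconsistent profile count on row for {node!r}")
        parsed = []
        for v in vals:
            s = int(v)
            if s not in (0, 1, 2):
                raise ValueError(f"{path}: state {s} for node {node!r} outside {{0,1,2}}")
            parsed.append(s)
        if node not in edge_nodes:
            warnings.warn(f"{path}: profile node {node!r} absent from edge list; ignored")
            continue
        states_by_node[node] = parsed

    missing = [n for n in edge_nodes if n not in states_by_node]
    if missing:
        raise ValueError(f"{path}: nodes in edges with no profile state: {missing}")
    profiles = [
        DiscreteProfile(edge_nodes, [states_by_node[n][l] for n in edge_nodes])
        for l in range(n_profiles)
    ]
    return edges, SteadyStateConstraintSet(profiles)


def write_network_definition(path, edges, constraints: SteadyStateConstraintSet, sep="\t"):
    """Write the two-section definition format read by :func:`read_network_definition`."""
    with open(path, "w") as fh:
        fh.write(_EDGES_HEADER + "\n")
        fh.write(sep.join(("source", "target")) + "\n")
        for u, v in edges:
            fh.write(f"{u}{sep}{v}\n")
        fh.write(_PROFILES_HEADER + "\n")
        header = ["node"] + [f"profile_{l}" for l in range(constraints.n_profiles)]
        fh.write(sep.join(header) + "\n")
        for i, node in enumerate(constraints.node_ids):
            states = [str(p.states[i]) for p in constraints.profiles]
            fh.write(sep.join([str(node)] + states) + "\n")


def _model_to_dict(model: TernaryNetworkModel) -> dict:
    return {
        "node_ids": list(model.node_ids),
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "polarity": e.polarity,
                "weight": e.weight,
                "threshold": e.threshold,
            }
            for e in model.edges
        ],
    }


def write_model(path, model: TernaryNetworkModel) -> None:
    """Serialize a model to JSON; ``read_model(write_model(m)) == m``."""
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)
        fh.write("\n")


def read_model(path) -> TernaryNetworkModel:
    with open(path) as fh:
        obj = json.load(fh)
    edges = [
        CandidateEdge(e["source"], e["target"], e["polarity"], e["weight"], e["threshold"])
        for e in obj["edges"]
    ]
    return TernaryNetworkModel(list(obj["node_ids"]), edges)


def read_reference_table(path) -> list:
    """Read a CSV of literature relationships (source,target,effect,category,n_refs)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"source", "target", "effect"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: reference table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ReferenceRelationship(
                source=row["source"],
                target=row["target"],
                effect=row["effect"].strip().lower(),
                category=row.get("category", ""),
                n_refs=int(row["n_refs"]) if row.get("n_refs", "") else 0,
            )
        )
    return out


def xlsx_to_csv(xlsx_path, csv_path, sheet=0) -> None:
    """Convert one sheet of a spreadsheet to CSV; the core readers consume CSV only."""
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    df.to_csv(csv_path, index=False)
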