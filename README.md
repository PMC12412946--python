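# dynastab

Inference of directed, signed, threshold-gated protein co-regulatory
networks from **cross-sectional** co-expression data, by requiring that
phenotype-representative expression profiles be **fixed points** of a
discrete dynamical system.

Protein–protein interaction networks built from observational cohorts are
undirected: mutual information (or correlation) says two proteins co-vary,
not which one regulates the other or whether the action activates or
represses. Time-course data would resolve this, but most clinical
proteomics is a single cross-sectional snapshot. `dynastab` exploits a
different signal: subjects sampled during *stable* illness should sit at
dynamically stable states of the underlying regulatory network. If two
phenotype groups (say frequent and infrequent infectious exacerbators in
COPD) each have a representative expression profile, then any plausible
regulatory network must hold **both** profiles as steady states. That
requirement, plus mild structural conditions, is enough to constrain
direction and mode of action for much of the network.

## The model

Each protein holds a ternary activation state, Low = 0 / Nominal = 1 /
High = 2. A directed edge *j → i* carries three integer parameters:
polarity *p(j,i)* ∈ {−1, 0, +1}, decisional weight *w(j,i)* ∈ {0, 1, 2}
and perception threshold *t(j,i)* ∈ {1, 2}, with *p = 0 ⇔ w = 0* (an
absent edge has no weight). The drive on node *i* is

    s*_i(t) = Σ_{j ∈ Ω_i}  w(j,i) · p(j,i) · ⌊ s_j(t) / t(j,i) ⌋

and the target state (image) is that drive clamped to [0, 2] — a piecewise
linear response with an implicit decay to zero when no activator fires.
States move toward their image at most one level per update:

    s_i(t+1) = s_i(t) + sign(s*_i − s_i) · min(|s*_i − s_i|, Δs_max)

A profile where every node equals its image is a fixed point.

Inference expands every undirected interaction into both directed
candidates and solves a constraint-satisfaction problem over all (p, w, t):
each observed profile must be a fixed point, every node keeps at least one
active incoming and one active outgoing edge (no sources/sinks — closed
loops only), and at least one incoming activator (else the node could
never hold a nonzero state). The solution space is sampled into an
ensemble of competing models; per-parameter consensus, a
centroid-representative model, and a majority-vote signed network summarize
what the ensemble agrees on.

The surrounding pipeline covers the full path from a raw abundance table:

1. **network_assembly** – unit-range normalization; equal-width binned
   mutual information for all protein pairs and against the clinical
   covariate; a pooled shuffle null; Otsu foreground thresholding;
   Bonferroni-corrected significance; a signal-to-noise (≥ 2× mean null
   MI) filter; pruning to within two steps of the phenotype; 2-core
   reduction.
2. **phenotyping** – ternary discretization, two-group spectral
   clustering, Calinski–Harabasz scoring against a permutation null, and
   per-cluster centroid-nearest representative profiles.
3. **csp_inference / ternary_dynamics** – the constraint solver and the
   simulator that independently verifies every sampled model.
4. **analysis_validation** – centrality metrics and scoring of ensemble
   votes against literature-documented relationships.
5. **synthetic_fixtures** – ground-truth scenario generation so that the
   entire pipeline is testable with a known correct answer.

## Worked example

Generate a 5-protein ground-truth scenario, then infer an ensemble of 100
models from its network definition file (undirected edges + two steady
state profiles):

```sh
$ dynastab synth --nodes 5 --edges 7 --per-cluster 30 --noise 0.05 \
      --seed 4 --out-dir fixtures
wrote scenario to fixtures
$ dynastab infer --network fixtures/network_definition.tsv \
      --n-models 100 --seed 1 --out ensemble.json --model-out model.json
status=SAT models=100
```

`status=SAT` means the two profiles are jointly explainable as fixed
points; 100 distinct parameterizations were sampled. Summarizing:

```python
>>> from dynastab import csp_inference as ci
>>> ens = ci.read_ensemble("ensemble.json")
>>> maj, _ = ci.majority_vote_network(ens)
>>> len(maj)
14
>>> sorted(maj.items())[:2]
[(('N00', 'N01'), 1), (('N00', 'N02'), 1)]
```

Here all 14 directed candidates are recruited by majority vote, each with
positive modal polarity — with only two fixed points on a small dense
skeleton the ensemble stays diverse (only 1 of 42 parameters exceeds 80%
agreement), illustrating how consensus strength measures how sharply the
steady-state data pin down the regulatory logic. Node metrics of the
representative model (`dynastab metrics --model model.json --out
metrics.tsv`) report in/out degree, betweenness, closeness and eigenvector
centrality per protein; the highest-betweenness nodes are the network's
information brokers.

The two-section definition file format is plain TSV:

```
[edges]
source  target
N00     N01
...
[profiles]
node    profile_0   profile_1
N00     0           2
...
```

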