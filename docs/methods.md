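# Methods

## Scope and assumptions

`dynastab` treats a cross-sectional cohort of protein abundance profiles
as a set of snapshots of a regulatory system at rest. Its central
assumption is *dynamic stability*: subjects sampled during stable illness
occupy attractors of a shared regulatory network, and the two phenotype
groups correspond to two distinct fixed points of one and the same
network. Inference then asks which directed, signed, threshold-gated
parameterizations of the observed undirected interaction skeleton hold
both representative profiles fixed. The method does not attempt causal
discovery in the interventional sense; it enumerates the regulatory
logics *consistent with* stability, and reports where they agree.

## Ternary dynamics

States live in {0, 1, 2} (Low / Nominal / High). For node *i* with
regulator set Ω_i the drive is Σ w·p·⌊s_j / t⌋ over active incoming
edges, and the image is the drive clamped to [0, 2].

Design choices that the update rule leaves open, and how they are fixed:

- **Threshold gating** is floor division of the *source* state by the
  edge threshold: a t = 2 edge transmits only when its source is fully
  High (⌊1/2⌋ = 0, ⌊2/2⌋ = 1), and then at unit strength. This makes
  t = 2 a genuine perception threshold rather than an attenuation factor.
- **The image is clamped before use.** The alternative (requiring the
  raw drive to equal the observed state exactly) makes saturated states
  needlessly hard to hold: a node observed High would demand a drive of
  exactly 2, outlawing strong redundant activation. Clamp semantics treat
  any drive ≥ 2 as High and any drive ≤ 0 as Low. The strict-equality
  encoding remains available (`semantics="equality"`) for sensitivity
  analysis.
- **Rate limiting** is signed and magnitude-capped: a state moves toward
  its image by at most `max_step` (default 1) levels per update.
- **Update scheme** defaults to synchronous (deterministic, required for
  attractor enumeration); asynchronous random-order updating is available
  since convergence behaviour can depend on the scheme.
- Decay is implicit: a node with all activators at zero has image 0.

Exhaustive attractor search iterates the synchronous map over all 3^K
states and is limited to K ≤ 12 (531,441 states); beyond that, sampled
trajectories from random initial states are used.

## Constraint-satisfaction inference

Every undirected interaction becomes two opposing directed candidates,
each with free (p, w, t). Constraints:

1. coupling: p = 0 ⇔ w = 0;
2. steady state, per node and per observed profile: observed 0 ⇒ drive ≤ 0,
   observed 1 ⇒ drive = 1, observed 2 ⇒ drive ≥ 2;
3. no sources or sinks: ≥ 1 active incoming and ≥ 1 active outgoing
   candidate per node (the closed-loop requirement is imposed on both
   directions, since either a source or a sink breaks loop membership);
4. ≥ 1 incoming candidate with p = +1 per node (a node with only
   repressors decays to 0 and could never hold a nonzero observed state).

Inactive candidates are canonicalized to t = 1 so the threshold of an
absent edge cannot manufacture spurious "distinct" solutions; the
per-candidate domain is then 9 admissible triples. Both orientations of
one undirected interaction may be simultaneously active, so reciprocal
regulation is representable.

The solver is a randomized backtracking enumerator written for this
package. Candidates are assigned grouped by target node; per-node drive
intervals (current partial sum plus the attainable range of unassigned
incoming candidates), in/out-degree reachability and activator
reachability are maintained incrementally and prune the search. Ensemble
sampling rests on two mechanisms: each model is found by a fresh search
with independently randomized variable and value orders (seeded from the
master seed), and all previously found assignments are blocked, so the
sampler touches different corners of the solution space and terminates
exactly when no further solution exists. On skeletons small enough to
enumerate, the sampler provably returns the complete solution set; this
is verified in tests against brute-force enumeration over all 9^6
assignments of a triangle skeleton. Every returned model is additionally
re-verified by the independent simulator (`ternary_dynamics.is_fixed_point`
on every constraint profile).

Solution-space size is reported in three conventions: 18 per candidate
ignoring the coupling constraint, 10 with coupling (threshold free), and
9 canonical. For a 25-interaction skeleton these give 10^62.7, 10^50 and
10^47.7 — order-of-magnitude figures for how underdetermined the problem
is before constraints are applied. No single convention reproduces every
published order-of-magnitude claim in this literature; the exact counts
are what `count_parameter_space` returns.

Ensemble summaries: per-parameter modal value and agreement fraction
(threshold 0.80 by default, inclusive); the representative model is the
member nearest the per-parameter centroid (Euclidean over the integer
parameter vector; Hamming optional; ties by ensemble order), with
inactive candidates dropped; the majority-vote network keeps candidates
whose modal polarity is nonzero (ties resolve conservatively toward 0,
i.e. no call).

## Network assembly

- **MI estimator.** Equal-width plug-in estimator on the unit square.
  The default grid is ⌈√n⌉ bins per axis; for small cohorts (n ≈ 60–70)
  where the data have three latent expression levels, 4 bins per axis is
  the recommended setting and is what the shipped analyses use — the
  plug-in bias grows as (bins−1)²/2n nats, and at √n bins it would rival
  the clinical-covariate MI itself. Natural log by default. A
  k-nearest-neighbour estimator (scikit-learn) is available behind
  `estimator="knn"`.
- **Null model.** Each of 50 iterations permutes every column
  independently and records all pairwise MI values; the pooled values
  form one null distribution. The pool must be large relative to the
  Bonferroni denominator: an edge can only pass p ≤ α/M if the pool has
  more than M/α values, which the 50-shuffle default guarantees for the
  relevant network sizes.
- **Otsu foreground threshold.** 256 equal-width histogram bins over the
  observed MI range; the returned boundary maximizes the between-class
  variance ω₀ω₁(μ₀−μ₁)² and is verified in tests against exhaustive
  search (ties from empty histogram bins are broken toward the smaller
  boundary). Edges at or above the boundary are foreground.
- **Significance.** Empirical p = (1 + #{null ≥ MI}) / (1 + |null|),
  Bonferroni-corrected with M = number of foreground edges.
- **Signal-to-noise.** MI ≥ 2 × mean(null), boundary inclusive.
- **Phenotype relevance.** The clinical covariate enters as a dedicated
  node with unit-ranged values and the same estimator; after filtering,
  proteins farther than 2 unweighted steps from it are dropped, and the
  phenotype node itself is removed.
- **Closed loops.** Iterative degree-≥ 2 pruning (the 2-core), which
  guarantees every surviving node can sit on a cycle; a single-pass
  variant is available. Protein-only degrees are counted (the phenotype
  node is already gone).

All steps only remove nodes/edges, and the whole assembly is
bit-reproducible under a fixed seed.

## Phenotyping

Discretization maps unit-range values onto thirds of [0, 1] with
half-open bands (top band closed); equal-count tertiles are an
alternative. Spectral clustering (k = 2, 2 eigenvectors, k-means
assignment) runs on an RBF affinity with the median-heuristic bandwidth
(symmetrized kNN connectivity optional). The Calinski–Harabasz index is
compared against a size-preserving permutation null; p-values are
empirical with the +1 correction. Cluster 0 is always the group with the
higher mean clinical covariate, for stable output ordering.
Representatives are the real subjects nearest (Euclidean, ties by input
order) their cluster's centroid in discrete space — real profiles, not
synthetic averages, so they are guaranteed to be realizable states.

## Synthetic scenarios

`synthetic_fixtures` generates ground truth the rest of the package can
be scored against. A random Hamiltonian cycle (directed, all-activating,
w = t = 1) guarantees the structural constraints; extra skeleton edges get
random orientation and parameters; candidates are rejection-sampled until
exhaustive search certifies ≥ 2 distinct fixed points (the two most
mutually distant are used as phenotypes). Abundances put each subject at
the band center (c + 0.5)/3 of their cluster's fixed point plus Gaussian
noise clipped to [0, 1]; with noise σ < 1/6 the default discretizer
recovers every state exactly. The clinical covariate is Normal(2.5, 0.5)
vs Normal(1.5, 0.5) events/year, truncated at 0 — a typical frequent- vs
infrequent-exacerbator contrast. Optional background proteins
(uniform(0, 1), phenotype-independent) emulate the unrelated proteome the
assembly pipeline must reject.

What the generator does *not* emulate: measurement error structure and
batch effects of LC-MS quantification, heavy-tailed abundance
distributions, correlated background proteins, and any within-cluster
regulatory heterogeneity. Passing tests therefore demonstrate internal
consistency (the pipeline recovers what its own model class generated),
not field performance on real proteomes.

Default scenario sizes used in tests and the acceptance script (5–8
nodes, 7–12 interactions, 60–68 subjects) are chosen so exhaustive
attractor search and full solution enumeration stay tractable while the
cohort dimensions mirror a realistic small clinical study.

## Numerical and degenerate-input conventions

- Constant abundance columns are an error (they cannot be unit-ranged).
- Missing abundance values are rejected by default; optional per-protein
  median imputation.
- Calinski–Harabasz returns +inf when within-cluster scatter is exactly
  zero with k > 1.
- Empirical p-values use the (1 + exceedances)/(1 + draws) convention,
  so they are never zero.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; set iteration never determines output
  order (sorted where needed), so results are independent of the process
  hash seed.

## Known limitations

- The steady-state constraint uses the two representative profiles only;
  within-cluster variability is not propagated into the inference.
- Consensus strength depends on how sharply the profiles constrain the
  skeleton; on small dense skeletons with few distinct observed states
  the ensemble legitimately stays diverse.
- Exhaustive guarantees (attractor search, completeness versus brute
  force) apply only up to the documented node/candidate limits; beyond
  them the sampler's coverage is heuristic, though soundness of every
  returned model is always verified.
- The literature-validation module consumes a pre-extracted reference
  table; it does not query databases, so its recall/PPV is relative to
  whatever reference is supplied.
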