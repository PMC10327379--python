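# Methods

## Model

The package treats a disease and a molecule as perturbations of the same
protein–protein interaction network and scores a molecule by how similar
the two perturbations are once they have spread through the network.

**Network.** An undirected graph with integer confidence scores in
[0, 999] per edge (the STRING convention). Reading an edge list merges
duplicate pairs by maximum score, drops self-loops (the node is kept), and
orders nodes lexicographically; identifiers are opaque strings, with no
namespace mapping. Thresholding keeps edges with score ≥ t and leaves the
node universe unchanged, so nodes may become dangling. The transition
operator divides each column of the weighted adjacency by its sum (entries
score(i,j)/Σₖ score(k,j)); dangling columns stay zero and are recorded. By
default the confidence scores act as edge weights; a `binary` mode treats
every retained edge as weight 1. Column-stochastic normalization was chosen
over symmetric degree normalization so that the propagation fixed point is
a probability distribution — an invariant every profile is checked against.

**Propagation.** Random walk with restarts:
p ← c·p₀ + (1 − c)·(W·p + m_d·p₀), where p₀ is uniform over the mapped
seeds, c ∈ [10⁻⁴, 1] is the restart probability and m_d is the probability
mass currently on dangling nodes, redirected to the restart vector so the
iterate stays exactly on the simplex. Two solvers compute the same fixed
point:

- `rwr` — power iteration, L1 tolerance 1e-6, at most 1,000 iterations by
  default; it errors with the final residual when it does not converge.
  The iteration contracts at rate (1 − c), so at the small end of the
  restart grid (c = 10⁻⁴, ≈ 1.4 × 10⁵ iterations to tolerance) it is not a
  practical choice.
- `make_rwr_solver` — exact solution via one sparse LU factorization of
  B = I − (1 − c)·W per (threshold, c) pair; the dangling term is a
  rank-one update handled in closed form (Sherman–Morrison), so every seed
  set costs a single triangular solve. The featurizer and the pipeline use
  this path; tests verify the two solvers agree to 1e-9 and that the power
  iteration matches a dense linear solve on random graphs to 1e-8.

At c = 1 the profile is the restart vector itself. On a path graph with an
*interior* single seed, profile mass decreases with hop distance for any
c ∈ (0, 1); for an *endpoint* seed this can fail at small c because the
column-stochastic stationary distribution weights nodes by degree — a known
property of this normalization, not an error.

**Features.** For each setting (t, c_d, c_m) of the grid — thresholds
(400, 600, 800), 24 disease-side and 30 molecule-side restart
probabilities log-spaced inclusive of both endpoints, 2,160 settings in
enumeration order thresholds-outer / c_d / c_m — the feature is the Pearson
correlation of the disease profile at (t, c_d) with the molecule profile at
(t, c_m), computed over the full node universe. Only the grid's total
cardinality and endpoints are externally fixed; the 3 × 24 × 30
factorization is this package's default and every axis is configurable.
Correlations enter the classifier untransformed. A constant profile makes
the correlation undefined and is treated as an error, since it signals a
degenerate propagation. Molecule targets pass a confidence cutoff of 200
(inclusive) first; molecules with no surviving, network-mapped target are
excluded and listed in the run report's attrition log rather than given
scores.

**Classifier.** One univariate logistic regression per setting, fitted
with class-balanced sample weights (weight n/(2·n_class)) and a weak ridge
penalty on the slope (λ = 1e-4, the intercept unpenalized — equivalent to
scikit-learn's `LogisticRegression(C=1e4, class_weight="balanced")`, which
the unit tests use as an independent cross-check). The fits are batched
across settings with a damped-Newton (IRLS) solver so that the
~10⁵ univariate fits of a nested-CV run cost seconds. The protocol:

- *Generalization*: 25 repeats of 5-fold nested stratified CV. Per outer
  fold, an inner 5-fold stratified CV on the training part alone picks the
  single best setting by mean balanced accuracy (ties → lowest
  grid-enumeration index); that setting is refitted on the whole training
  part and scored on the held-out fold with threshold 0.5. The summary is
  the mean ± sample standard deviation over all 125 fold scores. A spy
  test asserts the selection step never receives held-out rows.
- *Ensemble*: each setting's own balanced accuracy comes from a single
  5-fold stratified CV on the full labeled set; settings strictly above
  the nested-CV mean become members (refitted on all data). If none
  qualifies, the single best setting is used, with a warning.
- *Scoring*: a molecule's correlation probability (%) is the mean of the
  member probabilities × 100. The whole path is a pure function of
  (features, labels, random_state).

The member count and the CV accuracy are outcomes of the data, never
configuration constants.

**Enrichment.** Genes are ranked by the product of the disease and
molecule profiles (descending, ties broken by gene identifier). The
preranked GSEA statistic increments the running sum at in-set genes by
|score|^w normalized by the total in-set weight (w = 1 by default) and
decrements at misses by 1/(N − N_hit); the enrichment score is the signed
extremum, with an exact tie between the positive and negative extremum
(possible at w = 0) resolved toward the positive one within 1e-12. If every
in-set score is zero, hit increments fall back to uniform 1/N_hit. The null
permutes gene labels — equivalently, places the N_hit hits uniformly at
random — with nominal p = (1 + #{|ES*| ≥ |ES|}) / (n_perm + 1)
(n_perm = 1,000 by default, so the smallest attainable p is ≈ 1e-3). Sets
overlapping the ranking by fewer than 3 or more than 500 genes are flagged
untested. Only nominal p is reported (the selection rule is p < 0.001,
strict); FDR control is out of scope. A 500-trial simulation keeps the
null p-value distribution within Kolmogorov distance 0.1 of uniform.

## Synthetic benchmark

The generator emulates the statistical structure of the real inputs
without claiming biological realism:

- *Interactome*: a preferential-attachment graph (n_nodes = 300,
  attachment = 3 → exactly (n − m)·m = 891 edges, connected, heavy-tailed
  degrees) with integer edge scores uniform on [200, 999].
- *Disease module*: 25 nodes grown by breadth-first expansion from a
  random start. Within each BFS shell the expansion order is randomized;
  a fixed lexicographic order would systematically pull in the oldest and
  hence highest-degree nodes.
- *Molecules*: 30 positives, 150 negatives, 40 queries (half planted, half
  random, identities recorded), 3–8 targets each, target scores ≥ 200 so
  cutoff attrition is explicit. A planted target (probability
  overlap_prob = 0.9 for positives) is a one-step random walk from a
  uniformly chosen module node — stay with probability 1/2, else move to a
  uniform interaction partner. Its support is exactly the module's closed
  1-hop neighborhood, but the measure concentrates near the module; in a
  scale-free graph the closed neighborhood of a 25-node module covers
  roughly half the network, so sampling it *uniformly* would make positives
  nearly indistinguishable from random negatives. Negatives and random
  queries draw targets uniformly from all nodes.
- *Gene sets*: the disease module as a positive control plus random decoy
  sets of the same size.

Everything is deterministic given the scenario seed, and all emitted files
round-trip through the production readers. What passing recovery tests
show: the pipeline detects network-neighborhood overlap when it exists
(nested CV ≈ 0.9–1.0 balanced accuracy across seeds) and reports chance
(≈ 0.5) when overlap_prob = 0. What they do not show: performance on real
interactomes, whose score distributions, density, and annotation biases the
generator does not imitate.

## Problem sizes and numerics

Tests and the acceptance script run the benchmark at the default scenario
with the restart grids scaled to 6 × 6 per threshold (108 settings) — this
keeps a full nested-CV run under a minute while exercising every code
path; the 24 × 30 default remains the library default. Tolerances: profile
normalization 1e-9; column stochasticity 1e-12; iterative-vs-exact solver
agreement 1e-8; enrichment-score oracle agreement 1e-12. Tie-breaks are
deterministic everywhere (lowest grid index for settings, lexicographic
for genes and molecule ids). Reports round probabilities to one decimal in
the TSV and keep full precision in the JSON; outputs contain no timestamps
so a rerun with the same config is byte-identical.

## Known limitations

- The per-setting univariate reading of the classifier ignores
  correlations between settings; no multivariate combination is offered.
- Restart probabilities below ~10⁻³ make profiles nearly seed-independent
  (the walk forgets its restart vector), so those features carry little
  signal; they are retained for completeness of the grid.
- Class imbalance is handled only through balanced sample weights and the
  balanced-accuracy metric.
- Identifier namespaces are not reconciled; seeds or targets absent from
  the network are dropped with warnings.
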