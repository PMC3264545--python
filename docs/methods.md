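# Methods

## Network model and descriptive statistics

The analysis substrate is a simple undirected graph over opaque protein
identifiers: interactions are binary (unweighted) and symmetric, self-loops
and duplicate records — common artifacts of merged interaction databases —
are dropped at parse time with logged counts.  All per-protein indices are
computed on the giant component; ties between equal-sized components are
broken toward the component containing the lexicographically smallest
identifier so the choice is reproducible.

Density is 2m/(n(n−1)).  "Clustering coefficient" is ambiguous between
global transitivity (3·triangles / connected triples) and the mean of local
coefficients; the package computes transitivity by default and exposes the
mean-local variant under its own name (`mean_local_clustering`), because on
hub-dominated sparse graphs the two differ widely and silent substitution
is a classic source of irreproducibility.  Diameter and average path length
are defined only on connected graphs; on disconnected input they are
reported as null with a warning rather than silently restricted.

## The six centrality indices

Degree and eigenvector score describe the local scale; topological
importance at 1 and 4 steps the meso scale; betweenness and closeness the
global scale.  Conventions are pinned by the worked 9-node example that the
test suite locks in (all six printed values must hold simultaneously):

- **Betweenness** is raw (unnormalized) fractional geodesic counting over
  unordered pairs with endpoints excluded — the only convention giving the
  worked example's B = 19.
- **Closeness** is (n−1)/Σ<sub>j</sub> d(i,j) — the only convention giving
  C = 0.615.
- **Eigenvector score** is the dominant eigenvector of the 0/1 adjacency
  matrix (not of the effect matrix), max-rescaled to 1.  It is computed by
  power iteration on A + I: the unit shift leaves eigenvectors unchanged
  but makes the dominant eigenvalue strictly largest in modulus, so the
  iteration also converges on bipartite graphs (trees), where plain power
  iteration oscillates.  Convergence is certified on the eigen-relation
  residual max|Av − λv| < tol (default 1e−10).
- **Topological importance** composes one-step effects r<sub>1,ij</sub> =
  a<sub>ij</sub>/D<sub>i</sub> multiplicatively along walks and additively
  across walks, i.e. plain powers of the row-stochastic effect matrix;
  walks may revisit nodes and intermediate diagonal entries are not zeroed.
  This is the composition under which the m = 1 case reduces exactly to the
  sum of reciprocal neighbor degrees (the worked example's 1 + 0.25 + 0.33
  = 1.58); path-only variants differ in the third decimal at m = 4 on
  sparse graphs.  Row-stochasticity yields the conservation law
  Σ<sub>i</sub> φ<sub>q,i</sub> = n − trace(E<sup>q</sup>), hence
  Σ<sub>i</sub> TI¹<sub>i</sub> = n on any simple graph — asserted at
  machine precision in the tests.  TI is evaluated at m = 1 (short-range
  extension of degree) and m = 4 (roughly half the diameter of the target
  networks: meso-scale without saturating to the global indices).

All-pairs shortest-path quantities (betweenness, closeness, diameter,
average path length) are delegated to igraph for speed; the test suite
checks them against brute-force geodesic enumerators on every connected
graph with ≤ 7 nodes, and TI (m ≤ 3) against an independent recursive
walk-effect summation.

Before clustering, each index column is divided by its maximum so all six
live on [0, 1] ("max-1" normalization).  An all-zero column (possible for
betweenness on degenerate inputs) is left untouched with a warning rather
than divided by zero.

## Two-round model-based hub detection

Profiles are clustered with finite Gaussian mixtures.  Candidates are
every combination of covariance family and component count K = 1..20; each
candidate is fitted by EM with 10 seeded restarts and scored by
BIC = 2 logL − p·log n (mclust sign convention: larger is better; the
convention is declared in the output because BIC magnitudes are not
comparable across ecosystems).

**Candidate families.**  The default set comprises the per-component-volume
structures expressible in scikit-learn — spherical, diagonal, and full
(unconstrained ellipsoidal, the analog of mclust's VVV).  The
shared-covariance family ("tied", EEE) is implemented and selectable but
not in the default set: centrality tables contain thousands of
near-duplicate peripheral profiles next to a sparse central cloud, and a
single shared covariance gets pinned to the duplicate-heavy bulk scale,
whereupon the BIC-best tied fit degenerates into shattering the sparse
central region one protein per component.  The equal-shape ellipsoidal
family (VEV) has no scikit-learn counterpart; the contract is "BIC-best
within the declared candidate set", with the chosen family reported.

**Degeneracy screening.**  EM with a covariance ridge (reg_covar = 1e−6 on
the diagonal) never *fails* on singular configurations — it silently
returns collapsed components whose likelihood is inflated by the floor.
Selection therefore screens restarts individually and scores each candidate
by its best *non-degenerate* restart (best-of-restarts without screening
would systematically prefer collapse).  A fitted component is judged
collapsed when its covariance reaches within 10× of the ridge floor in an
eigen-direction while holding fewer than d + 1 effective points
(rank-deficient scatter), or in *every* direction regardless of size (a
point mass on exact-duplicate rows).  A candidate whose restarts all
collapse is skipped — the equivalent of an NA cell in an mclust BIC grid.
If every candidate collapses (e.g. a table of identical rows) the
least-complex collapsed fit is returned with a warning so degenerate inputs
still produce the obvious answer (one cluster).  As a scan heuristic, a
family's K-scan stops after 5 consecutive non-improving BIC values; the
BIC-in-K curves here are quasi-concave and spot checks across generator
seeds show identical selections with and without the early stop.

**Central-cluster selection.**  Components are ranked by the mean of their
six centrality means (ties: larger mean betweenness, then smaller size).
The round-1 "central set" is the union of all components scoring at least
half the top component's score, floored at `min_central_cluster`
(default 10) members: BIC-optimal mixtures frequently describe the central
tail with several adjacent components, and taking the top component alone
would return an arbitrary sliver of it.  The 0.5 ratio sits in the wide
empirical gap between central-tail components (≥ ~0.5× top) and bulk
components (≤ ~0.35× top) across generator seeds; it is a selection
heuristic, not a fitted constant.  Round 2 refits the mixture on the
central set alone and returns its single most central component as the hub
set.  If the central set cannot reach the minimum even after merging all
components (tiny tables), round 2 is skipped with a warning and the set is
returned directly.

Determinism: given the seed, the restart seeds, grid order and selection
are fully determined; permuting table rows leaves the hub set unchanged.

## Redundancy of the indices

Pairwise agreement between two index rankings is the Goodman–Kruskal gamma:
(C − D)/(C + D) over all unordered protein pairs, where pairs tied in
either ranking are excluded (classical strict-exclusion treatment; no
average-rank preprocessing).  The statistic is computed by direct sign
comparison over all pairs (O(n²) vectorized — 1.4M pairs for a
1,657-protein table is trivial).  Note the measure is reported as "lambda"
in parts of the applied network literature; the implemented statistic is
gamma — a signed concordance measure in [−1, 1] — since association tables
in this domain contain negative entries that the classical lambda (range
[0, 1]) cannot produce.  `gk_lambda` is kept as an alias.

The index dendrogram agglomerates the six indices (average linkage) on the
Euclidean distance between their association-matrix rows with the two
self/pair entries excluded, so two indices group when they relate to all
*other* indices alike — not merely when they correlate with each other.
The alternative dissimilarity 1 − score was rejected because it ignores
exactly that profile information.  Dendrograms export to Newick with merge
heights as branch lengths.

Four-index subsets are evaluated by re-running the two-round procedure on
the restricted columns and counting how many reference hubs land in the
final round's top one and top two components (components again ranked by
centrality mean) — mirroring the "1 cluster"/"2 clusters" bookkeeping used
when a restricted index set splits the hub group.

## Null models

Three reference families are matched to an input network: uniform G(n,m);
degree-preserving randomization by double edge swaps (attempted swaps =
10 × m; swaps creating loops or duplicates are skipped, so swap-free graphs
like stars return unchanged — the reason for a hand-rolled loop rather than
a library call that raises on exhaustion); and Watts–Strogatz small-world
graphs packing the same edge count onto ~40% of the nodes (668-node analog
for a 1,657-node network), hence strictly denser, with rewiring probability
p = 0.05 by default.  Per-model, per-replicate association matrices are
averaged entrywise and the dendrogram is built from the mean matrix.  All
generators emit simple graphs and are reproducible from the NullModelSpec seed.

## Annotation statistics

Vitamin labels follow the 13-class scheme (A, B1, B2, B3, B5, B6, B7, B9,
B12, C, D, E, K); the 6-class scheme folds the B complex together.  Fat-
soluble = {A, D, E, K}; water-soluble = the rest.  A protein carrying both
a fat- and a water-soluble association counts in both groups (logged), and
multi-vitamin proteins count once per associated class in enrichment
profiles — required for the profiles to be well-defined, with the
consequence that per-group proportions may sum above 1.

Chi-squared tests are Pearson with an optional Yates continuity correction;
because the conventional default differs between ecosystems, the pipeline
always reports corrected and uncorrected statistics side by side.  The
two-sample Kolmogorov–Smirnov test (asymptotic p) accepts arbitrary numeric
vectors; the pipeline feeds it per-class proportion vectors, which is a
statistically unusual but deliberate usage inherited from the analysis
tradition this package serves, and is documented as such.

## Synthetic data generator

The generator grows networks in the regime the pipeline targets, with
ground truth for recovery testing:

1. **Hub backbone** — n_hubs = 20 proteins wired pairwise with probability
   backbone_p = 0.4 under Chung-Lu-style per-hub weights (log-sd 0.25),
   components stitched to connectivity.  This is the assortative core:
   high-degree proteins linked to each other.
2. **Seed proteins** — 180 further "vitamin-protein" analogs, each
   attaching 1–2 links, 75% onto the hub core (following fixed per-hub
   lognormal attachment propensities, log-sd 0.35) and 25% onto earlier
   seeds: short branches off the backbone.
3. **Periphery** — 1,400 interactors attaching 1 + Bernoulli(0.6) links
   split 30/25/45% between hub core, seeds and earlier periphery (branch
   growth).

Defaults land at density ≈ 0.002, diameter ≈ 10, average path length ≈ 4.4,
giant component > 90% of nodes, and a degree–betweenness gamma > 0.8.  The
two independent axes of hub heterogeneity (attachment propensity vs.
backbone embedding) matter: they spread the planted hubs into a diffuse,
roughly Gaussian 6-D cloud — per-index spread comparable to real hub
groups — that is separated from the seed band yet free of the exact-
duplicate sub-blobs that would make the mixture fit collapse.  Annotations
give hubs the label "D" with probability 0.85 and the transcription-factor
flag with probability 0.8, against independent per-class background rates
of 0.12 and a background TF rate of 0.15; publication counts are log-normal
(μ = 3, σ = 1 on the log scale, median ≈ 20 papers).  Background rates are
the package's own choice of a realistic contrast; the enrichment margin they
imply is what the annotation tests assert.

What the generator does *not* emulate: experimental false positives and
study-bias (ascertainment) structure, overlapping protein complexes and
dense modules away from the hub core (real transitivity is slightly higher),
and correlated multi-label annotation patterns.  Passing recovery tests
therefore demonstrates that the procedure isolates a planted multi-central
assortative core under realistic sparsity — not that it is robust to every
failure mode of real interactome data.

## Numerical and reproducibility choices

- Floating-point comparisons in tests at absolute tolerance 1e−9 unless an
  explicitly printed-precision check applies; the worked example's TI value
  is compared at 0.01 (it quotes two decimals with 1/3 rounded to 0.33).
- All stochastic stages consume numpy `SeedSequence`-derived integers; the
  pipeline derives per-stage seeds as
  `SeedSequence([master_seed, stage_index])`, so stages can be re-run
  independently and a full run is byte-reproducible (asserted on the
  serialized report).
- Problem sizes in the test suite: clustering tests run on a reduced
  400-node / 10-hub scenario; the recovery acceptance check runs the full
  1,600-node default over 20 seeds; oracle equivalence is exhaustive over
  all 996 connected graphs on ≤ 7 nodes.

## Known limitations

- The equal-shape mclust families (VEV et al.) are not expressible in
  scikit-learn; model-family labels are therefore reported with approximate
  mclust aliases and BIC magnitudes are not comparable to mclust output.
- Whole-network acceptance checks against the originally deposited
  1,657-protein edgelist require that file to be supplied at
  `data/vitamin_ppi_edgelist.tsv`; it is not redistributable with the
  package.
- Gamma computation is O(n²) per index pair; fine to ~10⁴ proteins,
  quadratic beyond.
- The small-world null fixes edge count and lets the user choose the node
  count and rewiring probability; it is an interpretation of "same
  interactions on fewer nodes", not a unique construction.
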