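# Methods

## Scope and data model

persistnet analyses cohorts of per-subject structural connectomes given as
symmetric, nonnegative, zero-diagonal region-by-region fiber-count matrices
(tractography trace counts between parcellation regions). It does not touch
imaging data: registration, tractography and atlas construction happen
upstream. Region counts are arbitrary; 68 regions (a Desikan–Killiany-style
cortical parcellation) is the default cohort size, and nothing in the code
assumes it.

## Network construction

The default edge weight between regions *i* and *j* is one minus the Pearson
correlation of their fiber-connection profiles, where a profile is the full
*i*-th row of the count matrix (length *R*, self-entry a structural zero).
Weights live in [0, 2]; 0 means perfectly correlated profiles. Design
choices:

- **Profile definition.** Whether to drop entries *i* and *j* from both rows
  before correlating is genuinely open in the connectome literature; both
  behaviours exist behind `exclude_pair` (default off: full rows, simpler
  and symmetric). With exclusion, the effective profile length — and hence
  the degrees of freedom of edge significance tests — drops by 2.
- **Degenerate profiles.** A constant (zero-variance) row has no defined
  correlation. Default is a hard error naming the region;
  `on_degenerate='unit'` instead assigns weight 1 ("no association") to all
  its edges and logs the fallback.
- **Variants.** `spearman_1minus` uses average-rank rank correlation (1 −
  ρ); `pearson_abs` uses |r| (note: *high* = strong, range [0, 1]);
  `partial_1minus` computes partial correlations from the inverse of a
  shrunk covariance. The profile covariance of R variables observed over R
  entries is singular by construction, so shrinkage toward the diagonal is
  mandatory; the default intensity is 0.1 and is exposed. `direct` validates
  and passes through an externally formed association matrix (e.g.
  FA-weighted) — its construction from tracts is out of scope.

**Edge significance thresholding** (used only by the graph-theoretic
indices): each edge's correlation gets a two-sided p-value from the
t-transform *t* = *r*·√(df/(1 − *r*²)) with df = profile length − 2, and an
edge survives when *p* · *n*_tests < α with *n*_tests = R(R−1)/2 (Bonferroni,
α = 0.05 default). α ≥ 1 disables thresholding entirely — the natural
reading of "no correction bite" that also keeps the boundary case
well-defined. Surviving edges keep their original weights.

## Persistent features

The filtration threshold is **inclusive** (edges with weight ≤ λ): with the
strict reading, a merge at an event value would not be visible at that value,
contradicting the worked six-node example in which β₀ drops to 5 exactly at
the smallest MST weight. β₀ at λ is computed as *n* − #{MST weights ≤ λ};
correctness against direct component counting is property-tested.

The IPF admits more than one concrete formula consistent with its defining
properties (monotone decreasing, zero once the network is fully merged, total
remaining persistence). The default is the discrete form IPF(λ) = Σ{w ∈ MST
weights : w > λ}; the continuous alternative Σ(w − λ)⁺ is available as
`ipf_formula='continuous'`. Both are exposed because published uses of
integrated persistence differ in this choice; the discrete form is the
package default and all reported indices use it.

**Slope indices.** Each curve is reduced to |OLS slope| of value against
filtration value. The regression sample is the curve's own breakpoint pairs
(default) — deterministic, and exactly reproducible on the worked example
(BNP pairs (0,6), (0.1,5), (0.2,4), (0.4,2), (0.5,1) give Sxy/Sxx =
−1.72/0.172 = −10, index 10.0). A `sampling='grid'` mode evaluates the step
function at 101 uniform points over [0, λ_max] instead, which weights the
regression by how long each β₀ level persists and puts subjects with
different breakpoint sets on a common footing. Single-breakpoint (constant)
curves have index 0 by convention.

Degenerate/edge cases: disconnected inputs get a spanning forest per
component (logged) — the final β₀ exceeds 1 and IPF still ends at 0 once all
components have internally merged. Persistence is always computed on the
*original* weighted network, never the thresholded one: scanning all
thresholds is the point of the method.

Scaling behaviour (verified numerically in the tests): multiplying all
weights by *c* > 0 scales the BNP index by 1/*c* (breakpoints stretch,
values fixed) and leaves the IPF index invariant (values and breakpoints
both scale by *c*).

## Graph-theoretic indices

Computed on the Bonferroni-thresholded network. Weights serve double duty,
following each index's standard formula literally: as **lengths** for CPL
(mean shortest-path length over ordered reachable pairs; disconnected
networks average over reachable pairs only, logged) and GE (mean inverse
shortest-path length, 1/∞ = 0), and as connection **magnitudes** for NS
(mean row sum), CC, Mod and EC. That semantic tension is inherent to
dissimilarity weighting and is documented rather than "fixed";
`affinity=True` applies the 2 − w transform to the magnitude-based indices
for users who prefer affinities.

- **CC** is the geometric-mean triangle form averaged over all nodes, with
  weights normalised by the maximum surviving weight so CC ∈ [0, 1]; nodes
  of degree < 2 contribute 0.
- **Mod** is Newman's Q of the best partition found. The solver is exact
  (incremental set-partition enumeration) for networks of up to 10 nodes and
  greedy agglomeration (Clauset–Newman–Moore) above; both routes are
  deterministic, and the exact route exists because greedy agglomeration
  demonstrably misses the optimum on a non-trivial fraction of small
  unstructured graphs. Realistic networks always take the greedy path.
- **EC** is the entrywise-nonnegative principal eigenvector (dense
  symmetric eigendecomposition — no iteration/convergence concerns at these
  sizes) of the weight matrix on the largest connected component, unit
  Euclidean norm, summarised as the mean over all nodes with absent nodes
  contributing 0 (`summary='max'` available). Components tied in size break
  toward the one containing the lowest node index.

## Group statistics

Per index: a tie-corrected Kruskal–Wallis omnibus test across all groups
(χ² p-value, k − 1 df; all-identical values degrade to H = 0, p = 1), and a
two-sided permutation test of the group-mean difference for every unordered
pair. The permutation p uses add-one smoothing, p = (1 + #{|Δ*| ≥ |Δ|}) /
(1 + n_perm), with n_perm = 10,000 by default; when n_perm covers all
C(m+n, m) distinct splits the test switches to exact enumeration (no
smoothing). Tail comparisons use a 1e−12 absolute guard against float
round-off. Pairwise seeds are derived deterministically from the base seed
and the comparison label, so any single row of the comparison table can be
reproduced in isolation. Significance is *reported* (flags at α = 0.05
pairwise, 0.01 omnibus) and never used to filter; no multiple-testing
correction is applied across indices or contrasts by default (a
Bonferroni-across-comparisons option exists).

## Synthetic cohort generator

The generator emulates group-structured fiber-count cohorts with a two-level
stochastic block model: regions fall into `n_modules` contiguous modules
(default 4), within-module pairs expect `within_mean` = 100 traces,
between-module pairs `between_mean` = 20 (order-of-magnitude plausible for
per-pair probabilistic-tractography trace counts with a few thousand seeds).
Counts are Poisson per upper-triangle entry, mirrored (the
`lognormal` noise model adds mean-preserving multiplicative noise instead,
and its σ = 0 limit returns the expected-count matrix exactly, which the
tests use as the deterministic mode).

**Disconnection severity δ ∈ [0, 1]** (defaults AD 0.6, MCI 0.3, NC 0.0)
models degeneration as:

1. collapse of the within-module surplus: E[count] = between + (within −
   between)·(1 − δ), and
2. thinning of between-module fibers: E[count] = between·(1 − κδ), with
   κ = `between_attenuation` = 0.5 (κ = 1 gives pure between-module
   thinning).

Mechanism (1) carries the phenotype: strong within-module profile
correlations weaken, pushing component merges to higher filtration values
while the between-module bridges — already near the weight ceiling — barely
move. Merges compress into a narrower, later band of weights, which (a)
raises β₀ at most λ (more segregation) and (b) steepens both persistence
curves, raising the IPF/BNP indices in the severity order AD > MCI > NC.
Pure between-module thinning alone does the opposite on both counts —
removing shared background makes within-module profiles *more* similar and
stretches the filtration axis — which is why it is not the default
mechanism.

What the generator does **not** emulate: spatial geometry and tract lengths,
hemispheric symmetry, hub/rich-club structure, inter-subject variability in
module layout, and measurement artefacts of registration or tractography.
Passing tests therefore demonstrate that the pipeline detects the modelled
disconnection phenotype, not that it reproduces effect sizes on real imaging
cohorts.

Determinism: a cohort is a pure function of its `CohortSpec` (including
seed); identical specs regenerate byte-identical cohorts, and the pipeline's
output tables are byte-identical across reruns of the same config.

## Problem sizes used in the validation suite

The test suite exercises: the six-node worked example; ≥ 100 random graphs
of up to 12 nodes against brute-force component counting; exhaustive
spanning-tree and partition enumeration up to 6–8 nodes; permutation-test
calibration with 2000 null replicates at 500 permutations; and 50 replicate
cohorts of 3 × 30 subjects at 68 regions for the qualitative severity
ordering. These sizes keep the full suite to well under a minute of compute
apart from the replicate-cohort check (~25 s) while leaving every check
statistically meaningful.

## Known limitations

- Only zeroth homology (components); no higher-dimensional features
  (cycles/voids), persistence diagrams or dendrograms.
- Global indices only; no nodal/regional reporting, small-world σ or hub
  statistics.
- The edge p-values assume the t-distribution of a correlation coefficient
  over independent observations; profile entries are not truly independent,
  so the Bonferroni threshold is a pragmatic de-noising rule, not a
  calibrated test (the same pragmatism applies in the field's standard
  toolchain).
- Partial-correlation networks depend on the shrinkage intensity; no
  data-driven selection is attempted.
- Cross-sectional only; no longitudinal modelling.
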