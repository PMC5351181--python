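# Methods

`imbforest` implements a pipeline for imbalanced binary (and, for the
optimizers, multiclass) tabular classification: minority-class oversampling
guided by CURE clustering, a from-scratch CART random forest with
out-of-bag (OOB) accounting, and three binary-encoded metaheuristics that
jointly choose a feature subset and the forest parameters by minimising OOB
error. This note records the models, the parameter choices, the numerical
conventions, and what the synthetic-data experiments do and do not show.

## Oversampling model

All seven samplers share one contract. Let the imbalance ratio be
IR = n_minority / n_majority. Synthetic minority rows are appended one at a
time, and generation stops as soon as IR strictly exceeds the target IR₀
(default 0.7), evaluated after every point. Every synthetic row is a convex
combination of two points,

    x_new = x_origin + rand · (x_anchor − x_origin),  rand ~ U(0,1),

and the triple (origin, anchor, rand) is stored as a provenance record, so
each synthetic row is reproducible bitwise. What differs between methods is
how origin and anchor are chosen:

| method       | origin                          | anchor                               |
|--------------|---------------------------------|--------------------------------------|
| random       | uniform minority row            | itself (rand ≡ 0: duplication)       |
| smote        | round-robin over minority       | one of its k nearest minority pts    |
| borderline1  | "danger" minority points only   | one of its k nearest minority pts    |
| safelevel    | round-robin over minority       | k-NN minority pt; gap biased safe    |
| csmote       | uniform minority row            | minority mean                        |
| kmeans       | minority row, cluster-weighted  | k-NN within its k-means cluster      |
| cure         | retained (non-noise) minority   | a shrunk CURE representative         |

Neighbourhood sizes follow the usual settings for these methods: k = 5
interpolation neighbours and an m = 20 all-class neighbourhood for the
borderline/safe-level classification. Borderline-SMOTE1 classifies a
minority point by the majority count k′ among its m nearest neighbours in
the whole set: k′ = m is noise (excluded), k′ < m/2 is safe (excluded),
m/2 ≤ k′ < m is danger (the generation base); when no danger point exists
the sampler falls back to plain SMOTE with a warning. Safe-level SMOTE
computes sl(x) = minority count among the m nearest neighbours and draws the
gap by the five-case scheme documented in `SafeLevelSmote` (skip when both
safe levels are zero; duplicate the origin when only the neighbour's is
zero; otherwise a uniform gap confined toward the safer endpoint).
k-NN distance ties break toward the lower row index via stable sorts, which
makes every sampler a pure function of its seed.

The embedded k-means (for `KMeansSmote`) is seeded Lloyd iteration with
initial centres drawn from the minority points, a 100-iteration cap, a
relative centre-shift tolerance of 1e-6, and emptied clusters reseeded to a
random point. Singleton clusters duplicate their point.

## CURE clustering and CURE-SMOTE

CURE agglomerates the minority class from singletons, always merging the
pair of clusters with the smallest representative-to-representative
Euclidean distance. A merged cluster's centroid is the size-weighted mean
of its parents' centroids; its representatives are re-selected
farthest-first from the member points (first the point farthest from the
centroid, then iteratively the point maximising the minimum distance to the
chosen set), capped at `num_rep` = 15, and shrunk toward the centroid by
α = 0.5: p ← p + α(Uc − p). Representatives are recomputed exactly at each
merge rather than updated incrementally — the minority classes this is
applied to hold tens to hundreds of points, so exactness costs little.
Distance ties break toward the lowest (cluster-id, cluster-id) pair, with
ids assigned in input order and then in merge-creation order; the nearest
pair is tracked with a lazy-deletion heap, which produces the identical
merge order to a full rescan (asserted against a brute-force reference).

Noise removal is two-stage. During merging, a cluster that holds less than
`small_cluster_fraction` (default 1/(10c)) of the points and has not
participated in a merge for `stall_rounds` = 10 rounds is removed. This
stall rule arms only once the cluster count has fallen to a third of the
point count, with stagnation counted from that moment: earlier, a tight
blob still contains legitimate singletons that are merely awaiting their
turn, and removing them would shred the blob (this activation point mirrors
CURE's own two-phase outlier handling). After the merge loop, clusters
below the same size threshold are also removed. If everything is removed,
the clustering reports no clusters and CURE-SMOTE raises rather than
interpolating from nothing.

CURE-SMOTE min-max normalizes the whole dataset first (constant columns map
to 0, not NaN, to keep distances finite), clusters the minority class,
drops the noise indices from the generation base, and interpolates between
a uniformly drawn retained minority point and a uniformly drawn
representative of that point's cluster. All representatives of the cluster
are eligible anchors (the anchor actually used is recorded in provenance).
Because representatives are shrunk toward the centroid, synthetic points
stay inside the convex hull of the retained minority points — the mechanism
by which boundary noise does not spawn synthetic neighbours. The output
stays in normalized space (downstream classification happens there), and
the sampler exposes the fitted bounds so held-out data can be mapped into
the same space.

## CART random forest

Each of `n_trees` trees is grown on a bootstrap of the training rows. At
every node a fresh uniform subset of κ features is drawn without
replacement from all M features; the best split minimises the size-weighted
Gini impurity over thresholds at midpoints between consecutive distinct
sorted values. Branches stop at purity, depth 20 (default), `min_leaf` = 1,
or when no valid split exists; `min_leaf` defaults to 1 because forest
performance is comparatively insensitive to it. Prediction is majority
voting with ties to the lexicographically smallest class label. A
"depleting" per-tree feature budget (removing used features from later
nodes) is deliberately not implemented: per-node independent draws are the
standard random-subspace semantics.

Split scores are compared as exact integer fractions
(n·gini_w = (nl²nr − sl·nr + nr²nl − sr·nl)/(nl·nr) with sl, sr the sums of
squared class counts): on small nodes score ties are common, and float
rounding would otherwise scramble the documented lowest-feature /
lowest-threshold tie rule. The tree-growing and traversal loops are
numba-compiled; a pure-Python `best_split` with the identical rule is the
reference the jitted kernel is tested against.

Two OOB estimates are exposed. `oob_error_` is the per-tree average: each
tree's misclassification rate on the rows absent from its bootstrap,
averaged over trees. This is the quantity the optimizers minimise.
`oob_error_aggregate_` is the conventional aggregate-vote estimate (predict
each row by the trees not trained on it). Trees with an empty OOB set —
probability (1 − 1/N)^N ≈ e^{-N/e...}, negligible for N ≥ 20 — contribute
error 0 with a warning. The ensemble margin is the mean over samples of
(vote fraction for the true class) − (largest other-class vote fraction).

## Hybrid optimizers

The chromosome is 9 bits of nTree ∥ bit_length(M) bits of κ ∥ M mask bits.
Validity requires 1 ≤ nTree ≤ 500 (9 bits decode 0–511; 0 and >500 are
rejected — a 0-tree forest is undefined), a non-empty mask, and
1 ≤ κ ≤ popcount(mask). Initial solutions are rejection-sampled uniformly;
during search, an invalid chromosome has its offending block redrawn
(bounded retries, then a targeted uniform repair), so validity is a loop
invariant. The objective f is the forest's per-tree-average OOB error
(aggregate-vote misclassification for multiclass) on the masked features;
fitness is F = 1/max(f, 1e-6), the ε guarding f = 0. The forest seed is
held fixed within an optimizer run (common random numbers): with a
population of 5, unpaired re-randomised fitness comparisons would be
noise-dominated. Objective values are cached per bit string.

Shared defaults: popsize 5, maxgen 20.

**GA** (Pc = 0.6, Pm = 0.1): roulette selection with p_i = F_i/ΣF_i;
single-point crossover at a uniformly chosen position where the parents
differ (identical parents pass through); bit-flip mutation applied per bit
at rate Pm, with the draw regenerated until valid; generational replacement
with one-elite preservation. Two choices here were open: a reading in which
mutation flips a single bit per individual was tried first and recovers the
8-bit surrogate optimum (below) in well under half of seeded runs — with a
population of 5 it cannot maintain exploration — so the per-bit rate plus
elitism was adopted.

**Binary PSO** (c1 = c2 = 1.5, w = 0.5): per-bit velocities
v ← wv + c1 r1 (pbest − x) + c2 r2 (gbest − x) with per-dimension uniform
r1, r2; each bit becomes 1 with probability sigmoid(v). The stated velocity
range −0.5:0.5 is applied as the *initialization* range. Clamping v to
±0.5 on every iteration would confine all bit-flip probabilities to
[0.38, 0.62], reducing the search to coin-flipping; with w < 1 the
unclamped dynamics are in any case bounded by (c1+c2)/(1−w) = 6. An
optional hard clamp (`v_clamp`) is available.

**AFSA** (visual 3, try_number 5, delta 0.618): vision is a Hamming ball of
radius `visual`. For each fish, the swarm move (toward the neighbourhood's
per-bit majority centre, ties keeping the fish's own bit) and the follow
move (toward the best neighbour) are both attempted when their crowding
conditions F_target/nf > delta·F_i hold; moving keeps agreeing bits and
redraws differing bits with a fair coin; the fitter of the two outcomes is
kept. Otherwise the fish preys: up to `try_number` random valid states
within the visual radius, moving toward the first improvement, else a
random step. The global best over every evaluated state is retained.

## Synthetic data

`make_circle_data` emulates a 2-D imbalanced geometry: the majority class
uniform on the annulus with radii 0.5–1.0, the minority in one or two
interior Gaussian clumps (σ = 0.1, truncated at 3σ so each clump has a
bounded radius), plus optionally scattered minority noise points over the
annulus. Defaults give 113 majority / 23 minority (IR ≈ 0.2).
`make_informative_gaussian` draws two standard-normal classes whose means
differ by `effect_size` on the first `m_informative` coordinates only
(defaults: 3 informative, 7 noise, effect 2.0, 150 rows per class), and
records the informative index set in metadata.

These generators reproduce the *structure* the methods target — interior
minority clumps with outliers, and a known informative subspace under an
exact imbalance ratio — not the marginal distributions, feature
correlations, label noise or mixed types of real clinical/UCI tables.
Passing tests therefore demonstrate mechanism (noise exclusion, boundary
behaviour, feature recovery), not expected performance on any particular
real dataset.

## Experiment drivers and problem sizes

The oversampler benchmark repeats: stratified 3:1 split → oversample the
training side → 100-tree forest → F-value, G-mean, AUC on the held-out
side and OOB on the (augmented) training side, averaging over R repeats
(default 100; the test suite and validation runs use R between 1 and 20
per seed, which suffices for the directional comparisons they make). The
per-class train count is floor(0.75·n_c + 0.5) with an adjustment pass so
the total equals floor(0.75·N + 0.5). OOB is computed on the forest as
trained, i.e. after oversampling. The hybrid driver compares the fixed
baselines κ ∈ {1, ⌊√M⌋, ⌊log₂M + 1⌋, M} at nTree = 100 on all features
against the three optimizers, reporting OOB, margin, stratified 4-fold CV
accuracy, and the chosen (nTree, κ, feature count). The feature-recovery
study uses 20 seeded runs of each optimizer on the default Gaussian
fixture; all randomness descends from one master seed and per-repeat seeds
are logged.

## Degenerate inputs and conventions

Zero-denominator metrics return 0 with an `undefined` flag rather than
raising, so degenerate classifiers score worst instead of aborting a sweep.
AUC is trapezoidal with tied scores grouped and equals the normalised
Mann–Whitney statistic; constant scores give 0.5. Minority classes smaller
than k (or than the cluster count) reduce the parameter with a warning; a
single minority point degenerates SMOTE-family interpolation to
duplication. Multiclass imbalance ratio is min/max class size, reported but
not consumed by the (binary) samplers.

## Known limitations

- The forest is exact but desk-scale: no presorting across nodes, no
  parallel tree growth; hundreds of features × thousands of rows will be
  slow.
- CURE is applied in-memory to the minority class only; the published
  large-scale machinery (sampling, partitioning) is out of scope.
- The AFSA neighbourhood metric (Hamming) and the PSO velocity-range
  reading are documented choices where the underlying descriptions are
  silent; both are validated against exhaustive surrogate optima rather
  than derived.
- Optimizer results with popsize 5 and maxgen 20 are intentionally cheap
  searches; they find good, not certified-optimal, parameter combinations.
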