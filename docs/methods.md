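# Methods

## Model

`mcpnet` treats a reconstructed gene network as a weighted graph whose
edge weights quantify pairwise statistical dependence between
expression profiles.  Two network types are supported:

* **GCN** (gene co-expression network): undirected; the weight matrix
  W is square, symmetric, non-negative, with a zero diagonal.
* **GRN** (gene regulatory network): directed from regulators (TFs) to
  targets; W is rectangular, rows indexed by TFs.

Negative weights (e.g. anti-correlation) are replaced by their
magnitude on load: the method ranks interaction *strength* and is
agnostic to sign.  The diagonal is forced to zero — self-dependence is
the profile's entropy, which would otherwise dominate every capacity
computation without carrying network information.

### Path capacities and the MCP score

The capacity of a length-L walk is its minimum edge weight; the L-path
capacity η^L_st is the best capacity over all length-L walks from s to
t.  Walks may revisit vertices, including s and t: closed loops model
regulatory feedback, and permitting repeats is precisely what makes
the recursive bisection

    η^L = η^h ⊗ η^(L−h),  h = ⌊L/2⌋,

exact (a shorter walk of length h can always be padded to length L by
repetition, so composing the two half-problems loses nothing).  Here ⊗
is the max-min matrix product, associative because max and min
distribute over each other.  Bisection reduces the naive
O(|V|^(L−1))-per-pair enumeration to O(log L) cubic products; the
enumeration survives as `brute_force_eta`, the testing oracle
(guarded to |V| ≤ 12, L ≤ 6).

The MCP score ρ^L = W/η^L compares direct to best-indirect strength.
Conventions, chosen for consistent AUPRC ranking semantics:

* 0/0 → 0 (no evidence either way, ranked last),
* positive/0 → +∞ (a direct edge with no indirect route of that
  length — maximally kept, ranked first),
* self-pairs are unscored (set to 0) in every score matrix, but η
  matrices retain their diagonal internally: closed walks such as
  t→i→t are legitimate sub-walks of longer recursions.

Intermediate η diagonals therefore may be nonzero even though W's
diagonal is zero; only final score diagonals are zeroed.

The DPI filter removes edges with `0 < W_st < (1−tolerance)·η²_st`;
the tolerance is applied multiplicatively, and at tolerance 0 the
removal set coincides exactly with {ρ² < 1}.

In GRN mode the indirect route is constrained to L−1 TF–TF hops
followed by one TF–target edge (targets never act as intermediaries):
η_grn(L) = η_tt(L−1) ⊗ W_tg.  The alternative decomposition — one
TF–target edge followed by gene–gene hops — is served by running GCN
mode on the full gene set.

### Ensemble score

M = W / (Σ_k a_k η^{L_k}) with convex weights a_k.  The default term
set is lengths (1, 2, 3, 4) — including a direct term a₁ on η¹ = W, so
one-hot vectors reproduce every single-length network and the constant
score 1 at direct edges — configurable down to the strict
indirect-only form (2…L).  Weights are found by exhaustive search over
all lattice compositions of 1.0 (spacing `interval`, default 0.1;
C(13,3) = 286 vectors for four terms), maximizing AUPRC on the
training groundtruth.  The search is deterministic: grid in
lexicographic order, ties broken toward the lexicographically smallest
vector.  No off-lattice refinement is attempted.  Because scores enter
AUPRC only through their ranking at labelled pairs, the optimizer
evaluates candidates on those pairs directly; the returned optimum is
identical to full-matrix evaluation (asserted in tests).

### Stouffer transform

CLR-style background correction: infinities are clipped to the largest
finite entry; per-row and per-column z-scores are computed over
off-diagonal entries with the population σ (z = 0 where σ = 0),
clamped at 0, and combined as (z_row + z_col)/√2.  The transform is
invariant under affine rescaling aM + b (a > 0) of the score matrix.

### AUPRC

Average precision with tie grouping: labelled pairs only, ranked by
score descending with +∞ first; one precision–recall point per
distinct score value; AP = Σ over positives of the precision at that
positive's tie group / n_pos.  No interpolation — the convention is
deterministic and exact under ties, and the area is reproducible from
the returned curve as Σ Δrecall·precision.

## MI estimation

Profiles are rank-transformed within each gene (rank k of n maps to
(k−0.5)/n, ties averaged), which makes the estimator invariant under
strictly monotone transforms and removes marginal shape.  MI is then
estimated by Darbellay–Vajda adaptive partitioning of the unit square:
a cell is quadri-sected at the conditional medians of its points while
a chi-squared test (3 df) on the four quadrant counts rejects
uniformity at significance `significance` (default 1e-4).  Cells with
fewer than `min_cell` = 8 points are never split.  Cells with more
than 4×`min_cell` = 32 points are *always* split: the quadrant test
has little power against smooth density gradients in heavily populated
cells (the conditional-median split re-balances both marginals, which
masks exactly those departures), and without forced refinement the
estimator retains a large negative bias under strong dependence.  MI
is accumulated over final cells as Σ (n_c/n)·ln(n·n_c/(n_x·n_y)) with
global marginal interval counts n_x, n_y, clamped at 0.

Calibration measured by the acceptance suite: for bivariate Gaussians
at n = 5000 the estimate is within ±0.1 nats of −½ln(1−r²) for
r ∈ {0.3, 0.6, 0.9} (mean over 20 seeds), and independent uniforms at
n = 2000 score below 0.05 nats.  At small n (≲ 200, typical per-pair
sample counts) the estimator underestimates MI substantially; this is
inherent to partition estimators and harmless downstream, where only
the ranking of pairs matters.  Exact symmetry mi(x,y) = mi(y,x) is
guaranteed by canonicalizing the argument order internally.

## Synthetic data generator

`make_planted_weights` emulates the statistical structure the MCP
score exists to exploit, not a biophysical simulation:

* true edges: weights ~ Uniform(0.6, 1.0);
* decoys: a `chain_frac` fraction of the non-edges joined by a
  two-edge chain of true edges; their weight is the chain's bottleneck
  × Uniform(0.7, 0.95), modelling data-processing-inequality leakage —
  dependence transmitted through a chain cannot exceed its weakest
  link.  Decoy weights therefore overlap the true-edge range (so a raw
  weight ranking is fooled) while every decoy has ρ² < 1 by
  construction;
* remaining non-edges: |Normal(0, noise_sd)| background.

Groundtruth: positives = true edges; negatives = decoys plus an
equally sized uniform sample of noise pairs.  Defaults (40 genes, 60
edges, chain_frac 0.5, noise_sd 0.05) are the study conditions of the
acceptance suite.  `simulate_expression` generates a linear-Gaussian
system over the true edges only (each edge oriented by insertion
order, which also yields an acyclic evaluation order; roots N(0,1),
children = weighted parent sum + N(0, noise_sd)), so decoy-pair
dependence arises mechanistically through shared neighbours rather
than by construction.

What passing these tests does *not* show: robustness to the mixed
noise families, saturation effects and non-linear kinetics of real
expression compendia, to single-cell sparsity, or to groundtruth that
is biased toward well-studied regulators.  The generator's decoys are
exactly two-edge leaks; real indirect dependence spans longer and
mixed path types.  A known failure mode of the ratio score is visible
in the generator too: noise pairs with tiny weight and no strong
indirect route can score ρ ≈ 1 (tiny/tiny), occasionally outranking
weak true edges.

## Parallelism and determinism

Score matrices are assembled tile by tile (default 64 rows); each tile
is a pure function of its index ranges, evaluated by a thread pool
(numpy kernels release the GIL).  Max/min arithmetic is
order-independent, so outputs are bit-identical for any tile size and
worker count — asserted down to file checksums by the pipeline tests.
Distributed (multi-node) execution is out of scope.

All stochastic operations (splits, generators, the robustness
experiment) take explicit integer seeds; derived seeds come from
`numpy.random.SeedSequence` so nested loops are reproducible and
independent.

## Numerical conventions and limits

* TSV everywhere: tab-separated, UTF-8, `.` decimal; dense matrices
  carry an empty first header cell; edge lists are headerless
  3-column; +∞ serializes as the token `inf`.
* GCN inputs are sanitized on load: |·|, symmetrized by elementwise
  max (conservative — keeps the strongest direction; warns if the
  asymmetry exceeds 1e-12), zero diagonal.  An undirected edge listed
  once in an edge list implies its mirror; absent pairs are weight 0.
* Groundtruth splits are stratified by label, rounded half-up, and
  clamped so both halves keep at least one pair per label; strata with
  fewer than two pairs are rejected.
* The brute-force oracle and the |V| ≤ 12 guard bound the exact-
  equivalence tests; problem sizes in the test suite (≤ 40 genes,
  ≤ 5000 samples per MI pair, 10–20 replicate seeds) were chosen so
  the full suite and the acceptance script each complete in well under
  a minute on one CPU.
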