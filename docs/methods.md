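# Methods

## Model

The predictor is ε-insensitive support vector regression on a convex
combination of pathway kernels. For P gene sets mapped onto the columns
of a standardized expression matrix, each set m defines a Gaussian kernel

    K_m(i, j) = exp(−‖x_i,m − x_j,m‖² / (2σ_m²))

on its sub-profiles x·,m, with width σ_m equal to the mean Euclidean
distance over all unordered pairs of training samples on that
sub-matrix (self-pairs excluded; ordered vs unordered makes no
difference to the mean). Widths are estimated once per training set and
reused for the test-vs-train cross-kernels, so test data never influence
the model. Beyond the Gaussian's unit diagonal, kernels are not
centred, trace- or Frobenius-normalized.

The combined kernel is K_η = Σ_m η_m K_m with η on the unit simplex.
Training alternates two exact steps until the weights settle:

1. solve the SVR dual QP on K_η for (α⁺, α⁻);
2. update η_m ∝ η_m √(αᵀK_mα) with α = α⁺ − α⁻, renormalized to the
   simplex.

Step 2 is the closed-form minimizer of the block-norm (group-Lasso) form
of the regularized objective at fixed coefficients, so each step can
only lower the joint objective: the sequence of per-iteration primal
optima is non-increasing. Because the dual QP is stated as a
minimization, its optimal value mirrors this with the opposite sign —
the recorded `objective_trace` is the primal optimum (−dual value), the
quantity that decreases. The nested problem is nonconvex jointly in
(η, α), so the alternation reaches a local optimum; this matches the
method's design, which trades global optimality for exact, convex
inner steps.

## The dual solver

The 2N-variable QP (box constraints, one equality constraint) is solved
by sequential minimal optimization with second-order working-set
selection: at each step the maximally KKT-violating pair of variables is
chosen (the second member by largest guaranteed objective decrease) and
the two-variable subproblem is solved in closed form. Termination is
controlled by the maximal KKT violation (default 1e−8). A ridge jitter
of 1e−10 on the kernel diagonal guards against semidefinite kernels.
Warm starts are used across η-updates — the feasible set does not depend
on the kernel — which cuts inner iterations by an order of magnitude in
the alternation. Round-off is cleaned at exit: coefficients are clipped
to [0, C] and the overlap min(α⁺, α⁻) is subtracted so complementarity
holds exactly.

The intercept comes from the KKT conditions: every free support vector
(0 < α < C, tolerance 1e−8) pins b via its tube-boundary equation; their
values are averaged. With no free support vector the inequality
conditions leave an interval for b; its midpoint is taken. With an
all-zero α (tube wider than the response range) that interval is
[max(y−ε), min(y+ε)].

Accuracy is established in the tests against two independent routes: a
brute-force dense QP solve (SLSQP run to ftol 1e−14) for the objective
and coefficients, and libsvm (`sklearn.svm.SVR` with a precomputed
kernel) for fitted values and intercept.

## Parameters

| parameter | default | meaning |
|---|---|---|
| C | tuned | box bound on dual coefficients; larger C fits harder |
| tube multiplier | tuned | ε = multiplier × SD (N−1 denominator) of the *current* training responses, recomputed per CV fold and per replication |
| C grid | 10⁻³ … 10⁺³ (7 decades) | CV sweep |
| multiplier grid | 0, 0.25, …, 2 (9 values) | CV sweep |
| CV folds | 4 | inner cross-validation on the training split |
| MKL iterations | 200 max | alternation typically settles in tens; early stop when ‖Δη‖₁ < 1e−6 |
| selection threshold | 0.01 | sets with final η above it form the selected model |
| solver tolerance | 1e−8 | maximal KKT violation at termination |
| η floor | 1e−12 | weights below it snap to exactly 0 (absorbing state of the multiplicative update) |

Responses are tumour volumes (length × width × depth from clinical
tables; rows with missing dimensions or non-positive products are
dropped), cube-root transformed so the target returns to a linear
scale. Responses are *not* standardized — the tube-width multiplier
construction plays that role. Features are z-scored with training-split
statistics (sample SD, N−1); zero-variance training features map to 0.
Replication r of the 80/20-split protocol uses seed base_seed + r.

## Numerical choices and degenerate inputs

- Grid-search ties break toward the smallest C, then the smallest
  multiplier: the most regularized model among equals.
- αᵀK_mα < 0 from round-off is clamped to 0 before the square root.
- If every dual coefficient is zero (tube covers all responses) the
  η-update denominator vanishes; the fit keeps the current weights,
  returns the constant-intercept model, and warns.
- A gene set matching no expression column is dropped before kernel
  construction (warned); one whose sub-matrix is constant across
  samples would give σ = 0 and receives a fallback width of 1.0, making
  its kernel the all-ones matrix — harmless inside a convex combination.
- Gene-to-column matching is exact and case-sensitive; no alias
  resolution, since silent aliasing would change partitions.

## Synthetic cohorts

The generator emulates the *shape* of a bulk expression study, not its
marginal distributions. Genes within a set share an exchangeable
correlation of 0.5 through a per-set latent factor (sets independent;
genes outside all sets i.i.d.); this mimics strong within-pathway
co-expression while keeping set identity crisp. Each informative set
contributes a Gaussian radial bump of its sub-profile around a randomly
drawn center, with bandwidth set to the root-mean-square distance of the
samples from that center so the bump varies across the cohort. The
summed signal is standardized to unit SD, Gaussian noise added (default
SD 0.5, i.e. half the signal SD), shifted by +3 to be positive, and
cubed into volumes — the pipeline's cube-root then recovers a
well-scaled target near 3 ± 1.

The default study conditions are N = 150 samples, D = 600 genes, P = 20
disjoint sets of 30, sets 1–2 informative. The recovery study runs 10
such cohorts at fixed hyperparameters C = 10 and tube multiplier 0.5 —
values in the middle of the CV grids that a cohort of this size and
noise level supports — rather than re-running the full 7 × 9 × 4-fold
sweep per cohort; the sweep protocol itself is verified separately by
instrumented tests. The paired tumour/normal mode draws normal tissue
from the expression model and adds a per-gene mean shift plus
independent noise for the tumour copy, planting known regulated genes.

What passing these simulations does *not* show: robustness to RNA-seq
count noise (no negative-binomial sampling, library sizes or FPKM unit
fidelity), to heavy-tailed or skewed expression, to correlated noise
between sets, or to misspecified gene-set collections. They establish
the algorithmic claims — solver correctness, monotone alternation,
sparse recovery of truly informative sets when the signal is kernel-
representable — not clinical performance.

## Differential-expression step

The tumour-vs-normal comparison is a per-gene two-sided Wilcoxon
signed-rank test on paired samples. Zero differences are dropped
(Wilcoxon's original treatment); the exact null distribution is used up
to 25 non-zero pairs and the normal approximation with continuity
correction above. Direction is the sign of the median paired
difference. Significance is the raw p < 0.05 rule; Benjamini–Hochberg
adjustment is available behind a flag but does not alter the flag
column, keeping the primary output comparable with the raw-p
convention. Fewer than 4 pairs is an error: the two-sided exact test
cannot reach p < 0.05 below that.

## Known limitations

- The alternation's convergence is verified empirically (monotone
  primal trace, settled weights); no convergence proof for the
  regression case is attempted.
- The intercept-recovery rule (KKT averaging over free support vectors,
  interval midpoint otherwise) is this package's choice among the
  standard options.
- SMO's runtime grows quickly past a few hundred training samples per
  solve; the replication protocol with the full grid is compute-heavy
  and is meant for cohort sizes in the hundreds, not thousands.
- The random-forest baseline often reported alongside SVR baselines is
  out of scope; the plain-SVR baseline is expressed as the single-kernel
  special case (`all_features_partition`), to which the MKL model
  provably reduces.
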