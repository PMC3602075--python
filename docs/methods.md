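# Methods

## Model

`lsadmix` infers population structure from unphased biallelic SNP
genotypes under the standard discrete admixture model.  Each individual
*i* draws the two allele copies at locus *l* independently with
reference-allele probability

    m_li = sum_k p_lk q_ki,

so the genotype count is `g_li ~ Binomial(2, m_li)`.  `P` (M loci x K
populations) holds per-population allele frequencies in [0, 1]; `Q` (K x
N individuals) holds admixture proportions, each column on the
probability simplex.  The model assumes Hardy–Weinberg equilibrium
within ancestral populations and linkage equilibrium between loci, and
handles no missing data (the reader can mean-impute on load).

Rather than maximising the binomial likelihood directly, the package
minimises the least-squares criterion

    || 2 P Q - G ||_F^2 .

This is the criterion whose gradient in `m` is the first-order Taylor
expansion of the negative binomial score around `m = 1/2`: the
approximation is tight for allele doses between roughly 0.35 and 0.65
and degrades toward the boundary, which is why the method is weakest for
individuals with near-zero contribution from some population.  The same
linearisation applied to a symmetric Dirichlet(alpha) prior on the
columns of `Q` around the barycentre `q_k = 1/K` yields the penalty

    K^2 (alpha - 1) || Q - 1/K ||_F^2 ,

which vanishes for the flat prior (`alpha = 1`), rewards sparse columns
for `alpha < 1`, and pulls columns toward even admixture for
`alpha > 1`.  `effective_alpha` converts a general Dirichlet
(alpha_1..alpha_K) into the symmetric shape with the same total variance
so a single degree-of-admixture number can stand in for an asymmetric
prior.

## Optimisation

The criterion is biconvex and is minimised by exact two-block coordinate
descent: starting from a random simplex initialisation of `Q` (K iid
uniforms per column, normalised), alternate

1. `update_P`: per locus, bounded-variable least squares on the shared
   design `2 Q'` with box [0, 1];
2. `update_Q`: per individual, least squares under `q >= 0`,
   `sum_k q_k = 1` on the penalised normal equations
   `gram = 4 P'P + K^2 (alpha - 1) I`, `rhs = 2 P'G + K (alpha - 1)`.

Both subproblems are solved to their global optimum (each is convex when
`gram` is positive definite), so the penalised criterion is monotone
non-increasing; convergence is declared when its absolute change over
one sweep falls below `epsilon`.

**Solvers.**  Both kernels use a combinatorial active/passive-set
strategy specialised for many right-hand sides sharing one Gram matrix:
columns whose active-set patterns coincide are solved in one grouped
linear solve.  The box solver maintains two active sets (clamped at 0,
clamped at 1); KKT conditions are checked at an absolute tolerance of
1e-8.  The simplex solver handles the equality constraint in closed form
with a Lagrange multiplier on each passive set (`q = a U j +
(U - a U J U) rhs` with `U` the inverse of the passive Gram block and
`a = 1/(j'Uj)`), which makes every iterate sum to one identically;
nonnegativity is enforced by the same active-set exchange.  Exchanges
move *all* violating variables at once and release *all* variables with
inward gradients; if the per-column objective fails to decrease twice in
a row the column falls back to single-variable exchange, which cannot
cycle.  A cap of `30 K` exchanges per column raises a diagnostic error
(never observed in practice).

For `alpha < 1` the penalty is negative and the normal equations are
formed directly (no square-root augmentation); if the penalised Gram
matrix loses positive definiteness — possible only for very small M —
the solver raises rather than returning a saddle point.  Entries exactly
at a bound are treated as clamped, making active-set partitions
deterministic.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `K` | required | number of ancestral populations (not estimated) |
| `alpha` | 1.0 | degree of admixture; 1 = uninformative prior |
| `epsilon` | `M*N*1e-10` | absolute stopping tolerance on the criterion (1e-4 at M=10000, N=100) |
| `max_iter` | 2000 | outer-sweep cap; hitting it reports `converged=False`, not an error |
| `seed` | 0 | controls the random initialisation of Q (and simulation) |
| `clip_likelihood` | 1e-10 | probability floor for the monitoring log-likelihood only |

The size-scaled `epsilon` keeps the stopping rule comparable across
problem sizes; at the study scale (M = 10000, N = 100) fits converge in
roughly 40–100 sweeps.  The degenerate-input policy is: genotype entries
outside {0, 1, 2} are rejected at validation; `K = 1` collapses to the
closed form `p_l = clip(mean(g_l)/2, 0, 1)`, `Q = 1`; rank-deficient
designs (fewer effective individuals than populations, collinear
frequency columns) raise with advice rather than silently regularising.

## Theoretical bounds

With `Q` known, the per-locus least-squares estimate
`p-hat = (1/2) G Q'(QQ')^{-1}` is unbiased over the genotype
distribution, and because `var(g) = 2m(1-m) <= 1/2`, the trace of its
covariance is bounded by `trace((QQ')^{-1})/8`.  For iid
Dirichlet(alpha) columns this bound approaches
`K^2 (1 + (K-1) alpha) / (8N)` — `(alpha+1)/(2N)` at K = 2 — so the
error vanishes as individuals accumulate.  The symmetric analysis for
known `P` gives `trace((P'P)^{-1})/8`, decreasing like 1/M.  Note the
closed forms are for the *unconstrained* estimator; the box/simplex
constrained estimators can only do better, but their finite-sample
covariance has no closed form here.  These formulas are implemented in
`lsadmix.theory` and double as independent oracles for the estimator
tests.

The `K^2 (1 + (K-1) alpha)/(8N)` general-K closed form is this
package's own reduction of `trace(E[qq']^{-1})/(8N)`; tests cross-check
it against the numeric inverse of the Dirichlet second-moment matrix for
several (K, alpha).

## Synthetic data

`lsadmix.simulate` draws `P` with iid Uniform(0, 1) entries (or accepts
a fixed frequency panel, e.g. one estimated from a reference cohort),
`Q` with iid Dirichlet columns, and `G ~ Binomial(2, PQ)` entrywise,
consuming a single seeded stream in the order P, Q, G.  This emulates
the study conditions: independent loci, exchangeable individuals, no
genotyping error, no linkage disequilibrium, no missing data, and allele
frequencies that are independent across populations (real populations
share drift history, so real `P` columns are correlated and less
informative per locus).  Passing tests on this generator therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to LD, array artefacts, or model
misspecification.

## Evaluation conventions

Population labels are unidentifiable, so estimates are aligned to truth
by the row permutation of `Q` minimising squared error (exhaustive over
K! for K <= 8); the same permutation is applied to the columns of `P`.
RMSE is computed over all entries of each matrix and reported in
percent; factorial-study results average per-trial RMSE across trials.
Alignment on `Q` (rather than `P`) is a package convention; at the
scales studied the optimal permutations coincide.

Reference experiment scales: the single-locus calibration experiment
uses 10000 replicates; the best-case grid uses 1000 trials per target
for the least-squares arm and 300 for the (slower) likelihood arm, whose
Monte-Carlo error at that size is well inside the comparison tolerance;
full-inference conditions use 50 trials at M = 10000.  The covariance
trace of the calibration experiment depends on the one random `Q` the
protocol draws (spread ~8% across draws), so the acceptance script
averages 32 independent repetitions of the whole experiment.

## Design choices

* **Update order** — P first (from the random initial Q), then Q, per
  sweep; the objective is evaluated after the full sweep.
* **Stopping rule** — absolute (not relative) change in the *penalised*
  criterion, matching the quantity the algorithm actually decreases.
  The `max_iter` cap is a package choice; block descent has
  data-dependent convergence speed.
* **Known-Q estimator is unconstrained** — the calibration and best-case
  experiments use the raw normal-equations estimate (entries may leave
  [0, 1]); a `clamp` flag exists for users but is off by default, and
  the likelihood arm starts from the clamped estimate.
* **Likelihood clamping** — the binomial log-likelihood is undefined at
  `m` in {0, 1}; probabilities are floored at 1e-10 for monitoring.
  The optimiser never evaluates it.
* **Dense arithmetic** — genotypes held as int8, factors as float64;
  target scale is `M*N` up to ~1e7 entries, where dense BLAS is the
  right tool.

## Known limitations

* The least-squares approximation is biased for strongly sparse
  admixture (columns of `Q` near simplex vertices); likelihood-based
  fits place more individuals exactly on the boundary.
* No modelling of linkage disequilibrium — prune dense panels to
  near-independent SNPs (~1e4) before fitting.
* `K` must be supplied; model selection (e.g. consensus across seeds) is
  out of scope.
* Multi-allelic loci, per-locus admixture, genotyping-error models, and
  standard errors for the estimates are not implemented.
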