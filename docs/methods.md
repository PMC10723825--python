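# Methods

## Overview

`subsetfam` implements Bayesian decision-analytic subset selection for
linear prediction and classification.  The starting point is any Bayesian
model `M` with posterior `p(theta | y)` and posterior predictive
`p(y~ | y)`.  Rather than selecting variables through the prior, selection
is treated as a decision problem: for each candidate subset `S` of
covariates we ask for the best *linear action* `delta_S` (coefficients
supported on `S`) under a predictive loss, then compare subsets by
out-of-sample predictive performance, and finally report the whole
*family* of subsets that are statistically indistinguishable from the
best one — not a single winner.

## Optimal actions ("fit to the fit")

Under aggregate weighted squared-error loss
`L = sum_i omega(x_i) (y~_i - x_i' delta_S)^2`, minimizing the posterior
predictive expectation decouples: the optimal action is the weighted least
squares fit of the model's fitted values `yhat_i = E[y~_i | y]` on the
active columns,

    delta_S = (X_S' Omega X_S)^(-1) X_S' Omega yhat .

Because the response of this regression is the regularized fit from `M`
rather than the raw data, every subset's coefficients inherit the model's
shrinkage.  If the weighted Gram matrix is singular the minimum-norm
pseudoinverse solution is returned and flagged.  For a linear `M`, the
full-subset action reproduces the posterior-mean coefficients exactly;
this identity is tested to 1e-8.

For classification the loss is weighted cross-entropy of a binary
functional `h(y~)` (the response itself, or an exceedance indicator
`I{y~ >= tau}` for continuous data).  The optimal action is a weighted
logistic regression of the predictive probabilities
`hhat_i = E[h(y~_i) | y]` on the active columns, solved by IRLS
(max 100 iterations, tolerance 1e-8 on the max absolute coefficient
change; non-convergence returns the last iterate with a flag).  Because
`hhat` lies strictly inside (0,1) for non-degenerate models, separation —
the classical failure mode of logistic regression — does not arise.
Probabilities are clipped to `[1e-6, 1 - 1e-6]` before the logit; a fully
saturated target warns rather than errors, since the clipped pseudo-data
are still well-defined.

## Subset search

Expected predictive RSS orders equally-sized subsets exactly as the plain
RSS against `yhat` does, so the search reduces to classical best-subsets
regression with pseudo-data `(X, yhat, omega)`.  For classification, a
second-order (IRLS) approximation at the full-model probabilities yields
subset-invariant pseudo-data `zhat_i = logit(hhat_i)` and working weights
`what_i = omega_i hhat_i (1 - hhat_i)`; the search runs on `(zhat, what)`
while all subsequent evaluation uses exact cross-entropy.

The branch-and-bound enumerator returns, for each size `k`, exactly the
`m_k` subsets with smallest weighted RSS (default `m_k = 15`; `m_k = 100`
is the other common choice).  It walks a binary include/exclude tree in
the style of Furnival and Wilson's leaps-and-bounds: each node carries two
sweep-state matrices — the augmented Gram swept on the included columns
(whose corner entry is the current RSS) and the same matrix swept on all
remaining free columns (whose corner entry is the RSS of the node's full
closure, a valid lower bound for the entire subtree, since RSS can only
increase when columns are removed).  Both states are maintained by single
O(f^2) sweep operations per branch — the sweep operator is involutory, so
excluding a column is one more sweep, not a recomputation — and dead
columns are dropped so matrices shrink with depth.  A subtree is pruned
when its bound cannot beat the current m_k-th best RSS at any reachable
size.  Candidate columns are pre-ordered by marginal explained sum of
squares, which tightens thresholds early.  Exactness is verified against
brute-force enumeration on hundreds of random fixtures.  RSS ties at the
retention boundary (measure-zero for continuous data) are broken
lexicographically by subset indices.

With many covariates, the search space is first screened to
`s_max = 35` columns (the intercept plus the 34 largest absolute
standardized posterior-mean coefficients).  The intercept is forced into
every subset.  Exhaustive (guarded to at most 25 columns), greedy forward
and greedy backward strategies are provided as oracles and baselines.

## Out-of-sample evaluation without refitting

Candidates are compared on K-fold out-of-sample losses (default K=10,
random equal folds).  Refitting `M` per fold is avoided by importance
sampling: the full-data posterior is the proposal for each training-fold
posterior, with weights `w_ks ∝ 1 / p(y_{I_k} | theta_s)` computed in log
space with max-subtraction.  Per-fold effective sample sizes are
recorded; a warning is raised when the minimum ESS falls below 25 (the
remedy is more posterior draws).  On a conjugate Gaussian fixture the
IS-weighted fold quantities match the closed-form training posterior, and
the IS predictive-loss draws match refit-based draws in distribution
(Kolmogorov–Smirnov check at S = 4000).

Each subset's training-fold action is the weighted least squares fit of
the importance-weighted predictive mean (computed from `E[y~|theta_s]`,
i.e. Rao-Blackwellized over the observation noise) on the training rows.
Two losses are then recorded per fold: the *empirical* loss against the
held-out responses, and a distribution of *predictive* losses against
posterior predictive draws of the held-out data.  For the predictive
draws, each fold's weighted sample is converted to an unweighted one by
systematic resampling; the resampled draw indices are shared by all
subsets, so per-draw loss differences are coupled (common random
numbers).  With uniform weights, systematic resampling returns every draw
exactly once, so the construction degenerates to plain cross-validation
on the pseudo-response.  Fold losses are averaged position-wise across
folds.

## The acceptable family

`S_min` is the subset minimizing the empirical K-fold loss.  For every
candidate `S`, the percent increase in predictive loss
`D~ = 100 (L~_S - L~_Smin) / L~_Smin` is computed draw-wise, and `S` is
*acceptable* when `P(D~ <= eta) >= eps` (defaults `eta = 0%`,
`eps = 0.10`).  Membership uses the non-strict comparison so the anchor
is always a member (its `D~` is identically zero).  `S_small` is the
smallest acceptable subset, ties broken by smallest empirical loss.  The
family grows as `eta` increases or `eps` decreases; `eps = 0` admits
every candidate.

When the target covariates are new (no held-out responses exist), the
empirical anchor is undefined; the family is instead anchored at the full
screened subset, whose point prediction under a linear model is the
posterior predictive expectation.

## Summaries

*Variable importance.*  `vi(j, l)` is the proportion of acceptable
subsets containing both `j` and `l` — an exact rational count.  The
diagonal `vi(j)` measures how many near-optimal explanations involve
covariate `j`; `vi(j) = 1` marks a *keystone* covariate present in every
member.  Pairs with large marginals but small joint inclusion are
redundant (interchangeable) predictors.  An n-way count over explicit
index tuples generalizes the pairwise metric.

*Uncertainty.*  The *predictive action* applies the WLS map to each
posterior predictive draw, `delta~_S = (X_S' Omega X_S)^{-1} X_S' Omega
y~`, reusing one factorization across draws.  Equal-tailed quantile
intervals of these coefficient draws quantify uncertainty for any subset,
including data-selected ones (`S_small`, `S_min`), which are treated as
posterior functionals — no additional selection adjustment is applied.
Coefficients outside the subset are reported as exactly zero.  Highest
posterior density intervals are reserved for the baseline selector that
keeps a covariate when its 95% HPD interval excludes zero.

## Reference models

The default regression model is Gaussian linear regression with horseshoe
priors: `beta_j ~ N(0, sigma^2 tau^2 lambda_j^2)` with half-Cauchy local
and global scales, sampled by a Gibbs sampler using inverse-gamma
auxiliary variables for the scales — the parametrization that scheme was
derived for.  A sigma-independent slab (`scale_by_sigma=False`) is
available; the two differ mainly in how strongly the error scale couples
into shrinkage when p is comparable to n.  The sampler is validated
against an independent random-walk Metropolis sampler of the same
posterior on a small fixture (posterior means and sds agree to ~0.02).
The intercept is unpenalized (diffuse `N(0, sigma^2 * 100^2)`).  When the column count exceeds n, the
conditional-normal draw switches to the O(n^2 p) algorithm of the
structured-prior literature (sample in the n-dimensional dual space).
Defaults are 1000 burn-in plus 1000 saved draws, thinning 1: horseshoe
Gibbs mixes quickly and 1000 draws suffice for point summaries.  The
number of *saved* draws matters most for the importance-sampled
cross-validation, whose fold-level estimates keep stabilizing well past
the point where posterior means have converged; the shipped study
harness therefore saves 4000 draws for the n = 50 designs — the
settings with the least stable validation-fold likelihoods — and 1000
elsewhere, while 500 saved draws visibly degrade the fold estimates
(per-fold effective sample sizes of a few dozen).  The classification reference model is Bayesian logistic
regression under independent Student-t(3, 2.5) priors on standardized
slopes (t(3, 10) on the intercept), sampled by Metropolis random walk
from a Laplace-approximation proposal.  Both samplers are deterministic
given a seed, and any external source of coefficient draws can be plugged
in instead (`SubsetSelection.from_draws`).

For real data, continuous covariates are centered and scaled to standard
deviation 0.5 by default, putting continuous and binary predictors on
comparable scales; coefficients can be mapped back to the raw scale.  The
synthetic-study harness fits on the raw scale, since its covariates are
standard normal by construction and true-coefficient comparisons are on
that scale.

## Synthetic study design

The generator emulates sparse linear signals in correlated designs:
covariates are marginally standard normal with AR(1) correlation
`rho^{|j - j'|}` (`rho = 0.75`), columns randomly permuted; the intercept
is -1 and `p* = 5` coefficients are nonzero (three +1, two -1) on
uniformly random columns; noise is Gaussian with
`sigma = sd(y*) / SNR`, using the realized sample standard deviation of
the noiseless signal per replicate.  Replicates use independent seeds
spawned from a master seed, so results are reproducible at any worker
count.

The harness scores marginal selection (TPR over the 6 active columns
including the always-selected intercept, TNR over the inactive columns),
RMSE against the noiseless signal for every family member, interval width
and coverage for the true coefficients, and a classical best-subset
baseline (unregularized search on the raw response, size chosen by AIC,
model-free marginal-correlation screening beyond 35 columns).

What the generator does *not* emulate: heavy-tailed or heteroscedastic
noise, non-Gaussian covariates, interactions, or model misspecification
more broadly — passing tests demonstrate internal correctness and
behavior under the stated design, not robustness on arbitrary real data.

## Problem sizes and numerical choices

The shipped end-to-end checks use 20–40 replicates per design point at
(n, p) in {(50, 50), (200, 400), (500, 50)} with 1000+1000 MCMC
iterations — small enough for a desk run, large enough that Monte-Carlo
error on selection rates is a few percentage points.  Other notable
constants: probability clip 1e-6 before logits; sweep pivot guard 1e-12
(redundant columns contribute nothing, matching the minimum-norm
convention); importance weights normalized exactly (checked to 1e-12);
family membership via non-strict `D~ <= eta`.

## Known limitations

* The branch-and-bound bitmask limits the searchable (post-screening)
  space to 63 columns; screening makes this a non-issue in practice.
* Importance weights degrade as validation-fold likelihoods become
  extreme (small n, very low noise); the ESS diagnostic flags this, and
  Pareto-smoothing is a possible extension not currently shipped.
* Cross-entropy evaluation fits one IRLS per subset per fold; for very
  large candidate sets this is noticeably slower than the squared-error
  path.
* Losses beyond squared error and cross-entropy are out of scope.
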