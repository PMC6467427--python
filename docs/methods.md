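# Methods

## Model and estimation problem

`glvfit` estimates the parameters of generalized Lotka-Volterra (gLV)
community dynamics from mono- and pairwise-culture time series. The gLV model
for species abundances x_s(t) is

    dx_s/dt = (mu_s + sum_{s'} alpha_{ss'} x_{s'}) x_s,

with growth rates mu_s (1/h) and interaction coefficients alpha_{ss'}
(1/(abundance*h), row = recipient, column = donor), giving S^2 + S parameters
for S species. The saturable variant replaces each interaction term with
alpha_{ss'} x_{s'} / (K_{ss'} + x_{s'}), adding S^2 half-saturation constants
K_{ss'} > 0 (2 S^2 + S parameters). Pairwise cocultures are passaged: at
scheduled dilution times all abundances jump to 1/20 of their pre-dilution
value.

Estimation is maximum a posteriori (MAP): minimize

    (1/2)(theta - theta_bar)^T Sigma_theta^{-1} (theta - theta_bar)
    + sum_k (1/2)(eta_k - eta_bar_k)^T Sigma_k^{-1} (eta_k - eta_bar_k)

subject to the dynamics, initial conditions, and box bounds on theta
(biologically feasible ranges 0.09 < mu_s < 2.1, |alpha_{ss'}| < 10,
-10 < alpha_ss < 0, K > 0). Measurement noise is heteroscedastic with a
floor: sigma_{k,s}(t) = 0.05 * max(0.1, eta_{k,s}(t)). The Gaussian (L2)
prior defaults to standard deviation 1/50 on every parameter; a Laplacian
(L1) prior is available through nonnegative variable splitting, which keeps
the problem twice continuously differentiable.

## Direct transcription

Rather than repeatedly simulating the ODEs, the dynamics are discretized by
implicit Euler — x^{j+1} = x^j + h f(x^{j+1}, theta), a one-point Radau
collocation scheme — and the discrete states of every experiment become
optimization variables alongside theta. Dilution events are duplicated grid
nodes linked by the jump constraint x+ = (1/20) x-. The observation map is
the identity on cultured species, and a measurement taken at a dilution time
refers to the pre-dilution node (samples are drawn before passaging). All
first and second derivatives of the objective and constraints are analytic
and assembled sparsely, so any interior-point solver consuming the standard
callback contract (objective, gradient, constraints, Jacobian, Lagrangian
Hessian, bounds, sparsity) can solve the problem. The backend shipped here is
SciPy's `trust-constr`; barrier strategy, step acceptance, and inertia
correction during iterations are its responsibility. Warm-started re-solves
(used heavily by rMAP) start the barrier parameter at 1e-6, which empirically
cuts iteration counts by roughly a third when starting at a nearby optimum.

Grid resolution. Mono-species experiments are sampled every 0.5 h for 24 h;
their grid refines each sampling interval into `mono_substeps` Euler steps.
Pairwise experiments run 96 h (8 samples at 12-h spacing, dilutions every
24 h) on `pairwise_n_intervals` equal intervals with sampling and dilution
times merged in exactly. The defaults place a node every 0.1 h in both
designs (5 substeps per mono interval; 960 pairwise intervals, i.e. 120 per
12-h sampling interval). This resolution was chosen so that the
grid-doubling sensitivity test below passes at its own threshold: with nodes
only at the sampling times (mono h = 0.5, pairwise h = 0.8), the first-order
Euler bias moves self-interaction estimates by ~0.04 under doubling, an
order of magnitude above the test's tolerance. The bias scales linearly in
h (measured empirical order 0.8-1.2), as expected for implicit Euler.

Discretization sufficiency. After solving on a grid, the problem is re-solved
on the 2x refined grid; the discretization is accepted when every parameter
satisfies |theta_i - theta_ref_i| < 0.01 or |theta_i - theta_ref_i| /
|theta_i| < 0.01 (absolute values on both tests). At the default grids this
check passes for the 3-species synthetic study (max shift 0.005); at the
raw sampling resolution it fails (max shift 0.039). Coarsening only the
pairwise grid 8x still passes (max shift 0.007): the 16 points of a pairwise
series carry much less parameter information than the 48-point mono series,
so the discriminative coarse case must also coarsen the mono grid.

## Robust (CVaR) objective

To mitigate outliers the sum of per-experiment errors e_k can be replaced by
a k-max (CVaR) objective: with threshold gamma and slacks s_k >= 0,

    K*gamma + 1/(1-beta) * sum_k s_k,    s_k >= e_k(w) - gamma.

Minimized over gamma this equals K times the mean of the ceil((1-beta)K)
largest experiment errors; at beta -> 0 it is exactly sum_k e_k, and as
beta -> 1 it approaches the largest error. The epigraph condition is
implemented with per-experiment error variables t_k pinned by equality rows
e_k(w) - t_k = 0, leaving the inequality s_k + gamma - t_k >= 0 linear; the
equality route is markedly more robust for the backend than a nonlinear
inequality coupling thousands of states through the barrier. CVaR solves are
additionally warm-started from the standard MAP solution
(`solve_robust`), since the minimax-like geometry is slow from a cold start.
At beta = 0.9 on a 5%-outlier dataset this trades a strictly smaller
top-10% experiment-error tail for a larger mean error — the standard
robust-statistics trade-off. The trade-off expresses at the experiment
granularity (the granularity the objective penalizes); per-point tails can
move the other way.

## Observability and covariance

At a solution, parameters are locally unique exactly when the constraint
Jacobian has full row rank and the reduced Hessian (the Lagrangian Hessian
projected onto the constraint null space) is positive definite. The null
space is never formed: the augmented KKT matrix M = [[H, J^T], [J, 0]] has
inertia (n, m, 0) precisely in that case, and the inertia is read off the
1x1/2x2 blocks of a symmetric-indefinite LDL^T factorization. Because
parameters are the only variables shared across experiments, a symmetric
permutation of M is block-bordered diagonal; per-experiment blocks are
factorized independently and Haynsworth additivity gives
Inertia(M) = sum_k Inertia(K_k) + Inertia(S) with S the parameter-space Schur
complement. The verdict is `observable` when every block has its healthy
saddle inertia and S is positive definite; a zero eigenvalue of S marks a
direction of non-identifiability. The prior term must be dropped for this
test (it adds Sigma_theta^{-1} to S and regularizes any deficiency away);
re-adding it flips a deficient verdict back to observable, which is the
regularization effect made visible. When observable, S^{-1} approximates the
parameter posterior covariance (with the prior included, the Gaussian
posterior covariance). Bounds active at the solution degrade the
approximation; the report counts them rather than correcting for them.

Numerical details: before factorization the matrix is symmetrically Ruiz-
equilibrated — an inertia-preserving congruence — because the raw KKT matrix
mixes likelihood weights ~4e4 with saddle-point reciprocals ~1e-9 and a
relative pivot threshold would otherwise misclassify genuine tiny
eigenvalues; a pivot is declared zero below 1e-8 times the largest pivot.
Multipliers are recovered at the solution from the stationarity conditions
by sparse least squares over the rows of variables strictly inside their
bounds, which is exact at an optimum and independent of backend sign
conventions.

## Randomized-MAP uncertainty quantification

Posterior spread is estimated by re-solving the MAP problem under random
data perturbations eta <- eta + N(0, sigma^2), warm-started from the MAP
solution, and collecting the re-estimated parameters. For linear
parameter-to-output maps the draws are Gaussian around theta* with
covariance (grad_m^T Sigma^{-1} grad_m)^{-1} — second-order-consistent
posterior samples; on a linear-Gaussian benchmark the 500-sample covariance
matches the closed form to ~10% Frobenius error. Two perturbation modes are
provided: data-only (the default, matching the community-study procedure)
and data-plus-prior-mean (theta_bar + N(0, Sigma_theta)), under which the
linear-Gaussian limit reproduces the full posterior covariance including
the prior term; which mode a given historical study used is ambiguous, so
neither is asserted as canonical. Unlike an unconstrained Gaussian
approximation, every rMAP draw respects the parameter bounds. Failed
re-solves are recorded and excluded from summaries; a failure fraction
above 20% flags the run. Moment summaries report skewness (third central
moment / sigma^3) and kurtosis (fourth / sigma^4, normal reference 3);
pairwise 95% confidence ellipses use the chi-square(2) quantile 5.991.

## Synthetic-data generator

The generator emulates the mono + pairwise coculture design family: S mono
experiments (48 samples each) and S(S-1)/2 pairwise experiments (8 samples
per member, 1/20 dilution every 24 h), i.e. S(S+1)/2 experiments, S^2
differential equations and 48S + 8S(S-1) data points — 78/300/666/1,176
experiments and 1,632/5,568/11,808/20,352 points for S = 12/24/36/48.
Generating parameters are drawn from mu_s ~ N(0.3, 0.1^2), alpha_ss ~
N(-1, 0.1^2), alpha_ss' ~ N(0, 0.1^2); initial abundances default to 0.01
per cultured species (a convention — the source designs do not state them).
Observations are the reference-integrator outputs (LSODA, rtol 1e-8,
atol 1e-10) plus N(0, sigma^2) noise with sigma computed from the noiseless
output, clipped at zero by default (abundances are physical; clipping is
optional). The recorded sigma is reused as the likelihood weight.
Replicated augmentation re-perturbs the base observations under fresh
experiment ids (11x the S=12 design gives 858 experiments and 1,584 states).

What the generator does not emulate: lag phases, time-varying interactions,
measurement dropout, irregular sampling, and relative-abundance
compositionality of real community data. Passing tests therefore demonstrate
correctness of the estimation machinery under the stated generative model,
not robustness to the structural misspecification real data would add.

## Study configurations used in the validation suite

Parameter-recovery checks run the 3-species full design at 5% noise with the
sigma = 1/50 L2 prior and printed bounds. Two prior centerings probe two
different claims, and the distinction matters: centered on the generating
values, the posterior covariance calibrates the estimation error (>= 90% of
parameters within 3 posterior standard deviations); centered on the
population means (0.3 / -1 / 0), the prior is deliberately over-confident
relative to the generating spread (1/50 vs 0.1), weakly identified
cross-interactions are shrunk several posterior standard deviations away
from their generating values, and coverage fails — but the noise term then
dominates the recovery error, which falls monotonically (0.064 / 0.014 /
0.0075 RMSE at 5% / 1% / 0.1% noise). Population-mean priors are the
default for synthetic workflows; truth-centered priors appear only in the
calibration check.

Problem sizes were chosen to keep the full suite within an ordinary
single-CPU session: recovery and discretization studies use S = 3 (~6,500
NLP variables at default grids, ~13,000 refined); the CVaR comparison uses
S = 3 at sampling-resolution grids (the comparison is grid-for-grid, so
both fits share whatever grid is used); rMAP consistency uses a
linear-Gaussian benchmark with closed-form re-solves for the 500-sample
covariance check plus small warm-started gLV runs for the bound-respect
property. The design-size table is exact combinatorics and runs at all four
published sizes.

## Known limitations

* The backend is a general NLP solver, not a structure-exploiting parallel
  one; the BBD Schur machinery here serves observability analysis, and its
  per-experiment stages are independent by contract but executed serially.
* CVaR solves need the two-stage warm start; cold starts can stall for
  hundreds of iterations.
* Implicit Euler is first order; grids substantially coarser than the
  defaults bias self-interaction estimates measurably (see the sufficiency
  test).
* The observability covariance is a local, second-order object; active
  bounds at the solution are flagged, not corrected for.
* Dense LDL^T factorizations cap the practical KKT analysis size at a few
  thousand variables per experiment block; the estimation path itself is
  fully sparse.
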