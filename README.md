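# glvfit

Scalable parameter estimation for dynamic microbial community models.

Microbial ecologists model gut-community dynamics with the generalized
Lotka-Volterra (gLV) equations,

    dx_s/dt = (mu_s + sum_{s'} alpha_{ss'} x_{s'}) x_s,

where x_s is the abundance of species s, mu_s its growth rate, and
alpha_{ss'} the effect of donor s' on recipient s (a saturable variant
alpha_{ss'} x_{s'}/(K_{ss'}+x_{s'}) is also supported). Fitting these models
to mono- and pairwise-culture time series is expensive with simulation-based
estimators: every trial parameter vector requires integrating stiff ODEs for
dozens of experiments. `glvfit` instead *transcribes* the dynamics — implicit
Euler turns every experiment's trajectory into sparse algebraic constraints,
and states and parameters are optimized jointly by an interior-point solver
with exact analytic first and second derivatives. One solve replaces
thousands of simulations, and the KKT system at the optimum comes for free,
enabling:

* **MAP estimation** with Gaussian (L2) or Laplacian (L1) priors, biological
  parameter bounds, heteroscedastic noise weights, and batch-passaging
  (dilution) events;
* **robust fitting** with a CVaR (k-max) objective that penalizes the mean
  of the largest per-experiment errors instead of their sum;
* **observability analysis**: LDL^T inertia of the block-bordered KKT matrix
  via Schur complements and Haynsworth additivity certifies whether the data
  identify the parameters uniquely, without forming null-space bases;
* **uncertainty quantification** by randomized MAP (rMAP): warm-started
  re-solves under data perturbations yield posterior samples that respect
  bounds and nonlinearity, with moments, correlations, and 95% confidence
  ellipses;
* **synthetic study generation** reproducing the published mono+pairwise
  design family (78 experiments / 156 parameters / 1,632 data points at 12
  species, up to 1,176 / 2,352 / 20,352 at 48).

It is aimed at systems-biology groups fitting community or kinetic models
who want estimation, identifiability diagnostics, and UQ from a single
algebraic problem formulation.

## Worked example

Estimate a 3-species community from synthetic data (5% multiplicative
noise, dilution 1/20 every 24 h in cocultures):

```python
import numpy as np
from glvfit import (PriorSpec, build_design, draw_parameters,
                    generate_dataset, transcribe)
from glvfit.solve import solve
from glvfit.kkt import posterior_covariance

params = draw_parameters(3, seed=42)            # mu~N(0.3,0.1^2), a_ss~N(-1,0.1^2)
design = build_design(3)                        # 3 mono + 3 pairwise experiments
data = generate_dataset(params, design, seed=7) # 192 noisy observations

prior = PriorSpec(form="l2", mean=params.theta("glv"), std=1/50)
nlp = transcribe("glv", design, data, prior=prior)   # 6,519 variables, 6,507 constraints
res = solve(nlp)

sd = np.sqrt(np.diag(posterior_covariance(nlp, res)))
err = np.abs(res.theta_star - params.theta("glv"))
print(res.status, res.n_iterations, "iterations")
print("max |error| =", err.max().round(4))
print("parameters within 3 posterior sd:", int((err <= 3*sd).sum()), "/ 12")
```

```
optimal 30 iterations
max |error| = 0.0191
parameters within 3 posterior sd: 11 / 12
```

The twelve parameters (3 growth rates, 9 interactions) are recovered to
~0.02 absolute accuracy, and the reduced-Hessian posterior standard
deviations correctly scale the estimation error for 11 of 12 parameters.

The same pipeline is available from the shell:

```bash
glvfit scale-study --sizes 12,24,36,48     # problem-size table
glvfit estimate --species 3 --seed 1 --output out/
glvfit uq --species 2 --samples 100 --output out/
```

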