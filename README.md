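# bigjm

Scalable Bayesian joint modelling of longitudinal biomarkers and
time-to-event outcomes, with divide-and-conquer posterior pooling and
dynamic subject-level risk prediction.

## Who this is for

Biostatisticians and epidemiologists working with cohorts — often EHR
extracts — where a repeatedly measured biomarker (tumour size, eGFR,
CD4 count, ...) and a censored event time (death, progression,
transplant) must be modelled *jointly*: the biomarker trajectory carries
prognostic information about the hazard, and ignoring the coupling biases
both submodels. At EHR scale a single MCMC run over every subject is
impractical, so the package fits the model on disjoint subject chunks and
pools the chunk posteriors.

## The model

Longitudinal submodel (linear mixed model, identity link):

    y_i(t) = eta_i(t) + e_i(t),    eta_i(t) = x_i(t)' beta + z_i(t)' b_i,
    e_i(t) ~ N(0, sigma^2),        b_i ~ N_q(0, D)  or multivariate t_df(0, D)

with x_i(t) = z_i(t) = (1, t) by default (random intercept + slope).

Survival submodel (proportional hazards with a current-value association):

    h_i(t) = h0(t) exp( gamma' w_i + alpha * eta_i(t) ),
    log h0(t) = gamma0_0 + sum_q gamma0_q B_q(t; v)

where B_q are clamped cubic B-splines with interior knots v at event-time
quantiles, and alpha measures how strongly the current biomarker level
drives the hazard.

Inference is Metropolis-within-Gibbs MCMC over (beta, b_i, D, sigma,
gamma, alpha, gamma0) with conjugate draws for D and sigma^2, a vectorised
random-walk sweep over all subjects' b_i, and an exact Gibbs recentering
move for the shared intercept/slope directions. For large n, subjects are
partitioned into chunks of a configurable size, each chunk is fitted
independently (sharing one spline basis placed on the full event-time
set), and the chunk summaries are pooled either by mean-and-standard-error
combination (default) or by precision (inverse-covariance) weighting.

Dynamic prediction conditions on one subject's history up to a landmark
time s: their random effects are sampled from p(b | history, T > s) with
population parameters fixed at the pooled posterior means, giving
conditional survival curves S(u | s) and biomarker trajectory bands.
Predictive accuracy over time is measured by the truncated Harrell
concordance and the IPCW (inverse-probability-of-censoring-weighted)
Brier score.

## Worked example

```python
from bigjm import (McmcConfig, SimulationConfig, fit_big,
                   simulate_joint_dataset)

long, surv, truth = simulate_joint_dataset(SimulationConfig(n_subjects=200, seed=1))
pooled = fit_big(long, surv, mcmc=McmcConfig(n_iter=2000, n_burnin=500),
                 chunk_size=100, seed=1)   # K = 2 chunks
for name in ("beta_intercept", "beta_time", "gamma_0", "alpha", "sigma"):
    print(f"{name:<16}{pooled.mean[name]:8.3f} +- {pooled.se[name]:.3f}")
```

prints (seed 1):

```
beta_intercept     0.390 +- 0.045
beta_time          0.336 +- 0.040
gamma_0            0.223 +- 0.082
alpha              0.650 +- 0.154
sigma              0.302 +- 0.009
```

The generating values were beta = (0.5, 0.3), gamma = 0.4, alpha = 0.6,
sigma = 0.3: each pooled mean lies within three pooled standard errors of
its target, and the clearly positive alpha recovers the biomarker-hazard
coupling. The scripts in `examples/` walk through each capability
(simulation, chunked fitting, dynamic prediction, evaluation) and print
annotated output.

A thin CLI wraps the same pipeline for shell use:

```bash
bigjm simulate -n 500 --seed 7 --out data/
bigjm fit      --config config.yaml
bigjm predict  --config config.yaml --fit-dir out/
bigjm evaluate --config config.yaml --fit-dir out/
```

with a YAML config holding paths, column maps and sampler settings; every
run records its seed and config hash and reproduces byte-identically.

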