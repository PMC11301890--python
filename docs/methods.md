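# Methods

## Model

`bigjm` fits a shared-random-effects joint model. Subject i contributes
longitudinal records y_il at times t_il and a right-censored event time
(T_i, delta_i) with baseline covariates w_i.

**Longitudinal submodel.** A Gaussian linear mixed model with identity
link: y_il = eta_i(t_il) + e_il, eta_i(t) = x_i(t)'beta + z_i(t)'b_i,
e_il ~ N(0, sigma^2). The design labels are `intercept`, `time` and
optionally subject-constant covariate names, so eta_i(t) is always affine
in t — the vectorised likelihood and the closed-form survival-time
inversion in the simulator both rely on this. Random effects are
multivariate normal N(0, D) or multivariate Student-t with df degrees of
freedom and scale matrix D (df is user-set, default 4, never estimated;
the Student-t is handled as a per-subject inverse-gamma scale mixture so
the D update stays conjugate). The family/link seam exists in `ModelSpec`
but only the Gaussian/identity instance is implemented.

**Survival submodel.** Proportional hazards with a current-value
association: h_i(t) = h0(t) exp(gamma'w_i + alpha * eta_i(t)). The
association function of the biomarker history is fixed to the current
value alpha * eta_i(t); other functionals (slope, cumulative) are an
extension point, not implemented.

**Baseline hazard.** log h0(t) = gamma0_0 + sum c_q B_q(t), with clamped
cubic B-splines on Q interior knots at the q/(Q+1) event-time quantiles
(type-7/linear interpolation) and boundary (0, max observed time). A
clamped basis satisfies partition of unity, which is collinear with the
intercept, so the first basis function is dropped: Q + 3 free spline
coefficients plus the intercept. Default Q = 2 — no principled rule
exists for Q; two interior knots give a usefully flexible but stable
log-hazard at the cohort sizes the tests use. Beyond the boundary knots
the basis is clamped (constant log-hazard), which keeps extrapolated
hazards in long-horizon prediction bounded.

**Priors.** Zero-mean normals with s.d. 10 on beta, gamma, alpha and all
baseline coefficients; inverse-Wishart(dim(b)+1, I) on D;
inverse-gamma(0.01, 0.01) on sigma^2. The random-effects density
sum_i log p(b_i | D) is accounted in the prior term, keeping the
likelihood conditional on b explicit.

## Sampler

Metropolis-within-Gibbs, dependency-light and bit-reproducible under a
seed:

1. all subjects' b_i proposed and accepted/rejected in one vectorised
   random-walk sweep against their per-subject conditionals;
2. beta, gamma, alpha, and the baseline block (intercept + spline
   coefficients jointly) as separate random-walk blocks against the joint
   log-posterior;
3. an exact Gibbs *recentering* move: for each design label shared by the
   fixed and random designs, eta is invariant under
   (beta_j + d, b_.j − d), so the conditional of the shift d is Gaussian
   and is drawn exactly. Without it the fixed intercept and the mean of
   the random intercepts mix an order of magnitude more slowly;
4. conjugate inverse-gamma sigma^2 and inverse-Wishart D draws (with
   inverse-gamma mixing-scale draws under Student-t effects).

Proposal scales adapt by Robbins–Monro during burn-in toward acceptance
0.25 (vector blocks) / 0.44 (scalars) and are frozen afterwards, so the
retained chain is a valid Markov chain. Defaults: 4000 iterations, 1000
burn-in, thin 1. Initial values are deterministic moment estimates:
pooled OLS for beta and sigma (floored at 0.01), per-subject OLS spread
for a diagonal D (floored at 0.01), log(events / total follow-up) for the
baseline intercept, zeros elsewhere. If the log-posterior is not finite
at the start, the initial point is jittered up to 100 times before
aborting.

All hazard integrals use 15-node Gauss–Legendre quadrature applied per
knot panel (the integrand is exp of a piecewise-cubic, smooth within each
panel), which makes cumulative hazards additive across split points to
~1e-12 and agrees with dense trapezoid integration to well below 1e-6
relative — both properties are tested.

## Divide-and-conquer pooling

`fit_big` validates the table pair, places the spline knots **once** on
the full event-time set (chunk-specific bases would make the baseline
coefficients non-commensurable), shuffles subjects by the master seed and
slices them into disjoint chunks (a trailing chunk smaller than
max(20, chunk_size/2) is merged into its predecessor; a chunk with no
events is merged forward until every fitted chunk has at least one).
Chunk k runs with seed `seed + 1 + k`, so results are reproducible and
independent of processing order.

Two pooling rules:

* `mean_se` (default): pooled mean = average of chunk posterior means;
  pooled variance = (1/K^2) * sum of chunk posterior variances — the
  combination for independent chunk estimates, which reproduces
  full-data-fit uncertainty scaling (the consistency test finds pooled
  standard errors within ~20% of the full fit's);
* `precision_weighted`: chunks combined through their inverse posterior
  covariance matrices, theta = (sum H_k)^-1 sum H_k m_k, mirroring a
  Hessian-accumulation update. A singular chunk covariance is an error,
  never silently regularised.

The two rules coincide exactly for equal diagonal chunk covariances
(tested to 1e-10). Pooling operates on chunk summaries; concatenating raw
chunk draws is possible future work.

## Dynamic prediction

Given a subject's history up to a landmark s (records at t <= s, known
event-free at s), the random effects are drawn by random-walk Metropolis
from p(b | history) ∝ p(b|D) · prod_l N(y_l | eta(t_l), sigma^2) ·
exp(−H_i(0, s)); the survival-to-landmark factor is included because the
prediction conditions on T_i > s. Population parameters are fixed at the
pooled posterior means (empirical-Bayes style) — `PooledFit` retains
means and standard errors, not joint draws, so parameter uncertainty is
*not* propagated into the bands; this is a documented limitation. Each
draw yields S(u|s, b) = exp(−H_i(s, u | b)) and a trajectory line; means
and equal-tailed 95% percentile bands are reported (default 2000 draws).
S(s|s) = 1 holds exactly and chained landmarks telescope for common
draws.

## Evaluation

From per-subject predicted survival S_i(t) on a grid (default: deciles of
the observed event times):

* **Concordance over time** — Harrell pairs truncated at t: over pairs
  with T_i < T_j, delta_i = 1, T_i <= t, the fraction with
  S_i(t) < S_j(t), ties counting 1/2; undefined (NaN) with no usable
  pairs.
* **Prediction error over time** — IPCW Brier score with weights from the
  Kaplan–Meier estimate G of the censoring distribution: 1/G(t) for
  subjects at risk at t, 1/G(T_i−) for events by t (left-continuous
  evaluation), 0 for subjects censored by t. With no censoring the
  weights are all 1 and the score reduces to the plain mean squared
  error.

These estimator choices (truncated Harrell concordance, censoring-KM
IPCW) are the standard ones in joint-model software and are named in the
output metadata. The package's Kaplan–Meier is right-continuous (product
over t_i <= t).

## Synthetic data generator

`simulate_joint_dataset` draws b_i (normal or Student-t scale mixture),
one standard-normal baseline covariate, a linear trajectory observed with
Gaussian noise on a fixed visit grid (default 0, 0.25, ..., 2.75; visits
at or after the observed time are discarded, the baseline visit always
kept), and an event time by inverting H_i(t*) = −log U. The generator's
true baseline hazard is **constant** (log_h0), deliberately simpler than
the fitted spline: closed-form checks exist (exponential survival under
alpha = 0) and a correct fit should recover an approximately flat spline.
Censoring is the minimum of an exponential time (rate `censor_rate`, 0 =
none) and the administrative horizon tau.

Default generating values: n = 500, beta = (0.5, 0.3),
D = diag(0.4, 0.04), sigma = 0.3, gamma = 0.4, alpha = 0.6,
log_h0 = −0.7, censor_rate = 0.15, tau = 3 — a moderately censored
(~25%) cohort with ~5 visits per subject, typical of a biomarker study.
What the generator does **not** emulate: informative censoring,
missing-not-at-random visit schedules, measurement-error heteroscedasticity,
or time-varying covariates — passing tests demonstrate correctness of the
machinery under the stated model, not robustness to those violations.

## Numerical choices and degenerate inputs

* Event times solved by bracketing + Brent to 1e-8 absolute, searching up
  to 10x the administrative horizon; an unreachable target returns +inf
  (censored at the cap).
* Quadrature: 15-node Gauss–Legendre per knot panel, no adaptive
  subdivision.
* sigma and the diagonal of D floored at 0.01 at initialisation
  (degenerate constant-outcome data hits the floor instead of crashing).
* Kaplan–Meier ties: events and censorings at the same time are handled
  with the at-risk count taken just before the time.
* Chunk covariance matrices are inverted exactly; singularity is an
  error by design.
* `validate_join` drops longitudinal records after the observed time
  (with a count) by default — EHR extracts routinely contain
  post-censoring rows — and errors instead when `drop_post_event=False`.

## Test problem sizes

Heavyweight checks run at n = 500 subjects / 4000 iterations / 10 seeds
(parameter recovery) and n = 400 / K = 4 / 10 seeds (pooling
consistency); module-level smoke tests use 60–300 subjects and shorter
chains, sizes chosen to exercise the same code paths at a few seconds
each.

## Known limitations

* Single longitudinal outcome; no competing risks; no AFT/AH hazard
  structures.
* Population-parameter uncertainty is not propagated into dynamic
  predictions (empirical-Bayes plug-in).
* df of the Student-t random effects is fixed, not estimated.
* In-process sequential chunk fitting only; no cluster scheduling.
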