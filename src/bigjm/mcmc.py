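"""Posterior sampling for the joint model on one data chunk.

Metropolis-within-Gibbs:

* each subject's random-effect vector b_i is updated by a random-walk
  Metropolis step on its full conditional (the subject's longitudinal and
  survival contributions plus the random-effects density) — all subjects
  are proposed and accepted/rejected in one vectorised sweep;
* beta, gamma, alpha and the baseline-hazard coefficients move in separate
  random-walk blocks against the joint log-posterior;
* the random-effects covariance D is drawn from its conjugate
  inverse-Wishart conditional (with per-subject inverse-gamma mixing draws
  when the random effects are Student-t);
* sigma^2 is drawn from its conjugate inverse-gamma conditional;
* a recentering move translates each shared fixed effect and the matching
  random-effect column jointly along the likelihood-invariant direction
  (beta_j -> beta_j + d, b_ij -> b_ij - d); the conditional of the shift d
  is Gaussian, so this is an exact Gibbs draw. It decorrelates the fixed
  intercept/slope from the mean of the random effects, which random-walk
  updates alone mix slowly.

Proposal scales adapt by Robbins-Monro during burn-in (targets 0.25 for
vector blocks, 0.44 for scalars) and are frozen afterwards so the retained
chain satisfies detailed balance. A fixed seed gives bit-identical draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BaselineHazardCoefficients, SplineBasis
from .data_io import ValidatedDataset
from .likelihood import JointParameters, ModelData, ModelSpec, PriorSpec

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "FitSummary",
    "initialize_parameters",
    "fit_mcmc",
    "summarize_draws",
    "effective_sample_size",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 4000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0
    step_scales: dict = field(
        default_factory=lambda: {
            "b": 0.5,
            "beta": 0.05,
            "gamma": 0.1,
            "alpha": 0.1,
            "baseline": 0.1,
        }
    )
    adapt: bool = True
    keep_random_effects: bool = False

    def __post_init__(self):
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained MCMC output: one row per kept iteration."""

    draws: pd.DataFrame
    acceptance: dict
    seed: int
    spec: ModelSpec
    basis: SplineBasis
    n_subjects: int
    n_records: int
    b_mean: np.ndarray  # posterior mean of random effects, (n, q)
    b_draws: np.ndarray | None = None  # (kept, n, q), memory-gated

    def covariance(self) -> pd.DataFrame:
        """Posterior covariance of the scalar parameters."""
        c = np.cov(self.draws.to_numpy(), rowvar=False)
        return pd.DataFrame(c, index=self.draws.columns, columns=self.draws.columns)


@dataclass
class FitSummary:
    """Per-parameter posterior mean / s.d. / central 95% interval."""

    table: pd.DataFrame  # index: parameter; columns: mean, sd, q2.5, q97.5, ess
    n_subjects: int
    n_records: int

    @property
    def means(self) -> pd.Series:
        return self.table["mean"]


def _param_names(md: ModelData, spec: ModelSpec, n_spline: int):
    names = [f"beta_{lab}" for lab in spec.fixed_design]
    names += [f"gamma_{j}" for j in range(md.p_w)]
    names += ["alpha", "sigma", "gamma0_0"]
    names += [f"gamma0_{j + 1}" for j in range(n_spline)]
    q = md.q_ran
    names += [f"D_{i}_{j}" for i in range(q) for j in range(i + 1)]
    return names


def initialize_parameters(
    data: ValidatedDataset, spec: ModelSpec, basis: SplineBasis,
    _md: ModelData | None = None,
) -> JointParameters:
    """Deterministic starting point from simple moment/OLS estimates.

    beta comes from pooled OLS of the outcome on the fixed design; D from
    the spread of per-subject OLS coefficients around the pooled fit
    (diagonal, floored at 0.01); sigma from the pooled residual s.d.; the
    baseline log-hazard intercept from the occurrence/exposure rate
    log(events / total follow-up); gamma, alpha and the spline coefficients
    start at zero.
    """
    md = _md if _md is not None else ModelData(data, spec, basis)
    if md.delta.sum() == 0:
        raise ValueError(
            "no events in the data; the survival submodel cannot be "
            "initialised — supply more data or merge chunks"
        )
    X = md.Vfix[md.rec_subj].copy()
    if md.tfix is not None:
        X[:, md.tfix] = md.rec_t
    beta, *_ = np.linalg.lstsq(X, md.rec_y, rcond=None)
    resid = md.rec_y - X @ beta
    sigma = max(float(resid.std()), 0.01)

    # per-subject OLS of residuals on the random design -> moment estimate of D
    q = md.q_ran
    coefs = []
    for i in range(md.n):
        mask = md.rec_subj == i
        if mask.sum() <= q:
            continue
        Z = md.Vran[i][None, :].repeat(mask.sum(), axis=0)
        if md.tran is not None:
            Z[:, md.tran] = md.rec_t[mask]
        bi, *_ = np.linalg.lstsq(Z, resid[mask], rcond=None)
        coefs.append(bi)
    if coefs:
        d_diag = np.maximum(np.var(np.asarray(coefs), axis=0), 0.01)
    else:
        d_diag = np.full(q, 0.01)
    D = np.diag(d_diag)

    g0 = float(np.log(md.delta.sum() / md.T.sum()))
    return JointParameters(
        beta=beta,
        random_effects=np.zeros((md.n, q)),
        D=D,
        sigma=sigma,
        gamma=np.zeros(md.p_w),
        alpha=0.0,
        baseline=BaselineHazardCoefficients(
            intercept=g0, spline_coefs=np.zeros(md.basis.n_free_coefs)
        ),
    )


class _Adapter:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, scale: float, target: float):
        self.log_scale = np.log(scale)
        self.target = target
        self.count = 0

    def step(self, accepted: float):
        self.count += 1
        gain = 1.0 / self.count**0.6
        self.log_scale += gain * (accepted - self.target)

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))


def _re_logpdf_mix(b, D_inv, logdet_D, lam):
    """Per-subject log N(b_i; 0, lam_i * D) under the scale-mixture view."""
    quad = np.einsum("ij,jk,ik->i", b, D_inv, b)
    q = b.shape[1]
    return -0.5 * (q * (_LOG_2PI + np.log(lam)) + logdet_D + quad / lam)


def fit_mcmc(
    data: ValidatedDataset,
    spec: ModelSpec,
    priors: PriorSpec,
    basis: SplineBasis,
    mcmc: McmcConfig,
    _md: ModelData | None = None,
    init: JointParameters | None = None,
    update_blocks: tuple[str, ...] = (
        "b", "beta", "gamma", "alpha", "baseline", "sigma", "D", "recenter",
    ),
) -> PosteriorDraws:
    """Sample the joint posterior on one data chunk.

    ``update_blocks`` restricts which parameter blocks move; freezing all
    but ``b`` turns the sampler into a draw from the random-effects
    conditional, which has a closed form in the Gaussian no-association
    case and is used as a correctness oracle.
    """
    md = _md if _md is not None else ModelData(data, spec, basis)
    rng = np.random.default_rng(mcmc.seed)
    params = init if init is not None else initialize_parameters(data, spec, basis, _md=md)

    n, q, p = md.n, md.q_ran, md.p_fix
    n_spline = basis.n_free_coefs
    beta = params.beta.copy()
    b = params.random_effects.copy()
    D = params.D.copy()
    sigma = float(params.sigma)
    gamma = params.gamma.copy()
    alpha = float(params.alpha)
    base = np.concatenate([[params.baseline.intercept], params.baseline.spline_coefs])
    lam = np.ones(n)  # Student-t mixing scales; stays 1 for normal REs
    student = spec.re_distribution == "student_t"
    shared_cols = [
        (j, list(spec.fixed_design).index(lab))
        for j, lab in enumerate(spec.random_design)
        if lab in spec.fixed_design
    ]

    prior_sd = priors.normal_sd_fixed

    def _baseline_obj(vec):
        return BaselineHazardCoefficients(intercept=vec[0], spline_coefs=vec[1:])

    def surv_by_subject(eta0, eta1, gamma_, alpha_, base_):
        return md.surv_loglik_by_subject(eta0, eta1, gamma_, alpha_, _baseline_obj(base_))

    D_inv = np.linalg.inv(D)
    logdet_D = float(np.linalg.slogdet(D)[1])

    eta0, eta1 = md.eta_coefs(beta, b)
    long_i = md.long_loglik_by_subject(eta0, eta1, sigma)
    surv_i = surv_by_subject(eta0, eta1, gamma, alpha, base)
    re_i = _re_logpdf_mix(b, D_inv, logdet_D, lam)

    # divergence guard: jitter the start until the posterior is finite
    tries = 0
    while not np.isfinite(long_i.sum() + surv_i.sum() + re_i.sum()):
        tries += 1
        if tries > 100:
            raise RuntimeError(
                "log-posterior not finite at initialization after 100 jitter "
                "attempts; check the data scaling"
            )
        beta = params.beta + 0.1 * rng.standard_normal(p)
        b = 0.1 * rng.standard_normal((n, q))
        eta0, eta1 = md.eta_coefs(beta, b)
        long_i = md.long_loglik_by_subject(eta0, eta1, sigma)
        surv_i = surv_by_subject(eta0, eta1, gamma, alpha, base)
        re_i = _re_logpdf_mix(b, D_inv, logdet_D, lam)

    targets = {"b": 0.25, "beta": 0.25, "gamma": 0.44 if md.p_w == 1 else 0.25,
               "alpha": 0.44, "baseline": 0.25}
    adapters = {
        k: _Adapter(mcmc.step_scales.get(k, 0.1), targets[k]) for k in targets
    }
    acc_counts = {k: 0 for k in targets}
    block_iters = {k: 0 for k in targets}

    kept = (mcmc.n_iter - mcmc.n_burnin) // mcmc.thin
    names = _param_names(md, spec, n_spline)
    out = np.empty((kept, len(names)))
    b_store = (
        np.empty((kept, n, q)) if mcmc.keep_random_effects else None
    )
    b_accum = np.zeros((n, q))
    k_out = 0

    a0, b0 = priors.sigma2_shape, priors.sigma2_rate
    df_wish0 = q + 1
    S0 = priors.d_prior_scale * np.eye(q)

    for it in range(mcmc.n_iter):
        adapting = mcmc.adapt and it < mcmc.n_burnin

        # --- subject random effects, vectorised sweep -----------------------
        if "b" in update_blocks:
            s_b = adapters["b"].scale
            b_prop = b + s_b * rng.standard_normal((n, q))
            e0p, e1p = md.eta_coefs(beta, b_prop)
            long_p = md.long_loglik_by_subject(e0p, e1p, sigma)
            surv_p = surv_by_subject(e0p, e1p, gamma, alpha, base)
            re_p = _re_logpdf_mix(b_prop, D_inv, logdet_D, lam)
            log_ratio = (long_p + surv_p + re_p) - (long_i + surv_i + re_i)
            accept = np.log(rng.random(n)) < log_ratio
            if accept.any():
                b[accept] = b_prop[accept]
                eta0[accept], eta1[accept] = e0p[accept], e1p[accept]
                long_i[accept] = long_p[accept]
                surv_i[accept] = surv_p[accept]
                re_i[accept] = re_p[accept]
            rate = float(accept.mean())
            if adapting:
                adapters["b"].step(rate)
            else:
                acc_counts["b"] += rate
                block_iters["b"] += 1

        # --- fixed-effect and hazard blocks ---------------------------------
        def _mh_block(name, cur_vec, apply_fn, prior_cur, prior_prop_fn):
            nonlocal eta0, eta1, long_i, surv_i
            s = adapters[name].scale
            dim = len(cur_vec)
            prop = cur_vec + s / np.sqrt(dim) * rng.standard_normal(dim)
            new_state = apply_fn(prop)
            if new_state is None:
                u = rng.random()  # keep the random stream aligned
                if adapting:
                    adapters[name].step(0.0)
                else:
                    block_iters[name] += 1
                return cur_vec
            lr = new_state["delta_ll"] + prior_prop_fn(prop) - prior_cur(cur_vec)
            accepted = np.log(rng.random()) < lr
            if accepted:
                new_state["commit"]()
                cur_vec = prop
            if adapting:
                adapters[name].step(1.0 if accepted else 0.0)
            else:
                acc_counts[name] += 1.0 if accepted else 0.0
                block_iters[name] += 1
            return cur_vec

        def _norm_prior(vec):
            return -0.5 * np.sum(np.asarray(vec) ** 2) / prior_sd**2

        # beta block: both likelihood terms change
        def _apply_beta(prop):
            e0p, e1p = md.eta_coefs(prop, b)
            lp = md.long_loglik_by_subject(e0p, e1p, sigma)
            sp = surv_by_subject(e0p, e1p, gamma, alpha, base)
            dll = (lp.sum() + sp.sum()) - (long_i.sum() + surv_i.sum())
            if not np.isfinite(dll):
                return None

            def commit():
                nonlocal eta0, eta1, long_i, surv_i
                eta0, eta1, long_i, surv_i = e0p, e1p, lp, sp

            return {"delta_ll": dll, "commit": commit}

        if "beta" in update_blocks:
            beta = _mh_block("beta", beta, _apply_beta, _norm_prior, _norm_prior)

        # gamma block: survival only
        if md.p_w and "gamma" in update_blocks:
            def _apply_gamma(prop):
                sp = surv_by_subject(eta0, eta1, prop, alpha, base)
                dll = sp.sum() - surv_i.sum()
                if not np.isfinite(dll):
                    return None

                def commit():
                    nonlocal surv_i
                    surv_i = sp

                return {"delta_ll": dll, "commit": commit}

            gamma = _mh_block("gamma", gamma, _apply_gamma, _norm_prior, _norm_prior)

        # alpha block: survival only
        def _apply_alpha(prop):
            sp = surv_by_subject(eta0, eta1, gamma, float(prop[0]), base)
            dll = sp.sum() - surv_i.sum()
            if not np.isfinite(dll):
                return None

            def commit():
                nonlocal surv_i
                surv_i = sp

            return {"delta_ll": dll, "commit": commit}

        if "alpha" in update_blocks:
            alpha = float(
                _mh_block(
                    "alpha", np.array([alpha]), _apply_alpha, _norm_prior, _norm_prior
                )[0]
            )

        # baseline-hazard block (intercept + spline coefficients jointly)
        def _apply_base(prop):
            sp = surv_by_subject(eta0, eta1, gamma, alpha, prop)
            dll = sp.sum() - surv_i.sum()
            if not np.isfinite(dll):
                return None

            def commit():
                nonlocal surv_i
                surv_i = sp

            return {"delta_ll": dll, "commit": commit}

        if "baseline" in update_blocks:
            base = _mh_block("baseline", base, _apply_base, _norm_prior, _norm_prior)

        # --- recentering: shift beta_j and random-effect column j jointly ---
        # eta is invariant under (beta_j + d, b_:,j - d) when fixed and
        # random designs share the label, so only the priors constrain d and
        # its conditional is Gaussian: an exact Gibbs draw.
        for j_ran, j_fix in (shared_cols if "recenter" in update_blocks else []):
            inv_lam = 1.0 / lam
            prec = float(np.sum(inv_lam)) * D_inv[j_ran, j_ran] + 1.0 / prior_sd**2
            lin = float(inv_lam @ (b @ D_inv[:, j_ran])) - beta[j_fix] / prior_sd**2
            d_shift = lin / prec + rng.standard_normal() / np.sqrt(prec)
            beta[j_fix] += d_shift
            b[:, j_ran] -= d_shift
            re_i = _re_logpdf_mix(b, D_inv, logdet_D, lam)

        # --- conjugate sigma^2 ----------------------------------------------
        if "sigma" in update_blocks:
            r = md.resid(eta0, eta1)
            ss = float(r @ r)
            shape = a0 + 0.5 * md.n_records
            rate_ = b0 + 0.5 * ss
            sigma = float(np.sqrt(rate_ / rng.gamma(shape)))
            long_i = md.long_loglik_by_subject(eta0, eta1, sigma)

        if "D" in update_blocks:
            # Student-t mixing scales, then the conjugate inverse-Wishart draw
            if student:
                quad = np.einsum("ij,jk,ik->i", b, D_inv, b)
                lam = (spec.df + quad) / (
                    2.0 * rng.gamma((spec.df + q) / 2.0, size=n)
                )
            bs = b / np.sqrt(lam)[:, None]
            S = S0 + bs.T @ bs
            D = stats.invwishart.rvs(df=df_wish0 + n, scale=S, random_state=rng)
            D = np.atleast_2d(D)
            D_inv = np.linalg.inv(D)
            logdet_D = float(np.linalg.slogdet(D)[1])
            re_i = _re_logpdf_mix(b, D_inv, logdet_D, lam)

        # --- record ----------------------------------------------------------
        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
            tri = D[np.tril_indices(q)]
            out[k_out] = np.concatenate([beta, gamma, [alpha, sigma], base, tri])
            b_accum += b
            if b_store is not None:
                b_store[k_out] = b
            k_out += 1

    draws = pd.DataFrame(out[:k_out], columns=names)
    acceptance = {
        k: (acc_counts[k] / block_iters[k] if block_iters[k] else float("nan"))
        for k in targets
    }
    return PosteriorDraws(
        draws=draws,
        acceptance=acceptance,
        seed=mcmc.seed,
        spec=spec,
        basis=basis,
        n_subjects=md.n,
        n_records=md.n_records,
        b_mean=b_accum / max(k_out, 1),
        b_draws=b_store[:k_out] if b_store is not None else None,
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    if m < 4 or np.var(x) == 0:
        return float(m)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[m - 1 :] / (np.arange(m, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, m - 1, 2):
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        s += pair
    return float(m / (1.0 + 2.0 * s))


def summarize_draws(draws: PosteriorDraws) -> FitSummary:
    """Posterior mean, s.d., central 95% interval and ESS per parameter."""
    df = draws.draws
    if len(df) < 10:
        raise ValueError(f"need at least 10 retained draws, got {len(df)}")
    table = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1),
            "q2.5": df.quantile(0.025),
            "q97.5": df.quantile(0.975),
            "ess": [effective_sample_size(df[c].to_numpy()) for c in df.columns],
        }
    )
    return FitSummary(
        table=table, n_subjects=draws.n_subjects, n_records=draws.n_records
    )
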