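"""Joint log-likelihood, priors and log-posterior kernel.

The longitudinal submodel is a Gaussian linear mixed model with linear
predictor eta_i(t) = x_i(t)' beta + z_i(t)' b_i (identity link); the
survival submodel is a proportional-hazards model whose hazard couples to
the current value of the linear predictor:

    h_i(t) = h0(t) exp(gamma' w_i + alpha * eta_i(t))

with log h0(t) a B-spline expansion. The unnormalised log-posterior adds
normal priors on the regression blocks, an inverse-Wishart prior on the
random-effects covariance D, an inverse-gamma prior on sigma^2, and the
random-effects density (normal or multivariate Student-t) itself.

Design vectors are affine in time: each label in ``fixed_design`` /
``random_design`` is ``intercept``, ``time`` or the name of a subject-level
covariate column, so eta_i(t) always reduces to an intercept plus slope per
subject — the property the vectorised likelihood exploits.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import (
    BaselineHazardCoefficients,
    SplineBasis,
    bspline_basis,
    gauss_legendre_nodes,
)
from .data_io import ValidatedDataset

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "JointParameters",
    "linear_predictor",
    "longitudinal_loglik",
    "survival_loglik",
    "log_prior",
    "log_posterior",
    "ModelData",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of the joint model.

    Only the Gaussian family with identity link is implemented end-to-end;
    the seam exists so other exponential-family responses could be added.
    The association is the current value alpha * eta_i(t).
    """

    fixed_design: tuple[str, ...] = ("intercept", "time")
    random_design: tuple[str, ...] = ("intercept", "time")
    family: str = "gaussian"
    link: str = "identity"
    association: str = "current_value"
    re_distribution: str = "normal"
    df: int = 4

    def __post_init__(self):
        if self.family != "gaussian" or self.link != "identity":
            raise ValueError("only the gaussian family with identity link is supported")
        if self.association != "current_value":
            raise ValueError("only the current_value association is supported")
        if self.re_distribution not in ("normal", "student_t"):
            raise ValueError("re_distribution must be 'normal' or 'student_t'")
        if self.re_distribution == "student_t" and self.df <= 2:
            raise ValueError("student_t random effects require df > 2")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weakly-informative default priors.

    Zero-mean normals with s.d. ``normal_sd_fixed`` on beta, gamma, alpha
    and the baseline-hazard coefficients; inverse-Wishart(dim(b)+1, I) on
    D; inverse-gamma(0.01, 0.01) on sigma^2.
    """

    normal_sd_fixed: float = 10.0
    d_prior_scale: float = 1.0
    sigma2_shape: float = 0.01
    sigma2_rate: float = 0.01

    def __post_init__(self):
        if min(self.normal_sd_fixed, self.d_prior_scale,
               self.sigma2_shape, self.sigma2_rate) <= 0:
            raise ValueError("all prior hyperparameters must be > 0")


@dataclass(frozen=True)
class JointParameters:
    """One point in the joint parameter space.

    ``random_effects`` has one row per subject, aligned with the survival
    table's row order.
    """

    beta: np.ndarray
    random_effects: np.ndarray
    D: np.ndarray
    sigma: float
    gamma: np.ndarray
    alpha: float
    baseline: BaselineHazardCoefficients

    def __post_init__(self):
        for name in ("beta", "random_effects", "D", "gamma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


def linear_predictor(x, z, beta, b) -> float:
    """eta = x' beta + z' b."""
    x, z, beta, b = (np.asarray(v, dtype=float) for v in (x, z, beta, b))
    if x.shape != beta.shape or z.shape != b.shape:
        raise ValueError(
            f"design/coefficient shape mismatch: x{x.shape} beta{beta.shape} "
            f"z{z.shape} b{b.shape}"
        )
    return float(x @ beta + z @ b)


def _design_constants(ds: ValidatedDataset, labels: tuple[str, ...]):
    """Per-subject constant design matrix with the time column zeroed.

    Returns (V, time_idx) where eta-contribution(s) = V @ coef + s * coef[time_idx].
    Covariates must be constant within subject (they enter the hazard at
    arbitrary times, so a per-record value would be ill-defined).
    """
    surv = ds.survival.records
    n = len(surv)
    long = ds.longitudinal.records
    first = long.groupby("subject_id", sort=False).first()
    first = first.reindex(surv["subject_id"])
    V = np.zeros((n, len(labels)))
    time_idx = None
    for j, lab in enumerate(labels):
        if lab == "intercept":
            V[:, j] = 1.0
        elif lab == "time":
            time_idx = j
        else:
            if lab not in long.columns:
                raise ValueError(f"design label {lab!r} not a longitudinal column")
            per_subj = long.groupby("subject_id")[lab].nunique()
            if (per_subj > 1).any():
                raise ValueError(
                    f"design covariate {lab!r} varies within subject; "
                    "only subject-constant design covariates are supported"
                )
            V[:, j] = first[lab].to_numpy()
    return V, time_idx


class ModelData:
    """Precomputed arrays for fast repeated likelihood evaluation.

    Everything that depends only on the data and the spline basis — record
    groupings, design constants, the basis at the observed times and at the
    per-subject Gauss-Legendre nodes — is computed once here. All likelihood
    code, including the MCMC sampler, runs off these arrays.
    """

    def __init__(self, ds: ValidatedDataset, spec: ModelSpec, basis: SplineBasis):
        self.spec = spec
        self.basis = basis
        surv = ds.survival.records
        long = ds.longitudinal.records
        self.ids = surv["subject_id"].to_numpy()
        self.n = len(surv)
        id_pos = {sid: k for k, sid in enumerate(self.ids)}

        self.rec_subj = long["subject_id"].map(id_pos).to_numpy(dtype=np.intp)
        self.rec_t = long["time"].to_numpy(dtype=float)
        self.rec_y = long["outcome"].to_numpy(dtype=float)
        self.n_records = len(long)
        self.rec_count = np.bincount(self.rec_subj, minlength=self.n).astype(float)

        self.T = surv["observed_time"].to_numpy(dtype=float)
        self.delta = surv["event"].to_numpy(dtype=float)
        covs = ds.survival.covariates
        self.W = (
            surv[list(covs)].to_numpy(dtype=float)
            if covs
            else np.zeros((self.n, 0))
        )

        self.Vfix, self.tfix = _design_constants(ds, spec.fixed_design)
        self.Vran, self.tran = _design_constants(ds, spec.random_design)
        self.p_fix = self.Vfix.shape[1]
        self.q_ran = self.Vran.shape[1]
        self.p_w = self.W.shape[1]

        # quadrature nodes/weights for H_i(0, T_i): 15 Gauss-Legendre nodes
        # per knot panel, zero-weight padded to a common width
        per_subj = [gauss_legendre_nodes(basis, 0.0, t) for t in self.T]
        width = max(len(nt) for nt, _ in per_subj)
        self.node_t = np.zeros((self.n, width))
        self.node_w = np.zeros((self.n, width))
        for i, (nt, nw) in enumerate(per_subj):
            self.node_t[i, : len(nt)] = nt
            self.node_w[i, : len(nw)] = nw
        # spline basis without the dropped first column
        self.B_T = bspline_basis(self.T, basis)[:, 1:]
        self.B_nodes = bspline_basis(self.node_t, basis)[:, :, 1:]

    # -- linear predictor as per-subject intercept + slope ------------------

    def eta_coefs(self, beta, b):
        """(eta0, eta1): eta_i(s) = eta0[i] + eta1[i] * s."""
        eta0 = self.Vfix @ beta + np.einsum("ij,ij->i", self.Vran, b)
        eta1 = np.zeros(self.n)
        if self.tfix is not None:
            eta1 += beta[self.tfix]
        if self.tran is not None:
            eta1 = eta1 + b[:, self.tran]
        return eta0, eta1

    # -- longitudinal ---------------------------------------------------------

    def resid(self, eta0, eta1):
        return self.rec_y - (eta0[self.rec_subj] + eta1[self.rec_subj] * self.rec_t)

    def long_loglik_by_subject(self, eta0, eta1, sigma):
        r = self.resid(eta0, eta1)
        ss = np.bincount(self.rec_subj, weights=r * r, minlength=self.n)
        return -0.5 * self.rec_count * (_LOG_2PI + 2.0 * np.log(sigma)) - ss / (
            2.0 * sigma**2
        )

    # -- survival -------------------------------------------------------------

    def surv_loglik_by_subject(self, eta0, eta1, gamma, alpha, baseline):
        g0, cs = baseline.intercept, baseline.spline_coefs
        wterm = self.W @ gamma if self.p_w else np.zeros(self.n)
        logh_T = g0 + self.B_T @ cs + wterm + alpha * (eta0 + eta1 * self.T)
        log_nodes = (
            g0
            + self.B_nodes @ cs
            + wterm[:, None]
            + alpha * (eta0[:, None] + eta1[:, None] * self.node_t)
        )
        with np.errstate(over="ignore"):
            H = np.sum(self.node_w * np.exp(log_nodes), axis=1)
        return self.delta * logh_T - H

    # -- random-effects density ----------------------------------------------

    def re_logpdf_by_subject(self, b, D):
        try:
            L = np.linalg.cholesky(D)
        except np.linalg.LinAlgError:
            return np.full(self.n, -np.inf)
        sol = np.linalg.solve(L, b.T)  # (q, n)
        quad = np.sum(sol * sol, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        q = b.shape[1]
        if self.spec.re_distribution == "normal":
            return -0.5 * (q * _LOG_2PI + logdet + quad)
        df = self.spec.df
        from scipy.special import gammaln

        const = (
            gammaln((df + q) / 2.0)
            - gammaln(df / 2.0)
            - 0.5 * q * np.log(df * np.pi)
            - 0.5 * logdet
        )
        return const - 0.5 * (df + q) * np.log1p(quad / df)


def _prepare(data: ValidatedDataset, spec: ModelSpec, basis: SplineBasis) -> ModelData:
    return ModelData(data, spec, basis)


def longitudinal_loglik(
    data: ValidatedDataset, params: JointParameters, spec: ModelSpec,
    _md: ModelData | None = None,
) -> float:
    """Gaussian log-likelihood of the biomarker records given the b_i."""
    if params.sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {params.sigma}")
    if _md is None:
        # basis irrelevant for the longitudinal part; build a trivial one
        tmax = float(data.survival.records["observed_time"].max())
        _md = ModelData(data, spec, SplineBasis((), (0.0, tmax), degree=0))
    eta0, eta1 = _md.eta_coefs(params.beta, params.random_effects)
    return float(np.sum(_md.long_loglik_by_subject(eta0, eta1, params.sigma)))


def survival_loglik(
    data: ValidatedDataset,
    params: JointParameters,
    spec: ModelSpec,
    basis: SplineBasis,
    _md: ModelData | None = None,
) -> float:
    """Sum over subjects of delta_i * log h_i(T_i) - H_i(0, T_i)."""
    if _md is None:
        _md = ModelData(data, spec, basis)
    eta0, eta1 = _md.eta_coefs(params.beta, params.random_effects)
    return float(
        np.sum(
            _md.surv_loglik_by_subject(
                eta0, eta1, params.gamma, params.alpha, params.baseline
            )
        )
    )


def log_prior(params: JointParameters, priors: PriorSpec, spec: ModelSpec) -> float:
    """Log prior density, including the random-effects term sum_i log p(b_i | D).

    Returns -inf for a non-positive-definite D (sampler sentinel).
    """
    sd = priors.normal_sd_fixed
    fixed = np.concatenate(
        [
            np.atleast_1d(params.beta),
            np.atleast_1d(params.gamma),
            [params.alpha, params.baseline.intercept],
            np.atleast_1d(params.baseline.spline_coefs),
        ]
    )
    lp = float(np.sum(stats.norm.logpdf(fixed, scale=sd)))

    D = params.D
    q = D.shape[0]
    try:
        np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        return -np.inf
    lp += float(
        stats.invwishart.logpdf(D, df=q + 1, scale=priors.d_prior_scale * np.eye(q))
    )
    lp += float(
        stats.invgamma.logpdf(
            params.sigma**2, priors.sigma2_shape, scale=priors.sigma2_rate
        )
    )

    b = params.random_effects
    if b.size:
        if spec.re_distribution == "normal":
            lp += float(np.sum(stats.multivariate_normal.logpdf(b, cov=D)))
        else:
            lp += float(np.sum(stats.multivariate_t.logpdf(b, shape=D, df=spec.df)))
    return lp


def log_posterior(
    data: ValidatedDataset,
    params: JointParameters,
    priors: PriorSpec,
    spec: ModelSpec,
    basis: SplineBasis,
    _md: ModelData | None = None,
) -> float:
    """Unnormalised log-posterior: likelihoods plus log prior."""
    lp = log_prior(params, priors, spec)
    if not np.isfinite(lp):
        return -np.inf
    if _md is None:
        _md = ModelData(data, spec, basis)
    return (
        longitudinal_loglik(data, params, spec, _md=_md)
        + survival_loglik(data, params, spec, basis, _md=_md)
        + lp
    )
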