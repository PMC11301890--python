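"""Subject-level dynamic predictions given biomarker history.

Given a fitted model (population parameters fixed at their pooled posterior
means — an empirical-Bayes simplification) and one subject's history up to
a landmark time s, the subject's random effects are sampled from

    p(b | history) ∝ p(b | D) * prod_l N(y_l | eta(t_l), sigma^2)
                               * exp(-H(0, s | b))

— the survival-to-landmark factor is included because the prediction is
conditional on being event-free at s. Conditional survival and trajectory
curves are then Monte-Carlo averages over those draws:

    S(u | s, b) = exp(-H(s, u | b)),    y(t | b) = x(t)' beta + z(t)' b.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .basis import (
    BaselineHazardCoefficients,
    SplineBasis,
    bspline_basis,
    gauss_legendre_nodes,
)
from .likelihood import ModelSpec
from .mcmc import FitSummary
from .pooling import PooledFit

__all__ = [
    "SubjectHistory",
    "DynamicPrediction",
    "point_parameters",
    "posterior_b_given_history",
    "predict_survival",
    "predict_trajectory",
    "predictions_to_frame",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SubjectHistory:
    """One subject's longitudinal records up to the landmark s.

    The subject is known to be event-free at s; all record times must be
    <= s.
    """

    subject_id: str
    times: np.ndarray
    outcomes: np.ndarray
    covariates: np.ndarray  # baseline covariates w_i
    landmark: float

    def __post_init__(self):
        for name in ("times", "outcomes", "covariates"):
            object.__setattr__(
                self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            )
        if self.landmark < 0:
            raise ValueError("landmark must be >= 0")
        if self.times.size and self.times.max() > self.landmark + 1e-12:
            raise ValueError(
                f"history of subject {self.subject_id} contains records after "
                f"the landmark {self.landmark}"
            )


@dataclass
class DynamicPrediction:
    subject_id: str
    landmark: float
    horizon: np.ndarray
    survival_mean: np.ndarray
    survival_lower: np.ndarray
    survival_upper: np.ndarray
    trajectory_grid: np.ndarray | None = None
    trajectory_mean: np.ndarray | None = None
    trajectory_lower: np.ndarray | None = None
    trajectory_upper: np.ndarray | None = None


@dataclass(frozen=True)
class _PointParams:
    beta: np.ndarray
    gamma: np.ndarray
    alpha: float
    sigma: float
    baseline: BaselineHazardCoefficients
    D: np.ndarray


def point_parameters(fit, spec: ModelSpec, basis: SplineBasis) -> _PointParams:
    """Extract posterior-mean population parameters from a fit object."""
    if isinstance(fit, PooledFit):
        means = fit.mean
    elif isinstance(fit, FitSummary):
        means = fit.means
    else:
        means = pd.Series(fit)
    beta = np.array([means[f"beta_{lab}"] for lab in spec.fixed_design])
    gamma = np.array(
        [means[k] for k in means.index if k.startswith("gamma_") and
         not k.startswith("gamma0_")]
    )
    n_spline = basis.n_free_coefs
    baseline = BaselineHazardCoefficients(
        intercept=float(means["gamma0_0"]),
        spline_coefs=np.array([means[f"gamma0_{j + 1}"] for j in range(n_spline)]),
    )
    q = len(spec.random_design)
    D = np.zeros((q, q))
    for i in range(q):
        for j in range(i + 1):
            D[i, j] = D[j, i] = means[f"D_{i}_{j}"]
    return _PointParams(
        beta=beta,
        gamma=gamma,
        alpha=float(means["alpha"]),
        sigma=float(means["sigma"]),
        baseline=baseline,
        D=D,
    )


def _design_consts(labels, w_lookup):
    """Constant part and time flag for an affine-in-time design."""
    const = []
    has_time = False
    for lab in labels:
        if lab == "intercept":
            const.append(1.0)
        elif lab == "time":
            const.append(0.0)
            has_time = True
        else:
            const.append(w_lookup(lab))
    return np.asarray(const), has_time


class _SubjectModel:
    """Cached per-subject quantities for b-posterior evaluation."""

    def __init__(self, history: SubjectHistory, pp: _PointParams,
                 spec: ModelSpec, basis: SplineBasis):
        self.pp = pp
        self.spec = spec
        self.basis = basis
        self.history = history
        # eta(t) = f0 + f1 t + b . (z0 + z1 t); extra design covariates are
        # not supported in prediction histories (subject covariates enter w)
        for lab in spec.fixed_design + spec.random_design:
            if lab not in ("intercept", "time"):
                raise ValueError(
                    "prediction supports intercept/time designs only; got "
                    f"label {lab!r}"
                )
        self.f0 = pp.beta[list(spec.fixed_design).index("intercept")] \
            if "intercept" in spec.fixed_design else 0.0
        self.f1 = pp.beta[list(spec.fixed_design).index("time")] \
            if "time" in spec.fixed_design else 0.0
        self.z_int = "intercept" in spec.random_design
        self.z_time = "time" in spec.random_design

        self.wterm = float(np.dot(pp.gamma, history.covariates)) \
            if pp.gamma.size else 0.0
        self.L = np.linalg.cholesky(pp.D)
        self.D_inv = np.linalg.inv(pp.D)
        self.logdet_D = float(np.linalg.slogdet(pp.D)[1])
        self.q = pp.D.shape[0]

        s = history.landmark
        if s > 0:
            self.nodes0, self.nw0 = gauss_legendre_nodes(basis, 0.0, s)
            B = bspline_basis(self.nodes0, basis)[:, 1:]
            self.logh0_nodes0 = (
                pp.baseline.intercept + B @ pp.baseline.spline_coefs + self.wterm
            )
        else:
            self.nodes0 = None

    def eta(self, t, b):
        """eta at times t (m,) for draws b (..., q) -> (..., m)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        base = self.f0 + self.f1 * t
        b = np.atleast_2d(b)
        out = np.broadcast_to(base, (b.shape[0], t.size)).copy()
        col = 0
        if self.z_int:
            out += b[:, [col]]
            col += 1
        if self.z_time:
            out += b[:, [col]] * t
        return out

    def log_target(self, b):
        """Unnormalised log p(b | history) for draws b (m, q) -> (m,)."""
        b = np.atleast_2d(b)
        quad = np.einsum("ij,jk,ik->i", b, self.D_inv, b)
        if self.spec.re_distribution == "normal":
            lp = -0.5 * (self.q * _LOG_2PI + self.logdet_D + quad)
        else:
            df = self.spec.df
            lp = (
                gammaln((df + self.q) / 2.0)
                - gammaln(df / 2.0)
                - 0.5 * self.q * np.log(df * np.pi)
                - 0.5 * self.logdet_D
                - 0.5 * (df + self.q) * np.log1p(quad / df)
            )
        h = self.history
        if h.times.size:
            eta = self.eta(h.times, b)
            r = h.outcomes[None, :] - eta
            lp = lp - 0.5 * np.sum(r * r, axis=1) / self.pp.sigma**2 \
                - 0.5 * h.times.size * (_LOG_2PI + 2 * np.log(self.pp.sigma))
        if self.nodes0 is not None:
            eta_n = self.eta(self.nodes0, b)
            H0 = np.sum(
                self.nw0 * np.exp(self.logh0_nodes0 + self.pp.alpha * eta_n), axis=1
            )
            lp = lp - H0
        return lp

    def cum_hazard_segment(self, t0: float, t1: float, b):
        """H(t0, t1 | b) for draws b (m, q) -> (m,)."""
        if t1 <= t0:
            return np.zeros(np.atleast_2d(b).shape[0])
        nodes, weights = gauss_legendre_nodes(self.basis, t0, t1)
        B = bspline_basis(nodes, self.basis)[:, 1:]
        logh0 = (
            self.pp.baseline.intercept + B @ self.pp.baseline.spline_coefs + self.wterm
        )
        eta_n = self.eta(nodes, b)
        return np.sum(weights * np.exp(logh0 + self.pp.alpha * eta_n), axis=1)


def posterior_b_given_history(
    history: SubjectHistory,
    fit,
    spec: ModelSpec,
    basis: SplineBasis,
    n_draws: int = 2000,
    seed: int = 0,
    n_burnin: int = 500,
) -> np.ndarray:
    """Random-walk Metropolis draws from p(b | history), shape (n_draws, q).

    Population parameters are held at the fit's posterior means. The scale
    adapts toward 25% acceptance during burn-in.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    pp = fit if isinstance(fit, _PointParams) else point_parameters(fit, spec, basis)
    sm = _SubjectModel(history, pp, spec, basis)
    rng = np.random.default_rng(seed)
    q = sm.q
    b = np.zeros(q)
    cur = float(sm.log_target(b)[0])
    scale = float(np.sqrt(np.trace(pp.D) / q))
    draws = np.empty((n_draws, q))
    kept = 0
    it = 0
    acc_win = 0
    while kept < n_draws:
        prop = b + scale * rng.standard_normal(q)
        lp = float(sm.log_target(prop)[0])
        if np.log(rng.random()) < lp - cur:
            b, cur = prop, lp
            acc_win += 1
        it += 1
        if it <= n_burnin:
            if it % 50 == 0:
                rate = acc_win / 50.0
                scale *= float(np.exp(rate - 0.25))
                acc_win = 0
        else:
            draws[kept] = b
            kept += 1
    return draws


def predict_survival(
    history: SubjectHistory,
    fit,
    spec: ModelSpec,
    basis: SplineBasis,
    horizon_grid,
    n_draws: int = 2000,
    seed: int = 0,
    b_draws: np.ndarray | None = None,
) -> DynamicPrediction:
    """Conditional survival S(u | s) with 95% pointwise credible bands.

    S(s | s) = 1 exactly; each horizon's survival is the Monte-Carlo
    average over b draws of exp(-H(s, u | b)).
    """
    grid = np.atleast_1d(np.asarray(horizon_grid, dtype=float))
    s = history.landmark
    if (grid < s - 1e-12).any():
        raise ValueError(f"horizon grid must start at the landmark s={s}")
    pp = fit if isinstance(fit, _PointParams) else point_parameters(fit, spec, basis)
    if b_draws is None:
        b_draws = posterior_b_given_history(
            history, pp, spec, basis, n_draws=n_draws, seed=seed
        )
    sm = _SubjectModel(history, pp, spec, basis)
    m = b_draws.shape[0]
    surv = np.empty((m, grid.size))
    H = np.zeros(m)
    prev = s
    order = np.argsort(grid)
    for j in order:
        u = grid[j]
        H = H + sm.cum_hazard_segment(prev, u, b_draws)
        prev = u
        surv[:, j] = np.exp(-H)
    return DynamicPrediction(
        subject_id=history.subject_id,
        landmark=s,
        horizon=grid,
        survival_mean=surv.mean(axis=0),
        survival_lower=np.quantile(surv, 0.025, axis=0),
        survival_upper=np.quantile(surv, 0.975, axis=0),
    )


def predict_trajectory(
    history: SubjectHistory,
    fit,
    spec: ModelSpec,
    basis: SplineBasis,
    time_grid,
    n_draws: int = 2000,
    seed: int = 0,
    b_draws: np.ndarray | None = None,
) -> DynamicPrediction:
    """Expected biomarker trajectory with 95% pointwise credible bands."""
    grid = np.atleast_1d(np.asarray(time_grid, dtype=float))
    if (grid < 0).any():
        raise ValueError("trajectory grid times must be >= 0")
    pp = fit if isinstance(fit, _PointParams) else point_parameters(fit, spec, basis)
    if b_draws is None:
        b_draws = posterior_b_given_history(
            history, pp, spec, basis, n_draws=n_draws, seed=seed
        )
    sm = _SubjectModel(history, pp, spec, basis)
    eta = sm.eta(grid, b_draws)  # (m, len(grid))
    return DynamicPrediction(
        subject_id=history.subject_id,
        landmark=history.landmark,
        horizon=grid,
        survival_mean=np.ones(grid.size),
        survival_lower=np.ones(grid.size),
        survival_upper=np.ones(grid.size),
        trajectory_grid=grid,
        trajectory_mean=eta.mean(axis=0),
        trajectory_lower=np.quantile(eta, 0.025, axis=0),
        trajectory_upper=np.quantile(eta, 0.975, axis=0),
    )


def risk_matrix(
    ds,
    fit,
    spec: ModelSpec,
    basis: SplineBasis,
    grid,
    n_draws: int = 300,
    seed: int = 0,
    landmark: float = 0.0,
):
    """Predicted survival for every subject in a dataset on a common grid.

    Builds each subject's history up to ``landmark`` (default baseline
    only) and returns an :class:`~bigjm.evaluation.RiskMatrix` suitable for
    the concordance / prediction-error curves.
    """
    from .evaluation import RiskMatrix

    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    pp = fit if isinstance(fit, _PointParams) else point_parameters(fit, spec, basis)
    surv_df = ds.survival.records
    rec = ds.longitudinal.records
    covs = list(ds.survival.covariates)
    S = np.empty((len(surv_df), grid.size))
    for k, row in enumerate(surv_df.itertuples()):
        sub = rec[(rec["subject_id"] == row.subject_id) & (rec["time"] <= landmark)]
        hist = SubjectHistory(
            subject_id=row.subject_id,
            times=sub["time"].to_numpy(),
            outcomes=sub["outcome"].to_numpy(),
            covariates=np.array([getattr(row, c) for c in covs], dtype=float),
            landmark=landmark,
        )
        p = predict_survival(
            hist, pp, spec, basis, grid, n_draws=n_draws, seed=seed + 7919 * k % 2_000_000
        )
        S[k] = p.survival_mean
    return RiskMatrix(
        subject_ids=surv_df["subject_id"].to_numpy(),
        grid=grid,
        values=S.clip(0.0, 1.0),
    )


def predictions_to_frame(preds: list[DynamicPrediction]) -> pd.DataFrame:
    """Tidy CSV-ready table: one row per subject x horizon x kind."""
    rows = []
    for p in preds:
        for u, m, lo, hi in zip(
            p.horizon, p.survival_mean, p.survival_lower, p.survival_upper
        ):
            rows.append((p.subject_id, p.landmark, u, m, lo, hi, "survival"))
        if p.trajectory_grid is not None:
            for u, m, lo, hi in zip(
                p.trajectory_grid, p.trajectory_mean,
                p.trajectory_lower, p.trajectory_upper,
            ):
                rows.append((p.subject_id, p.landmark, u, m, lo, hi, "trajectory"))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "landmark", "horizon", "mean", "lower", "upper", "kind"],
    )
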