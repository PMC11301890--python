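import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bigjm.basis import BaselineHazardCoefficients, SplineBasis
from bigjm.data_io import LongitudinalData, SurvivalData, validate_join
from bigjm.likelihood import (
    JointParameters,
    ModelSpec,
    PriorSpec,
    linear_predictor,
    log_posterior,
    log_prior,
    longitudinal_loglik,
    survival_loglik,
)

FLAT_BASIS = SplineBasis(interior_knots=(), boundary=(0.0, 10.0), degree=3)


def make_dataset(subjects, w_name=None):
    """subjects: list of (id, times, ys, T, delta[, w])."""
    long_rows, surv_rows = [], []
    for s in subjects:
        sid, times, ys, T, delta = s[:5]
        for t, y in zip(times, ys):
            long_rows.append((sid, float(t), float(y)))
        row = {"subject_id": sid, "observed_time": float(T), "event": int(delta)}
        if w_name:
            row[w_name] = float(s[5])
        surv_rows.append(row)
    long = LongitudinalData(records=pd.DataFrame(
        long_rows, columns=["subject_id", "time", "outcome"]))
    surv = SurvivalData(
        records=pd.DataFrame(surv_rows),
        covariates=(w_name,) if w_name else (),
    )
    return validate_join(long, surv)


def make_params(n, beta=(0.0, 0.0), b=None, D=None, sigma=1.0, gamma=(),
                alpha=0.0, g0=0.0, n_spline=3):
    return JointParameters(
        beta=np.asarray(beta, dtype=float),
        random_effects=np.zeros((n, 2)) if b is None else np.asarray(b, dtype=float),
        D=np.eye(2) if D is None else np.asarray(D, dtype=float),
        sigma=sigma,
        gamma=np.asarray(gamma, dtype=float),
        alpha=alpha,
        baseline=BaselineHazardCoefficients(g0, np.zeros(n_spline)),
    )


class TestLinearPredictor:
    def test_zero_coefficients(self):
        assert linear_predictor([1, 2], [1, 2], [0, 0], [0, 0]) == 0.0

    def test_hand_arithmetic(self):
        got = linear_predictor([1, 2], [1, 2], [0.5, 1], [0.1, -0.2])
        assert got == pytest.approx(2.2)

    def test_symmetric_in_block_order(self):
        x, beta = [1.0, 2.0], [0.5, 1.0]
        z, b = [1.0, 2.0], [0.1, -0.2]
        assert linear_predictor(x, z, beta, b) == linear_predictor(z, x, b, beta)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            linear_predictor([1.0], [1, 2], [0.5, 1.0], [0.1, -0.2])


class TestLongitudinalLoglik:
    def test_standard_normal_mode(self):
        ds = make_dataset([("1", [0.0], [0.0], 1.0, 1)])
        p = make_params(1)
        got = longitudinal_loglik(ds, p, ModelSpec())
        assert got == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_additive_over_observations(self):
        one = make_dataset([("1", [0.0], [0.3], 2.0, 1)])
        two = make_dataset([("1", [0.0, 1.0], [0.3, -0.4], 2.0, 1)])
        other = make_dataset([("1", [1.0], [-0.4], 2.0, 1)])
        p1 = make_params(1, sigma=0.7)
        got = longitudinal_loglik(two, p1, ModelSpec())
        expected = longitudinal_loglik(one, p1, ModelSpec()) + longitudinal_loglik(
            other, p1, ModelSpec()
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_normal_density_sum(self):
        ds = make_dataset(
            [("1", [0.0, 0.5, 1.0], [0.2, 0.5, 0.4], 2.0, 1),
             ("2", [0.0, 0.75], [-0.1, 0.6], 1.5, 0)]
        )
        b = np.array([[0.3, -0.1], [-0.2, 0.25]])
        p = make_params(2, beta=(0.1, 0.4), b=b, sigma=0.6)
        mu = {}
        for i, sid in enumerate(["1", "2"]):
            mu[sid] = lambda t, i=i: 0.1 + 0.4 * t + b[i, 0] + b[i, 1] * t
        expected = sum(
            stats.norm.logpdf(row.outcome, mu[row.subject_id](row.time), 0.6)
            for row in ds.longitudinal.records.itertuples()
        )
        got = longitudinal_loglik(ds, p, ModelSpec())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        ds = make_dataset([("1", [0.0], [0.0], 1.0, 1)])
        with pytest.raises(ValueError, match="sigma"):
            longitudinal_loglik(ds, make_params(1, sigma=0.0), ModelSpec())


class TestSurvivalLoglik:
    def test_event_with_constant_hazard(self):
        ds = make_dataset([("1", [0.0], [0.0], 1.0, 1)])
        p = make_params(1, g0=np.log(2.0))
        got = survival_loglik(ds, p, ModelSpec(), FLAT_BASIS)
        assert got == pytest.approx(np.log(2.0) - 2.0, abs=1e-10)

    def test_censored_subject_contributes_minus_cumhaz(self):
        ds = make_dataset([("1", [0.0], [0.0], 1.0, 0)])
        p = make_params(1, g0=np.log(2.0))
        got = survival_loglik(ds, p, ModelSpec(), FLAT_BASIS)
        assert got == pytest.approx(-2.0, abs=1e-10)

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(3)
        subjects = []
        for i in range(10):
            T = float(rng.uniform(0.5, 3.0))
            subjects.append(
                (f"s{i}", [0.0, T / 2], list(rng.normal(0, 1, 2)), T,
                 int(rng.random() < 0.6), float(rng.normal()))
            )
        ds = make_dataset(subjects, w_name="w1")
        b = rng.normal(0, 0.3, (10, 2))
        p = make_params(
            10, beta=(0.4, 0.25), b=b, sigma=0.5, gamma=(0.3,), alpha=0.7,
            g0=-0.8,
        )
        got = survival_loglik(ds, p, ModelSpec(), FLAT_BASIS)

        expected = 0.0
        surv = ds.survival.records
        for i, row in enumerate(surv.itertuples()):
            eta0 = 0.4 + b[i, 0]
            eta1 = 0.25 + b[i, 1]
            logh = lambda s: -0.8 + 0.3 * row.w1 + 0.7 * (eta0 + eta1 * s)
            grid = np.linspace(0.0, row.observed_time, 100_000)
            H = np.trapezoid(np.exp(logh(grid)), grid)
            expected += row.event * logh(row.observed_time) - H
        assert got == pytest.approx(expected, abs=1e-5)


class TestLogPrior:
    def test_hand_sum_at_origin(self):
        p = make_params(0, n_spline=3)
        got = log_prior(p, PriorSpec(normal_sd_fixed=1.0), ModelSpec())
        # 2 beta + alpha + g0 + 3 spline = 7 standard-normal terms at 0
        fixed_part = 7 * stats.norm.logpdf(0.0)
        rest = stats.invwishart.logpdf(np.eye(2), df=3, scale=np.eye(2)) + \
            stats.invgamma.logpdf(1.0, 0.01, scale=0.01)
        assert got == pytest.approx(fixed_part + rest, abs=1e-10)

    def test_doubling_prior_sd_lowers_each_term_by_log2(self):
        p = make_params(0, n_spline=3)
        lp1 = log_prior(p, PriorSpec(normal_sd_fixed=1.0), ModelSpec())
        lp2 = log_prior(p, PriorSpec(normal_sd_fixed=2.0), ModelSpec())
        assert lp1 - lp2 == pytest.approx(7 * np.log(2.0), abs=1e-10)

    def test_random_effects_contribution_at_zero(self):
        p0 = make_params(0)
        p3 = make_params(3)
        diff = log_prior(p3, PriorSpec(), ModelSpec()) - log_prior(
            p0, PriorSpec(), ModelSpec()
        )
        assert diff == pytest.approx(-3 * np.log(2 * np.pi), abs=1e-10)

    def test_non_positive_definite_D_gives_minus_inf(self):
        p = make_params(2, D=[[1.0, 2.0], [2.0, 1.0]])
        assert log_prior(p, PriorSpec(), ModelSpec()) == -np.inf


class TestLogPosterior:
    def _fixture(self):
        ds = make_dataset(
            [("1", [0.0, 0.5], [0.2, 0.5], 1.0, 1, 0.5),
             ("2", [0.0], [-0.3], 0.8, 0, -1.0)],
            w_name="w1",
        )
        p = make_params(2, beta=(0.1, 0.2), sigma=0.5, gamma=(0.3,), alpha=0.4,
                        g0=-0.5)
        return ds, p

    def test_additivity_of_components(self):
        ds, p = self._fixture()
        spec, priors = ModelSpec(), PriorSpec()
        total = log_posterior(ds, p, priors, spec, FLAT_BASIS)
        parts = (
            longitudinal_loglik(ds, p, spec)
            + survival_loglik(ds, p, spec, FLAT_BASIS)
            + log_prior(p, priors, spec)
        )
        assert total == pytest.approx(parts, abs=1e-10)

    def test_flat_prior_limit_matches_likelihood_differences(self):
        ds, p1 = self._fixture()
        p2 = make_params(2, beta=(0.3, 0.1), sigma=0.5, gamma=(0.1,), alpha=0.2,
                         g0=-0.7)
        spec = ModelSpec()
        priors = PriorSpec(normal_sd_fixed=1e8)
        dpost = log_posterior(ds, p1, priors, spec, FLAT_BASIS) - log_posterior(
            ds, p2, priors, spec, FLAT_BASIS
        )
        dlik = (
            longitudinal_loglik(ds, p1, spec)
            + survival_loglik(ds, p1, spec, FLAT_BASIS)
            - longitudinal_loglik(ds, p2, spec)
            - survival_loglik(ds, p2, spec, FLAT_BASIS)
        )
        assert dpost == pytest.approx(dlik, abs=1e-8)

    def test_finite_at_simulator_truth(self, ds_small, basis_small):
        n = ds_small.n_subjects
        p = make_params(
            n, beta=(0.5, 0.3), D=[[0.4, 0.0], [0.0, 0.04]], sigma=0.3,
            gamma=(0.4,), alpha=0.6, g0=-0.7,
            n_spline=basis_small.n_free_coefs,
        )
        lp = log_posterior(ds_small, p, PriorSpec(), ModelSpec(), basis_small)
        assert np.isfinite(lp)

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(4)
        subjects = [
            (f"s{i:02d}", [0.0, 0.4], list(rng.normal(0, 1, 2)),
             float(rng.uniform(0.5, 2.0)), int(rng.random() < 0.5),
             float(rng.normal()))
            for i in range(20)
        ]
        b = rng.normal(0, 0.3, (20, 2))
        params = dict(beta=(0.2, 0.1), sigma=0.4, gamma=(0.3,), alpha=0.5, g0=-0.6)
        ds1 = make_dataset(subjects, w_name="w1")
        p1 = make_params(20, b=b, **params)
        perm = rng.permutation(20)
        ds2 = make_dataset([subjects[k] for k in perm], w_name="w1")
        p2 = make_params(20, b=b[perm], **params)
        spec, priors = ModelSpec(), PriorSpec()
        lp1 = log_posterior(ds1, p1, priors, spec, FLAT_BASIS)
        lp2 = log_posterior(ds2, p2, priors, spec, FLAT_BASIS)
        assert lp1 == pytest.approx(lp2, abs=1e-10)

    def test_null_association_separates_submodels(self):
        ds, _ = self._fixture()
        spec, priors = ModelSpec(), PriorSpec()
        base = dict(beta=(0.1, 0.2), sigma=0.5, alpha=0.0, g0=-0.5)
        for b_val in (np.zeros((2, 2)), np.full((2, 2), 0.3)):
            d = log_posterior(
                ds, make_params(2, gamma=(0.3,), b=b_val, **base), priors, spec,
                FLAT_BASIS,
            ) - log_posterior(
                ds, make_params(2, gamma=(0.9,), b=b_val, **base), priors, spec,
                FLAT_BASIS,
            )
            if b_val.sum() == 0:
                first = d
        # the gamma-effect on the posterior is identical whatever b is:
        assert d == pytest.approx(first, abs=1e-9)

    def test_conditional_of_b_matches_mixed_model_formula(self):
        # alpha = 0: the survival term drops out of b's conditional, which is
        # then the standard Gaussian mixed-model posterior
        times = np.array([0.0, 0.5, 1.0, 1.5])
        y = np.array([0.4, 0.9, 0.8, 1.4])
        ds = make_dataset([("1", times, y, 2.0, 1)])
        beta = np.array([0.2, 0.3])
        sigma, D = 0.5, np.diag([0.4, 0.1])
        Z = np.column_stack([np.ones_like(times), times])
        r = y - Z @ beta
        C = np.linalg.inv(Z.T @ Z / sigma**2 + np.linalg.inv(D))
        mean = C @ Z.T @ r / sigma**2

        spec, priors = ModelSpec(), PriorSpec()
        rng = np.random.default_rng(5)
        for _ in range(5):
            u, v = rng.normal(0, 0.5, (2, 2))
            pu = make_params(1, beta=beta, b=u[None, :], D=D, sigma=sigma)
            pv = make_params(1, beta=beta, b=v[None, :], D=D, sigma=sigma)
            d_post = log_posterior(ds, pu, priors, spec, FLAT_BASIS) - log_posterior(
                ds, pv, priors, spec, FLAT_BASIS
            )
            d_exact = stats.multivariate_normal.logpdf(
                u, mean, C
            ) - stats.multivariate_normal.logpdf(v, mean, C)
            assert d_post == pytest.approx(d_exact, abs=1e-8)
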