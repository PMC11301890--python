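import numpy as np
import pytest

from bigjm.basis import BaselineHazardCoefficients, SplineBasis, place_knots
from bigjm.data_io import validate_join
from bigjm.likelihood import ModelSpec
from bigjm.prediction import (
    SubjectHistory,
    _PointParams,
    posterior_b_given_history,
    predict_survival,
    predict_trajectory,
    risk_matrix,
)

FLAT_BASIS = SplineBasis(interior_knots=(), boundary=(0.0, 10.0), degree=3)


def flat_params(alpha=0.0, g0=-0.5, D=None, sigma=0.3, beta=(0.5, 0.3), gamma=()):
    return _PointParams(
        beta=np.asarray(beta, dtype=float),
        gamma=np.asarray(gamma, dtype=float),
        alpha=alpha,
        sigma=sigma,
        baseline=BaselineHazardCoefficients(g0, np.zeros(3)),
        D=np.diag([0.4, 0.04]) if D is None else np.asarray(D, dtype=float),
    )


def history(times=(), ys=(), landmark=0.0, w=()):
    return SubjectHistory(
        subject_id="x", times=np.asarray(times, dtype=float),
        outcomes=np.asarray(ys, dtype=float),
        covariates=np.asarray(w, dtype=float), landmark=landmark,
    )


class TestPosteriorB:
    def test_prior_sampling_without_history(self):
        # alpha = 0, no records, s = 0: the target is exactly N(0, D)
        pp = flat_params()
        draws = posterior_b_given_history(
            history(), pp, ModelSpec(), FLAT_BASIS, n_draws=4000, seed=1
        )
        d = np.diag(pp.D)
        np.testing.assert_array_less(
            np.abs(draws.mean(axis=0)), 3 * np.sqrt(d / 4000) * 5
        )  # factor 5 slack for RW autocorrelation
        np.testing.assert_allclose(draws.std(axis=0), np.sqrt(d), rtol=0.15)

    def test_matches_conjugate_gaussian_posterior(self):
        rng = np.random.default_rng(2)
        pp = flat_params()
        times = np.array([0.0, 0.5, 1.0, 1.5])
        b_true = np.array([0.6, -0.1])
        y = (pp.beta[0] + b_true[0]) + (pp.beta[1] + b_true[1]) * times
        y = y + pp.sigma * rng.standard_normal(times.size)
        h = history(times, y, landmark=1.5)
        draws = posterior_b_given_history(
            h, pp, ModelSpec(), FLAT_BASIS, n_draws=5000, seed=3
        )
        Z = np.column_stack([np.ones_like(times), times])
        r = y - Z @ pp.beta
        C = np.linalg.inv(Z.T @ Z / pp.sigma**2 + np.linalg.inv(pp.D))
        mean = C @ Z.T @ r / pp.sigma**2
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.05)
        np.testing.assert_allclose(draws.std(axis=0), np.sqrt(np.diag(C)), rtol=0.10)

    def test_seeded_draws_reproducible(self):
        pp = flat_params(alpha=0.4)
        h = history([0.0, 0.5], [0.4, 0.6], landmark=0.5)
        d1 = posterior_b_given_history(h, pp, ModelSpec(), FLAT_BASIS, 500, seed=9)
        d2 = posterior_b_given_history(h, pp, ModelSpec(), FLAT_BASIS, 500, seed=9)
        np.testing.assert_array_equal(d1, d2)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            posterior_b_given_history(
                history(), flat_params(), ModelSpec(), FLAT_BASIS, n_draws=50
            )


class TestPredictSurvival:
    def test_survival_at_landmark_is_one(self):
        pp = flat_params()
        h = history([0.0], [0.5], landmark=1.0)
        p = predict_survival(h, pp, ModelSpec(), FLAT_BASIS, [1.0, 1.5, 2.0],
                             n_draws=200, seed=4)
        assert p.survival_mean[0] == 1.0
        assert p.survival_lower[0] == 1.0 and p.survival_upper[0] == 1.0

    def test_constant_hazard_closed_form(self):
        # alpha = 0, log h0 = log 2: S(s+1 | s) = exp(-2)
        pp = flat_params(alpha=0.0, g0=np.log(2.0))
        h = history(landmark=1.0)
        p = predict_survival(h, pp, ModelSpec(), FLAT_BASIS, [1.0, 2.0],
                             n_draws=200, seed=5)
        assert p.survival_mean[1] == pytest.approx(np.exp(-2.0), abs=1e-6)

    def test_horizon_before_landmark_rejected(self):
        with pytest.raises(ValueError, match="landmark"):
            predict_survival(
                history(landmark=2.0), flat_params(), ModelSpec(), FLAT_BASIS,
                [1.0], n_draws=200,
            )

    def test_matches_dense_grid_hazard_integration(self):
        pp = flat_params(alpha=0.7, g0=-0.6, gamma=(0.3,))
        h = history([0.0, 0.4], [0.7, 0.9], landmark=0.5, w=(0.8,))
        b = posterior_b_given_history(h, pp, ModelSpec(), FLAT_BASIS, 300, seed=6)
        p = predict_survival(h, pp, ModelSpec(), FLAT_BASIS, [0.5, 1.4],
                             b_draws=b)
        grid = np.linspace(0.5, 1.4, 100_000)
        eta = (pp.beta[0] + b[:, [0]]) + (pp.beta[1] + b[:, [1]]) * grid[None, :]
        logh = -0.6 + 0.3 * 0.8 + 0.7 * eta
        H = np.trapezoid(np.exp(logh), grid, axis=1)
        expected = np.exp(-H).mean()
        assert p.survival_mean[1] == pytest.approx(expected, abs=1e-4)

    def test_chained_landmarks_telescope_with_common_draws(self):
        pp = flat_params(alpha=0.5, g0=-0.4)
        spec = ModelSpec()
        for b_val in ([0.3, -0.1], [0.0, 0.2], [-0.5, 0.0]):
            b = np.asarray([b_val])
            s, s2, u = 0.5, 1.2, 2.5
            S_su = predict_survival(history(landmark=s), pp, spec, FLAT_BASIS,
                                    [s, u], b_draws=b).survival_mean[1]
            S_ss2 = predict_survival(history(landmark=s), pp, spec, FLAT_BASIS,
                                     [s, s2], b_draws=b).survival_mean[1]
            S_s2u = predict_survival(history(landmark=s2), pp, spec, FLAT_BASIS,
                                     [s2, u], b_draws=b).survival_mean[1]
            assert S_su == pytest.approx(S_ss2 * S_s2u, abs=1e-8)

    def test_monotone_in_horizon_across_cohort(self, fitted_small):
        long, surv, _, pooled = fitted_small
        ds = validate_join(long, surv)
        grid = np.linspace(0.25, 2.5, 8)
        risk = risk_matrix(ds, pooled, ModelSpec(), pooled.basis, grid,
                           n_draws=150, seed=2)
        sub = risk.values[:50]
        assert (np.diff(sub, axis=1) <= 1e-12).all()


class TestPredictTrajectory:
    def test_degenerate_b_gives_fixed_effect_line(self):
        pp = flat_params()
        h = history([0.0], [0.5], landmark=0.5)
        grid = np.array([0.0, 1.0, 2.0])
        p = predict_trajectory(h, pp, ModelSpec(), FLAT_BASIS, grid,
                               b_draws=np.zeros((1, 2)))
        np.testing.assert_allclose(p.trajectory_mean, 0.5 + 0.3 * grid, atol=1e-12)
        np.testing.assert_allclose(p.trajectory_lower, p.trajectory_mean)

    def test_bands_widen_beyond_observed_history(self):
        rng = np.random.default_rng(7)
        pp = flat_params()
        times = np.arange(0.0, 1.01, 0.25)
        y = 0.5 + 0.3 * times + 0.3 * rng.standard_normal(times.size)
        h = history(times, y, landmark=1.0)
        p = predict_trajectory(h, pp, ModelSpec(), FLAT_BASIS,
                               [0.5, 2.5], n_draws=2000, seed=8)
        w = p.trajectory_upper - p.trajectory_lower
        assert w[1] >= w[0]

    def test_band_covers_true_trajectory_on_recovery_fixture(self, fitted_small):
        long, surv, truth, pooled = fitted_small
        ds = validate_join(long, surv)
        spec = ModelSpec()
        b_true = truth.random_effects
        ids = list(surv.records["subject_id"])
        rec = ds.longitudinal.records
        covered = total = 0
        for i in range(0, 40):
            sid = ids[i]
            sub = rec[rec["subject_id"] == sid]
            s = float(sub["time"].max())
            w = surv.records.loc[
                surv.records.subject_id == sid, list(surv.covariates)
            ].to_numpy()[0]
            h = SubjectHistory(sid, sub["time"].to_numpy(),
                               sub["outcome"].to_numpy(), w, landmark=s)
            grid = sub["time"].to_numpy()
            p = predict_trajectory(h, pooled, spec, pooled.basis, grid,
                                   n_draws=400, seed=100 + i)
            eta_true = (truth.beta[0] + b_true[i, 0]) + (
                truth.beta[1] + b_true[i, 1]
            ) * grid
            covered += int(
                ((p.trajectory_lower <= eta_true) & (eta_true <= p.trajectory_upper)).sum()
            )
            total += grid.size
        assert covered / total >= 0.85

    def test_trajectory_close_to_precise_observations(self):
        # many low-noise observations pin the subject's line down
        rng = np.random.default_rng(10)
        pp = flat_params(sigma=0.05)
        times = np.arange(0.0, 2.01, 0.1)
        b_true = np.array([0.4, -0.15])
        y = (0.5 + b_true[0]) + (0.3 + b_true[1]) * times
        y = y + 0.05 * rng.standard_normal(times.size)
        h = history(times, y, landmark=2.0)
        p = predict_trajectory(h, pp, ModelSpec(), FLAT_BASIS, [1.0],
                               n_draws=1000, seed=11)
        obs_at_1 = y[np.argmin(np.abs(times - 1.0))]
        assert abs(p.trajectory_mean[0] - obs_at_1) <= 3 * 0.05 + 0.05
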