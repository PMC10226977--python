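import math

import numpy as np
import pytest

from aftclock.data_model import CohortDataset, Marker
from aftclock.aft_model import (
    AFTParameters,
    AFTPosterior,
    COVARIATE_NAMES,
    DEFAULT_MARKERS,
    MCMCConfig,
    ModelSpec,
    ProgressionCurve,
    _corr_forward,
    _corr_logp_grad,
    _Posterior,
    _prepare_data,
    adjustment_correlation,
    evaluate_curve,
    extract_adjustments,
    fit_aft,
    log_likelihood,
    percent_variance_explained,
    shifted_age,
)
from aftclock.splines import MonotoneBasis
from aftclock.synthetic import CohortConfig, generate_cohort

from conftest import make_participant, obs


def _basic_params(n, basis=None, u=None, markers=DEFAULT_MARKERS, seed=0):
    basis = basis or MonotoneBasis()
    rng = np.random.default_rng(seed)
    curves = {
        m: ProgressionCurve(m, basis, rng.uniform(0.0, 0.2, basis.n_basis), 0.3)
        for m in markers
    }
    K = len(markers)
    return AFTParameters(
        curves=curves,
        beta=np.zeros((K, 5)),
        u=np.zeros((n, K)) if u is None else u,
        tau=np.full(K, 5.0),
        R=np.eye(K),
        sigma=np.full(K, 0.5),
        markers=markers,
    )


class TestShiftedAge:
    def test_reference_person_is_unshifted(self):
        assert shifted_age(70.0, np.zeros(5), np.zeros(5), 0.0) == 70.0

    def test_carrier_effect_adds_years(self):
        x = np.array([1.0, 0, 0, 0, 0])
        beta_k = np.array([9.0, 0, 0, 0, 0])
        assert shifted_age(70.0, x, beta_k, 0.0) == pytest.approx(79.0)

    def test_negative_adjustment_subtracts_years(self):
        assert shifted_age(70.0, np.zeros(5), np.zeros(5), -4.0) == pytest.approx(66.0)


class TestEvaluateCurve:
    def test_zero_weights_give_flat_intercept(self):
        basis = MonotoneBasis()
        c = ProgressionCurve(Marker.WMH_PCT, basis, np.zeros(basis.n_basis), 1.25)
        t = np.linspace(30, 120, 50)
        assert np.allclose(evaluate_curve(c, t), 1.25)

    def test_flat_extension_below_support(self):
        basis = MonotoneBasis()
        c = ProgressionCurve(
            Marker.AMYLOID_PET, basis, np.full(basis.n_basis, 0.1), 0.2
        )
        assert evaluate_curve(c, basis.lo - 20.0) == pytest.approx(
            evaluate_curve(c, basis.lo)
        )

    def test_curve_value_matches_quadrature_of_derivative(self):
        from scipy.integrate import quad

        basis = MonotoneBasis(n_interior=1)  # 2+ basis functions, cheap quad
        w = np.array([1.0, 1.0, 0.5, 0.25, 0.0][: basis.n_basis])
        c = ProgressionCurve(Marker.TAU_PET, basis, w, 0.0)
        mid = 0.5 * (basis.lo + basis.hi)
        integral, _ = quad(lambda x: c.derivative(x), basis.lo, mid, limit=300)
        assert integral == pytest.approx(evaluate_curve(c, mid), abs=1e-6)

    def test_nondecreasing_for_nonnegative_weights(self):
        basis = MonotoneBasis()
        rng = np.random.default_rng(4)
        c = ProgressionCurve(
            Marker.TAU_PET, basis, rng.uniform(0, 1, basis.n_basis), -1.0
        )
        t = np.linspace(20, 130, 500)
        assert np.all(np.diff(evaluate_curve(c, t)) >= -1e-12)


class TestLogLikelihood:
    def _one_obs_dataset(self, value, marker=Marker.WMH_PCT, age=75.0):
        return CohortDataset(
            observations=[obs("p", marker, age, max(value, 0.0), transformed=value)],
            covariates=[make_participant("p")],
        )

    def test_observation_on_curve_with_unit_sigma(self):
        params = _basic_params(1)
        params.sigma[:] = 1.0
        mu = params.curves[Marker.WMH_PCT].evaluate(75.0)
        ds = self._one_obs_dataset(float(mu))
        assert log_likelihood(ds, params) == pytest.approx(
            -0.5 * math.log(2 * math.pi), abs=1e-12
        )

    def test_duplicating_observations_doubles_the_value(self):
        ds, _ = generate_cohort(CohortConfig(n_participants=6, seed=1))
        params = _basic_params(6)
        base = log_likelihood(ds, params)
        doubled = CohortDataset(
            observations=ds.observations
            + [
                obs(o.participant_id, o.marker, o.age + 1e-4, o.raw_value,
                    o.transformed_value)
                for o in ds.observations
            ],
            covariates=ds.covariates,
        )
        assert log_likelihood(doubled, params) == pytest.approx(2 * base, rel=1e-6)

    def test_matches_brute_force_normal_density_sum(self):
        """Joint likelihood equals the naive per-observation sum (1e-10)."""
        from scipy.stats import norm

        ds, truth = generate_cohort(CohortConfig(n_participants=4, seed=3))
        ds = CohortDataset(ds.observations[:10], ds.covariates)
        params = _basic_params(4, seed=5)
        from aftclock.aft_model import build_covariate_matrix

        X, ids, _ = build_covariate_matrix(ds, params.education_center)
        pid = {p: i for i, p in enumerate(ids)}
        mk = {m: k for k, m in enumerate(params.markers)}
        expected = 0.0
        for o in ds.observations:
            k = mk[o.marker]
            t = o.age + X[pid[o.participant_id]] @ params.beta[k] + params.u[
                pid[o.participant_id], k
            ]
            mu = params.curves[o.marker].evaluate(float(t))
            expected += norm.logpdf(o.transformed_value, mu, params.sigma[k])
        assert log_likelihood(ds, params) == pytest.approx(expected, abs=1e-10)

    def test_non_finite_contribution_names_the_observation(self):
        # a finite but astronomically large residual overflows the
        # quadratic form; the error must identify the offending row
        params = _basic_params(1)
        ds = self._one_obs_dataset(1e200)
        with pytest.raises(ValueError, match="participant=p"):
            log_likelihood(ds, params)

    def test_translation_invariance_under_matched_u_and_knot_shift(self):
        """Shifting one marker's u by delta and its knots to compensate
        leaves the likelihood unchanged — the zero-mean prior on u is what
        pins the time origin."""
        ds, _ = generate_cohort(CohortConfig(n_participants=8, seed=6))
        base = _basic_params(8, seed=7)
        delta = 5.0
        k = 1  # tau PET
        u2 = base.u.copy()
        u2[:, k] += delta
        curves2 = dict(base.curves)
        m = base.markers[k]
        curves2[m] = ProgressionCurve(
            m, base.curves[m].basis.shifted(delta), base.curves[m].weights,
            base.curves[m].intercept,
        )
        shifted = AFTParameters(
            curves=curves2, beta=base.beta, u=u2, tau=base.tau, R=base.R,
            sigma=base.sigma, markers=base.markers,
        )
        assert log_likelihood(ds, shifted) == pytest.approx(
            log_likelihood(ds, base), abs=1e-8
        )


class TestCorrelationTransform:
    def test_forward_produces_valid_cholesky(self):
        rng = np.random.default_rng(0)
        for K in (2, 3, 4, 5):
            y = rng.normal(0, 1.2, K * (K - 1) // 2)
            L, _ = _corr_forward(y, K)
            R = L @ L.T
            assert np.allclose(np.diag(R), 1.0)
            assert np.all(np.linalg.eigvalsh(R) > 0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        K = 4
        T = K * (K - 1) // 2
        y = rng.normal(0, 0.8, T)
        dL = np.tril(rng.normal(0, 1, (K, K)))

        def f(yv):
            logp, _, L = _corr_logp_grad(yv, K, np.zeros((K, K)))
            return logp + float(np.sum(dL * L))

        _, grad, _ = _corr_logp_grad(y, K, dL)
        eps = 1e-6
        for i in range(T):
            yp, ym = y.copy(), y.copy()
            yp[i] += eps
            ym[i] -= eps
            fd = (f(yp) - f(ym)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-6)


class TestPosteriorGradient:
    def test_joint_log_density_gradient_matches_finite_differences(self):
        ds, _ = generate_cohort(CohortConfig(n_participants=12, seed=9))
        spec = ModelSpec(min_participants_per_marker=1)
        post = _Posterior(_prepare_data(ds, spec.markers), spec)
        rng = np.random.default_rng(2)
        theta = post.initial_point(rng) + 0.2 * rng.standard_normal(post.dim)
        lp, g = post.logp_grad(theta)
        assert np.isfinite(lp)
        eps = 1e-6
        idx = rng.choice(post.dim, size=60, replace=False)
        for i in idx:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (post.logp_grad(tp)[0] - post.logp_grad(tm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=2e-4, abs=2e-4)


class TestPercentVariance:
    @pytest.mark.parametrize(
        "r,expected,digits",
        [(0.57, 32.0, 0), (0.07, 0.5, 1), (0.0, 0.0, 6)],
    )
    def test_published_rounding(self, r, expected, digits):
        assert round(percent_variance_explained(r), digits) == expected

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            percent_variance_explained(1.2)


def _degenerate_posterior(n=3, r12=0.5, u_val=3.0):
    """Posterior whose draws are all identical — for summary-logic tests."""
    K = len(DEFAULT_MARKERS)
    basis = MonotoneBasis()
    C, S = 2, 10
    R = np.eye(K)
    R[0, 1] = R[1, 0] = r12
    avail = np.ones((n, K), dtype=bool)
    avail[0, 1] = False  # participant 0 never had tau PET
    return AFTPosterior(
        markers=DEFAULT_MARKERS,
        covariate_names=COVARIATE_NAMES,
        participant_ids=[f"p{i}" for i in range(n)],
        basis=basis,
        education_center=14.0,
        availability=avail,
        intercept=np.zeros((C, S, K)),
        weights=np.full((C, S, K, basis.n_basis), 0.05),
        beta=np.zeros((C, S, K, 5)),
        tau=np.full((C, S, K), 5.0),
        sigma=np.full((C, S, K), 0.3),
        R=np.broadcast_to(R, (C, S, K, K)).copy(),
        u=np.full((C, S, n, K), u_val),
    )


class TestSummaries:
    def test_degenerate_draws_give_point_mass_summaries(self):
        post = _degenerate_posterior(r12=0.5)
        corr = adjustment_correlation(post)
        row = corr[(corr.marker_1 == "amyloid_pet") & (corr.marker_2 == "tau_pet")]
        assert float(row["mean"].iloc[0]) == pytest.approx(0.5)
        assert float(row["ci_low"].iloc[0]) == pytest.approx(0.5)
        assert float(row["ci_high"].iloc[0]) == pytest.approx(0.5)

    def test_symmetric_draws_straddle_zero(self):
        post = _degenerate_posterior(r12=0.0)
        post.R[0, :, 0, 1] = 0.4
        post.R[0, :, 1, 0] = 0.4
        post.R[1, :, 0, 1] = -0.4
        post.R[1, :, 1, 0] = -0.4
        corr = adjustment_correlation(post)
        row = corr[(corr.marker_1 == "amyloid_pet") & (corr.marker_2 == "tau_pet")]
        assert float(row["ci_low"].iloc[0]) < 0 < float(row["ci_high"].iloc[0])

    def test_prior_only_adjustments_are_excluded(self):
        post = _degenerate_posterior(u_val=3.0)
        adj = extract_adjustments(post)
        assert adj[(adj.participant_id == "p0") & (adj.marker == "tau_pet")].empty
        row = adj[(adj.participant_id == "p1") & (adj.marker == "tau_pet")]
        assert float(row["mean"].iloc[0]) == pytest.approx(3.0)
        assert float(row["ci_low"].iloc[0]) == pytest.approx(3.0)


class TestFitApi:
    def test_identical_seeds_give_identical_draws(self):
        ds, _ = generate_cohort(CohortConfig(n_participants=40, seed=13))
        cfg = MCMCConfig(chains=1, warmup=60, draws=30, max_depth=5)
        a = fit_aft(ds, mcmc_config=cfg, seed=3)
        b = fit_aft(ds, mcmc_config=cfg, seed=3)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.R, b.R)

    def test_needs_at_least_two_markers(self):
        ds, _ = generate_cohort(CohortConfig(n_participants=30, seed=13))
        with pytest.raises(ValueError, match="at least 2"):
            fit_aft(ds, model_spec=ModelSpec(markers=(Marker.AMYLOID_PET,)))

    def test_sparse_marker_coverage_rejected(self):
        ds, _ = generate_cohort(CohortConfig(n_participants=25, seed=14))
        with pytest.raises(ValueError, match="tau_pet"):
            fit_aft(ds, model_spec=ModelSpec(min_participants_per_marker=25))

    def test_near_noiseless_fit_recovers_curve_and_adjustments(self):
        """With tiny residual noise and small shifts, the posterior mean
        curve tracks the generating curve and per-person adjustments land
        within +-1.5 years."""
        cfg = CohortConfig(
            n_participants=80,
            seed=19,
            tau=np.full(4, 0.3),
            sigma=np.array([0.01, 0.01, 0.02, 0.002]),
            beta=np.zeros((4, 5)),
        )
        ds, truth = generate_cohort(cfg)
        post = fit_aft(
            ds,
            mcmc_config=MCMCConfig(chains=1, warmup=250, draws=200, max_depth=6),
            seed=23,
        )
        params = post.mean_parameters()
        # curve accuracy over the age range the data covers
        ages = np.array([o.age for o in ds.observations])
        grid = np.linspace(np.percentile(ages, 5), np.percentile(ages, 95), 40)
        for k, m in enumerate(post.markers):
            fitted = params.curves[m].evaluate(grid)
            true_vals = truth.curves[m](grid)
            assert np.max(np.abs(fitted - true_vals)) < 0.05, m
        # adjustment accuracy for participants observed on the marker
        err = np.abs(params.u - truth.u)[post.availability]
        assert np.mean(err) < 1.5

    def test_missing_marker_masked_in_posterior(self, small_fit):
        dataset, truth, posterior = small_fit
        has_tau = {
            o.participant_id
            for o in dataset.observations
            if o.marker is Marker.TAU_PET
        }
        adj = extract_adjustments(posterior)
        tau_rows = set(adj[adj.marker == "tau_pet"].participant_id)
        assert tau_rows == has_tau

    def test_posterior_curves_nondecreasing_in_every_draw(self, small_fit):
        _, _, posterior = small_fit
        t = np.linspace(posterior.basis.lo, posterior.basis.hi, 60)
        D = posterior.basis.design(t)
        flat = posterior._flat(posterior.weights)
        rng = np.random.default_rng(0)
        for s in rng.choice(flat.shape[0], 25, replace=False):
            for k in range(len(posterior.markers)):
                vals = D @ flat[s, k]
                assert np.all(np.diff(vals) >= -1e-10)
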