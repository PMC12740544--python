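"""Mixed-effects engine: joint likelihood, Laplace approximation, fitting."""

import math

import numpy as np
import pytest
from scipy import stats

from dosim.nlmem import (
    CohortDataset,
    FitConfig,
    PopulationModel,
    SOEFStructural,
    SubjectRecord,
    conditional_neg2ll,
    estimate_individual,
    fit_population,
    individual_params,
    initial_model_heuristic,
    joint_neg2ll,
    laplace_subject_neg2ll,
    marginal_neg2ll,
)
from dosim.nlmem import _batch_marginal_neg2ll, _joint_parts
from dosim.kinetics import soef_eval
from dosim.simulate import SimulationConfig, generate_cohort


class LinearStructural:
    """Toy model linear in a single random effect: f(t) = theta + eta."""

    n_params = 1

    def map_params(self, theta, eta):
        return theta + eta

    def map_jacobian(self, theta, eta, p):
        return np.ones_like(p)

    def map_hess_diag(self, theta, eta, p):
        return np.zeros_like(p)

    def derivs(self, p, t, order=2):
        k = t.size
        f = np.full(k, p[0])
        fp = np.ones((k, 1)) if order >= 1 else None
        fpp = np.zeros((k, 1, 1)) if order >= 2 else None
        return f, fp, fpp

    def predict(self, p, t):
        return self.derivs(p, t, 0)[0]


@pytest.fixture()
def pop_model(default_truth_model):
    return default_truth_model


@pytest.fixture()
def one_subject(example_params):
    times = np.array([1.8, 18.7, 42.6, 66.3, 160.3])
    y = soef_eval(example_params, times)
    return SubjectRecord("S1", times, y, tp_labels=("TP1", "TP2", "TP3", "TP4", "TP5"))


class TestIndividualParams:
    def test_zero_eta_identity(self):
        theta = np.array([0.02, 0.01, 0.025, 0.005, 0.05, 2.0])
        assert np.allclose(individual_params(theta, np.zeros(6)).as_array(), theta)

    def test_ln2_doubles(self):
        theta = np.ones(6)
        p = individual_params(theta, np.full(6, math.log(2.0)))
        assert np.allclose(p.as_array(), 2.0 * theta)

    def test_scalar_exponential(self):
        p = individual_params(np.ones(6), np.full(6, 0.1))
        assert np.allclose(p.as_array(), math.exp(0.1))

    def test_positive_by_construction(self):
        rng = np.random.default_rng(0)
        p = individual_params(
            np.array([0.02, 0.01, 0.025, 0.005, 0.05, 2.0]),
            rng.normal(0, 3, 6),
        )
        assert np.all(p.as_array() > 0)


class TestJointNeg2LL:
    def test_gaussian_density_oracle(self, pop_model, one_subject, example_params):
        """The joint -2LL is the sum of observation and prior Gaussian terms."""
        rng = np.random.default_rng(2)
        eta = rng.normal(0, 0.2, 6)
        p = pop_model.theta * np.exp(eta)
        f = soef_eval(
            individual_params(pop_model.theta, eta), one_subject.times
        )
        obs_ll = stats.norm.logpdf(
            one_subject.activity, loc=f, scale=pop_model.sigma * np.abs(f)
        ).sum()
        prior_ll = stats.norm.logpdf(
            eta, loc=0.0, scale=np.sqrt(pop_model.omega)
        ).sum()
        oracle = -2.0 * (obs_ll + prior_ll)
        assert joint_neg2ll(pop_model, one_subject, eta) == pytest.approx(
            oracle, rel=1e-12
        )

    def test_unit_standardized_residual(self, pop_model, one_subject):
        """Shifting one observation by +sigma*f adds exactly 1 to the -2LL."""
        base = joint_neg2ll(pop_model, one_subject, np.zeros(6))
        y = one_subject.activity.copy()
        y[2] = y[2] * (1.0 + pop_model.sigma)
        shifted = SubjectRecord("S1", one_subject.times, y)
        assert joint_neg2ll(pop_model, shifted, np.zeros(6)) == pytest.approx(
            base + 1.0, abs=1e-9
        )

    def test_analytic_gradient_and_hessian(self, pop_model, one_subject):
        rng = np.random.default_rng(9)
        eta = rng.normal(0, 0.3, 6)
        struct = SOEFStructural()
        args = (
            pop_model.theta, pop_model.omega, pop_model.sigma,
            one_subject.times, one_subject.activity,
        )
        _, grad, hess = _joint_parts(
            *args, eta, struct, "proportional", 1e-9, 0.0, order=2
        )
        h = 1e-6
        for i in range(6):
            e = np.zeros(6)
            e[i] = h
            vp, gp, _ = _joint_parts(
                *args, eta + e, struct, "proportional", 1e-9, 0.0, order=1
            )
            vm, gm, _ = _joint_parts(
                *args, eta - e, struct, "proportional", 1e-9, 0.0, order=1
            )
            assert grad[i] == pytest.approx((vp - vm) / (2 * h), rel=1e-5, abs=1e-7)
            assert np.allclose(hess[i], (gp - gm) / (2 * h), rtol=1e-4, atol=1e-6)


class TestLaplace:
    def test_exact_for_linear_gaussian_single_obs(self):
        model = PopulationModel(
            theta=np.array([2.0]), omega=np.array([0.25]), sigma=0.3,
            error_model="additive",
        )
        sub = SubjectRecord("T", np.array([1.0]), np.array([2.7]))
        val, eta, hess = laplace_subject_neg2ll(
            model, sub, structural=LinearStructural()
        )
        var = 0.25 + 0.3**2
        exact = math.log(2 * math.pi * var) + (2.7 - 2.0) ** 2 / var
        assert val == pytest.approx(exact, abs=1e-8)

    def test_exact_for_linear_gaussian_multi_obs(self):
        model = PopulationModel(
            theta=np.array([2.0]), omega=np.array([0.25]), sigma=0.3,
            error_model="additive",
        )
        y = np.array([2.7, 1.5, 2.2])
        sub = SubjectRecord("T", np.array([1.0, 2.0, 3.0]), y)
        val, _, _ = laplace_subject_neg2ll(model, sub, structural=LinearStructural())
        # closed-form marginal: y ~ N(theta*1, sigma^2 I + omega * 1 1')
        c = 0.3**2 * np.eye(3) + 0.25 * np.ones((3, 3))
        r = y - 2.0
        exact = math.log(np.linalg.det(2 * math.pi * c)) + float(
            r @ np.linalg.solve(c, r)
        )
        assert val == pytest.approx(exact, abs=1e-8)

    def test_matches_numeric_integration_1d(self):
        """Laplace within 1% of trapezoid integration for a peaked posterior."""
        model = PopulationModel(
            theta=np.array([1.0]), omega=np.array([0.04]), sigma=0.1,
        )
        sub = SubjectRecord("T", np.array([1.0, 2.0]), np.array([1.1, 0.95]))
        struct = LinearStructural()
        val, _, _ = laplace_subject_neg2ll(model, sub, structural=struct)
        grid = np.linspace(-1.5, 1.5, 4001)
        joint = np.array(
            [joint_neg2ll(model, sub, np.array([g]), structural=struct) for g in grid]
        )
        integral = np.trapezoid(np.exp(-0.5 * joint), grid)
        oracle = -2.0 * math.log(integral)
        assert val == pytest.approx(oracle, rel=0.01)

    def test_degenerate_prior_limit(self, one_subject, pop_model):
        """As Omega -> 0 the marginal collapses to the conditional at eta=0."""
        model = PopulationModel(
            theta=pop_model.theta, omega=np.full(6, 1e-12), sigma=pop_model.sigma
        )
        val, _, _ = laplace_subject_neg2ll(model, one_subject)
        cond = conditional_neg2ll(model, one_subject, np.zeros(6))
        assert val == pytest.approx(cond, abs=1e-6)


class TestMarginal:
    def test_single_subject(self, pop_model, one_subject):
        ds = CohortDataset([one_subject])
        total = marginal_neg2ll(pop_model, ds)
        per, _, _ = laplace_subject_neg2ll(pop_model, one_subject)
        assert total == pytest.approx(per, rel=1e-12)

    def test_additive_over_duplicated_subject(self, pop_model, one_subject):
        import dataclasses

        twin = dataclasses.replace(one_subject, subject_id="S2")
        ds = CohortDataset([one_subject, twin])
        single = marginal_neg2ll(pop_model, CohortDataset([one_subject]))
        assert marginal_neg2ll(pop_model, ds) == pytest.approx(2 * single, rel=1e-12)

    def test_batch_path_matches_per_subject(self, pop_model, small_cohort):
        dataset, _, _ = small_cohort
        t_mat = np.stack([s.times for s in dataset.subjects])
        y_mat = np.stack([s.activity for s in dataset.subjects])
        total, _ = _batch_marginal_neg2ll(
            pop_model, t_mat, y_mat, None, 1e-9, SOEFStructural().consts
        )
        assert total == pytest.approx(marginal_neg2ll(pop_model, dataset), rel=1e-9)


class TestFitPopulation:
    def test_refuses_insufficient_degrees_of_freedom(self, pop_model):
        times = np.array([1.8, 18.7, 42.6, 66.3, 160.3])
        subjects = [
            SubjectRecord(f"S{i}", times, soef_eval_params(pop_model, times))
            for i in range(2)
        ]
        ds = CohortDataset(subjects)  # 10 observations < 13 + 1
        with pytest.raises(ValueError, match="degrees of freedom"):
            fit_population(ds, pop_model, FitConfig(n_starts=1))

    def test_noiseless_identifiability(self):
        """Near-noiseless homogeneous cohort: typical values recovered closely."""
        # schedule jitter is kept: identical times for every subject would
        # leave only five distinct design points for six structural
        # parameters (an exact-interpolation degeneracy); with no
        # inter-individual variability the IIV variances are held at ~0 and
        # the marginal fit reduces to pooled least squares on theta
        cfg = SimulationConfig(
            n_subjects=6, omega_true=(0.0,) * 6, sigma_true=1e-4, seed=3,
        )
        ds, _ = generate_cohort(cfg)
        init = initial_model_heuristic(ds)
        fit = fit_population(
            ds, init,
            FitConfig(n_starts=2, seed=0, fix_omega=(1e-10,) * 6),
        )
        truth = np.array(cfg.theta_true)
        # A1, A2, l1, l2 are sharply identified at clinical sampling times
        assert np.allclose(fit.model.theta[[0, 1, 3, 4]], truth[[0, 1, 3, 4]],
                           rtol=1e-3)
        # the fast secretion phase is over before the first sample, so
        # A3/l3 carry little information even without noise
        assert np.allclose(fit.model.theta[[2, 5]], truth[[2, 5]], rtol=0.05)

    def test_descent_and_canonical_order(self, small_cohort, small_fit):
        dataset, _, _ = small_cohort
        init = initial_model_heuristic(dataset)
        assert small_fit.ofv <= marginal_neg2ll(init, dataset) + 1e-6
        assert small_fit.model.theta[3] <= small_fit.model.theta[4]
        assert small_fit.n_obs == dataset.n_obs

    def test_covariance_is_symmetric_psd_diagonal(self, small_cohort):
        dataset, _, _ = small_cohort
        init = initial_model_heuristic(dataset)
        fit = fit_population(
            dataset, init, FitConfig(n_starts=1, seed=0, compute_cov=True)
        )
        assert fit.est_cov is not None
        assert np.allclose(fit.est_cov, fit.est_cov.T)
        assert np.all(np.diag(fit.est_cov) >= 0)
        assert fit.se is not None and np.all(fit.se >= 0)


def soef_eval_params(model, times):
    return soef_eval(individual_params(model.theta, np.zeros(6)), times)


class TestEstimateIndividual:
    def test_typical_subject_has_zero_eta_additive(self, pop_model, one_subject):
        """Observations exactly on the typical curve give eta = 0.

        Exact under an additive error model; the proportional model's
        variance depends on the prediction, which biases the mode slightly.
        """
        model = PopulationModel(
            theta=pop_model.theta, omega=pop_model.omega, sigma=1e-3,
            error_model="additive",
        )
        est = estimate_individual(model, one_subject)
        assert np.max(np.abs(est.eta)) < 1e-6
        assert np.allclose(est.params.as_array(), pop_model.theta, rtol=1e-5)

    def test_typical_subject_near_zero_eta_proportional(self, pop_model, one_subject):
        est = estimate_individual(pop_model, one_subject)
        assert np.max(np.abs(est.eta)) < 0.05
        assert np.allclose(est.params.as_array(), pop_model.theta, rtol=0.05)

    def test_param_cov_symmetric_nonnegative(self, pop_model, one_subject):
        est = estimate_individual(pop_model, one_subject)
        assert np.allclose(est.param_cov, est.param_cov.T)
        assert np.all(np.diag(est.param_cov) >= 0)

    def test_single_observation_is_local_posterior_mode(self, pop_model, one_subject):
        """One-point estimation: the returned eta beats nearby perturbations."""
        est = estimate_individual(pop_model, one_subject, subset=["TP3"])
        sub = one_subject.subset(["TP3"])
        base = joint_neg2ll(pop_model, sub, est.eta)
        rng = np.random.default_rng(8)
        for _ in range(40):
            trial = est.eta + rng.normal(0, 0.05, 6)
            assert joint_neg2ll(pop_model, sub, trial) >= base - 1e-9

    def test_vague_prior_approaches_least_squares(self, example_params):
        """With a huge prior variance the fit follows the data, not the prior."""
        times = np.array([1.8, 18.7, 42.6, 66.3, 160.3])
        true = example_params.as_array() * np.exp(
            np.array([0.3, -0.2, 0.0, 0.25, -0.1, 0.0])
        )
        from dosim.kinetics import SOEFParameters, soef_eval as fe

        y = fe(SOEFParameters.from_array(true), times)
        pop_tight = PopulationModel(
            theta=example_params.as_array(), omega=np.full(6, 1e-4), sigma=0.1
        )
        pop_vague = PopulationModel(
            theta=example_params.as_array(), omega=np.full(6, 25.0), sigma=0.1
        )
        sub = SubjectRecord("S", times, y)
        est_tight = estimate_individual(pop_tight, sub)
        est_vague = estimate_individual(pop_vague, sub)
        # identifiable components (slow/intermediate) reach the generating values
        for idx in (0, 1, 3, 4):
            assert est_vague.params.as_array()[idx] == pytest.approx(
                true[idx], rel=0.02
            )
            # the tight prior shrinks toward theta instead
            assert abs(est_tight.params.as_array()[idx] - example_params.as_array()[idx]) < abs(
                true[idx] - example_params.as_array()[idx]
            ) + 1e-12

    def test_empty_subset_rejected(self, pop_model, one_subject):
        with pytest.raises(ValueError):
            estimate_individual(pop_model, one_subject, subset=["TP9"])
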