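"""Approximate marginal likelihood: limits, quadrature oracle, EBEs, CWRES."""

import numpy as np
import pytest

import remipk as rp
from remipk.foce import (EstimationError, PackedData, agq_objective,
                         compute_diagnostics, empirical_bayes_etas,
                         eta_shrinkage, foce_objective)
from remipk.structural import concentration, individual_params, residual_sd


def _tiny_study(n_subjects=3, seed=0, model=None, obs_times=(0.2, 8.0, 24.0, 40.0)):
    model = model or rp.final_2017()
    design = rp.StudyDesign(n_subjects=n_subjects,
                            rich_times=tuple(obs_times))
    return rp.generate_study(design, model, seed=seed)


class TestObjectiveLimits:
    def test_matches_fixed_effects_loglik_as_omega_vanishes(self, final_model):
        """With no between-subject variance the objective must reduce to the
        eta=0 Gaussian -2 log-likelihood, computed here independently from
        the structural model."""
        ds = _tiny_study(n_subjects=4, seed=3)
        spec = final_model.with_params(omega2_cl=1e-13)
        got = foce_objective(ds, spec)
        expected = 0.0
        for s in ds.subjects:
            p = individual_params(spec, s.covariates, eta_cl=0.0)
            for o in s.observations:
                if o.blq_flag:
                    continue
                f = concentration(p, s.doses, o.time)
                sd = residual_sd(f, spec.sigma_prop, spec.sigma_add)
                expected += (np.log(2 * np.pi * sd ** 2)
                             + (o.concentration - f) ** 2 / sd ** 2)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_continuous_in_the_small_omega_limit(self, final_model):
        """The Laplace value converges to the degenerate-limit branch."""
        ds = _tiny_study(n_subjects=3, seed=5)
        limit = foce_objective(ds, final_model.with_params(omega2_cl=1e-13))
        near = foce_objective(ds, final_model.with_params(omega2_cl=1e-7))
        assert near == pytest.approx(limit, abs=0.05)

    def test_nearly_gaussian_integrand_is_exact(self, final_model):
        """Laplace equals exact quadrature when the integrand is Gaussian;
        a tiny omega makes it numerically so."""
        ds = _tiny_study(n_subjects=3, seed=8)
        spec = final_model.with_params(omega2_cl=1e-5)
        assert foce_objective(ds, spec) == pytest.approx(
            agq_objective(ds, spec), abs=1e-4)

    def test_deterministic(self, final_model, small_study):
        a = foce_objective(small_study, final_model)
        b = foce_objective(small_study, final_model)
        assert a == b


class TestQuadratureOracle:
    def test_close_to_exact_marginal_likelihood(self, final_model):
        """3-subject, 4-observation instances: FOCE-I within 0.1 of the
        64-node adaptive Gauss-Hermite -2 log marginal likelihood."""
        for seed in range(5):
            ds = _tiny_study(n_subjects=3, seed=seed)
            assert foce_objective(ds, final_model) == pytest.approx(
                agq_objective(ds, final_model, n_nodes=64), abs=0.1)

    def test_ranks_parameter_vectors_like_the_exact_surface(self, final_model):
        ds = _tiny_study(n_subjects=4, seed=11)
        rng = np.random.default_rng(17)
        agree = total = 0
        for _ in range(15):
            specs = []
            for _ in range(2):
                specs.append(final_model.with_params(
                    tvcl=final_model.tvcl * rng.uniform(0.6, 1.6),
                    tvv=final_model.tvv * rng.uniform(0.6, 1.6),
                    omega2_cl=final_model.omega2_cl * rng.uniform(0.5, 2.0)))
            f = [foce_objective(ds, s) for s in specs]
            a = [agq_objective(ds, s) for s in specs]
            if abs(a[0] - a[1]) < 0.5:
                continue  # ranking not meaningful below the approximation error
            total += 1
            agree += (f[0] < f[1]) == (a[0] < a[1])
        assert total >= 10 and agree == total


class TestEmpiricalBayes:
    def test_noise_free_subject_has_zero_eta(self, final_model):
        """Observations generated exactly at the population prediction put
        the conditional mode at the prior mode (under additive error, where
        the residual variance does not itself depend on eta)."""
        ds = _tiny_study(n_subjects=3, seed=0,
                         model=final_model.with_params(
                             omega2_cl=0.0, sigma_prop=0.0).with_params(sigma_add=0.0))
        spec = final_model.with_params(sigma_prop=0.0, sigma_add=0.15)
        ebes = empirical_bayes_etas(ds, spec)
        assert np.all(np.abs(ebes.to_numpy()) < 1e-4)

    def test_interaction_shifts_mode_under_proportional_error(self, final_model):
        """With proportional error the log-variance term rewards a higher
        clearance even for perfectly predicted data, so the mode moves off
        zero -- the 'interaction' in FOCE-I."""
        ds = _tiny_study(n_subjects=3, seed=0,
                         model=final_model.with_params(
                             omega2_cl=0.0, sigma_prop=0.0).with_params(sigma_add=0.0))
        ebes = empirical_bayes_etas(ds, final_model)
        assert np.all(ebes.to_numpy() > 0.01)

    def test_doubled_concentrations_give_negative_eta(self, final_model):
        base = _tiny_study(n_subjects=1, seed=2,
                           model=final_model.with_params(omega2_cl=0.0,
                                                         sigma_prop=0.0,
                                                         sigma_add=0.0))
        s = base.subjects[0]
        doubled = rp.StudyDataset(subjects=(
            rp.SubjectRecord(id=s.id, covariates=s.covariates, doses=s.doses,
                             observations=tuple(
                                 rp.Observation(o.time, 2 * o.concentration)
                                 for o in s.observations)),))
        spec = final_model.with_params(sigma_prop=0.02, sigma_add=0.01)
        eta = empirical_bayes_etas(doubled, spec).iloc[0]
        assert eta < -0.2  # higher concentrations mean lower clearance

    def test_ebe_mean_near_zero_in_large_cohort(self, final_model):
        ds = rp.generate_study(rp.rich_design(200), final_model, seed=21)
        ebes = empirical_bayes_etas(ds, final_model).to_numpy()
        assert abs(ebes.mean()) < 3 * final_model.omega_cl / np.sqrt(200)


class TestShrinkage:
    @pytest.mark.parametrize("sd_ratio,expected", [(1.0, 0.0), (0.9, 10.0), (0.0, 100.0)])
    def test_arithmetic(self, sd_ratio, expected):
        omega = 0.35
        rng = np.random.default_rng(0)
        ebes = rng.normal(0, 1, 500)
        ebes = (ebes - ebes.mean()) / ebes.std(ddof=0) * omega * sd_ratio
        assert eta_shrinkage(ebes, omega) == pytest.approx(expected, abs=1e-9)

    def test_zero_omega_rejected(self):
        with pytest.raises(ValueError):
            eta_shrinkage([0.1, -0.1], 0.0)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            eta_shrinkage([0.1], 0.3)


class TestDiagnostics:
    def test_no_iiv_additive_error_reduces_to_standardised_residual(self, final_model):
        ds = _tiny_study(n_subjects=3, seed=6)
        spec = final_model.with_params(omega2_cl=0.0, sigma_prop=0.0, sigma_add=0.2)
        d = compute_diagnostics(ds, spec)
        np.testing.assert_allclose(d["cwres"], (d["dv"] - d["pred"]) / 0.2, rtol=1e-9)
        np.testing.assert_allclose(d["pred"], d["ipred"], rtol=1e-12)

    def test_exact_observations_give_zero_cwres(self, final_model):
        noise_free = final_model.with_params(omega2_cl=0.0, sigma_prop=0.0,
                                             sigma_add=0.0)
        ds = _tiny_study(n_subjects=2, seed=9, model=noise_free)
        spec = final_model.with_params(sigma_prop=0.0, sigma_add=0.15)
        d = compute_diagnostics(ds, spec)
        assert np.all(np.abs(d["cwres"]) < 1e-5)

    def test_cwres_calibrated_under_the_true_model(self, final_model):
        ds = rp.generate_study(rp.rich_design(200), final_model, seed=13)
        d = compute_diagnostics(ds, final_model)
        assert abs(d["cwres"].mean()) < 0.1
        assert abs(d["cwres"].var(ddof=0) - 1.0) < 0.15

    def test_packing_rejects_all_blq_subject(self, final_model):
        cov = rp.CovariateRecord(sex=0, pump_speed=2350.0)
        s = rp.SubjectRecord(id="Q", covariates=cov,
                             doses=(rp.InfusionEvent(0.0, 0.2, 48.0),),
                             observations=(rp.Observation(1.0, 0.01),))
        with pytest.raises(EstimationError, match="Q"):
            PackedData.from_dataset(rp.StudyDataset(subjects=(s,)))
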