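"""Likelihood, MCMC sampling, evidence estimators and per-visit fits."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from littdce.curves import ConcentrationCurve, SignalCurve
from littdce.bayes_inference import (
    PriorSpec,
    compare_models,
    fit_visit,
    log_likelihood,
    marginal_log_likelihood,
    model_evidence,
    sample_posterior,
)
from littdce.pk_models import ExtToftsParams, ToftsParams, ext_tofts_forward, tofts_forward
from littdce.signal_model import spgr_signal


class TestLogLikelihood:
    def test_zero_residuals_analytic(self, aif, clean_tissue_curve):
        n = len(clean_tissue_curve)
        ll = log_likelihood([0.22, 0.3], "tofts", aif, clean_tissue_curve, 1.0)
        assert ll == pytest.approx(-0.5 * n * np.log(2 * np.pi), rel=1e-12)

    def test_doubling_sigma_with_zero_residuals(self, aif, clean_tissue_curve):
        n = len(clean_tissue_curve)
        l1 = log_likelihood([0.22, 0.3], "tofts", aif, clean_tissue_curve, 0.5)
        l2 = log_likelihood([0.22, 0.3], "tofts", aif, clean_tissue_curve, 1.0)
        assert l1 - l2 == pytest.approx(n * np.log(2.0), rel=1e-12)

    def test_matches_sum_of_normal_log_densities(self):
        t = np.linspace(0, 2, 5)
        aif = ConcentrationCurve(t, np.ones(5))
        p = ToftsParams(0.4, 0.5)
        pred = tofts_forward(p, aif).values
        obs = pred + np.array([0.01, -0.02, 0.03, 0.0, -0.01])
        sigma = 0.05
        expected = float(np.sum(norm.logpdf(obs, loc=pred, scale=sigma)))
        got = log_likelihood(p, "tofts", aif, ConcentrationCurve(t, obs), sigma)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_grid_mismatch_rejected(self, aif, clean_tissue_curve):
        other = ConcentrationCurve(
            clean_tissue_curve.times + 0.01, clean_tissue_curve.values
        )
        with pytest.raises(ValueError):
            log_likelihood([0.2, 0.3], "tofts", aif, other, 0.1)

    def test_nonpositive_sigma_rejected(self, aif, clean_tissue_curve):
        with pytest.raises(ValueError):
            log_likelihood([0.2, 0.3], "tofts", aif, clean_tissue_curve, 0.0)


class TestMarginalLikelihood:
    @pytest.mark.parametrize("ssr", [1e-4, 0.01, 1.0, 50.0])
    def test_matches_numeric_sigma_quadrature(self, ssr):
        n, bounds = 39, (1e-4, 1.0)
        lnr = np.log(bounds[1] / bounds[0])

        def integrand(log_sigma):
            s2 = np.exp(2 * log_sigma)
            return np.exp(
                -0.5 * n * np.log(2 * np.pi * s2) - ssr / (2 * s2)
            ) / lnr

        ref, _ = quad(integrand, np.log(bounds[0]), np.log(bounds[1]),
                      limit=400, epsabs=0, epsrel=1e-11)
        got = marginal_log_likelihood(ssr, n, bounds)
        assert got == pytest.approx(np.log(ref), abs=1e-6)


class TestSampler:
    def test_same_seed_identical_samples(self, aif, noisy_curve_factory):
        obs = noisy_curve_factory(0)
        r1 = sample_posterior("tofts", aif, obs, seed=7, n_steps=400)
        r2 = sample_posterior("tofts", aif, obs, seed=7, n_steps=400)
        assert np.array_equal(r1.samples, r2.samples)

    def test_samples_respect_prior_box(self, aif, noisy_curve_factory):
        obs = noisy_curve_factory(1)
        priors = PriorSpec.for_model("tofts")
        r = sample_posterior("tofts", aif, obs, priors=priors, seed=2, n_steps=400)
        kt, ve, sigma = r.samples[:, 0], r.samples[:, 1], r.samples[:, 2]
        assert kt.min() > 0 and kt.max() < 6.0
        assert ve.min() > 0 and ve.max() < 1.0
        assert sigma.min() > priors.sigma_bounds[0]
        assert sigma.max() < priors.sigma_bounds[1]
        lo, hi = r.ci95[0]
        assert 0 <= lo <= hi <= 6.0

    def test_prior_only_sampling_recovers_uniform_bounds(self, aif, clean_tissue_curve):
        r = sample_posterior(
            "tofts", aif, clean_tissue_curve, seed=3,
            n_walkers=64, n_steps=400, prior_only=True,
        )
        kt = r.samples[:, 0]
        assert len(kt) >= 10_000
        assert kt.min() < 0.06 and kt.max() > 5.94  # within 1% of [0, 6]

    def test_posterior_concentrates_near_truth(self, aif, noisy_curve_factory):
        obs = noisy_curve_factory(4)
        r = sample_posterior("tofts", aif, obs, seed=5)
        assert r.converged
        assert r.median[0] == pytest.approx(0.22, rel=0.1)
        assert r.median[1] == pytest.approx(0.3, rel=0.1)


class TestEvidence:
    def test_quadrature_matches_independent_brute_force(self, aif, noisy_curve_factory):
        """Two-stage brute force built here from scratch: coarse 3D scan of
        (ktrans, ve, log sigma) joint density, then trapezoid on a grid
        refined around the located peak."""
        from littdce.pk_models import forward_model_matrix
        from scipy.special import logsumexp as lse

        obs = noisy_curve_factory(5, noise_frac=0.05)
        n = len(obs)

        def joint(kts, ves, lss):
            kk, vv = np.meshgrid(kts, ves, indexing="ij")
            theta = np.column_stack([kk.ravel(), vv.ravel()])
            pred = forward_model_matrix("tofts", theta, aif.times, aif.values)
            ssr = ((obs.values[None, :] - pred) ** 2).sum(axis=1)
            ssr = ssr.reshape(len(kts), len(ves))
            s2 = np.exp(2 * lss)
            return (
                -0.5 * n * np.log(2 * np.pi * s2)[None, None, :]
                - ssr[:, :, None] / (2 * s2)[None, None, :]
            )

        kc = np.linspace(1e-6, 6, 200)
        vc = np.linspace(1e-6, 1, 200)
        sc = np.linspace(np.log(1e-4), 0.0, 80)
        coarse = joint(kc, vc, sc)
        i, j, k = np.unravel_index(np.argmax(coarse), coarse.shape)
        kf = np.linspace(max(1e-6, kc[i] - 0.2), min(6, kc[i] + 0.2), 300)
        vf = np.linspace(max(1e-6, vc[j] - 0.2), min(1, vc[j] + 0.2), 300)
        sf = np.linspace(max(np.log(1e-4), sc[k] - 2), min(0, sc[k] + 2), 150)
        ka, va, sa = (np.unique(np.concatenate(p)) for p in ((kc, kf), (vc, vf), (sc, sf)))
        ll = joint(ka, va, sa)
        ref = ll.max()
        integral = np.trapezoid(
            np.trapezoid(np.trapezoid(np.exp(ll - ref), sa, axis=2), va, axis=1), ka
        )
        brute = ref + np.log(integral) - np.log(6.0 * 1.0 * np.log(1e4))

        quad_ev = model_evidence("tofts", aif, obs, method="quadrature")
        assert quad_ev == pytest.approx(brute, abs=0.02)

    def test_importance_sampling_agrees_with_quadrature(self, aif, noisy_curve_factory):
        obs = noisy_curve_factory(6)
        zq = model_evidence("tofts", aif, obs, method="quadrature")
        zi = model_evidence("tofts", aif, obs, method="is", seed=1)
        assert zi == pytest.approx(zq, abs=0.05)

    def test_bic_is_a_coarse_but_sane_approximation(self, aif, noisy_curve_factory):
        obs = noisy_curve_factory(7)
        zq = model_evidence("tofts", aif, obs, method="quadrature")
        zb = model_evidence("tofts", aif, obs, method="bic")
        assert abs(zb - zq) < 25.0

    def test_occam_penalty_on_nested_models(self, aif, noisy_curve_factory):
        # data generated exactly by the simpler model: the simpler model
        # should not lose to its superset
        obs = noisy_curve_factory(8)
        z_tofts = model_evidence("tofts", aif, obs, method="is", seed=2)
        z_2cxm = model_evidence("twocxm", aif, obs, method="is", seed=2)
        assert z_tofts >= z_2cxm

    def test_unknown_method_rejected(self, aif, clean_tissue_curve):
        with pytest.raises(ValueError):
            model_evidence("tofts", aif, clean_tissue_curve, method="magic")


class TestCompareModels:
    def test_probabilities_normalised(self, aif, noisy_curve_factory):
        obs = noisy_curve_factory(9)
        cmp = compare_models(aif, obs, seed=0)
        assert sum(cmp.posterior_probability.values()) == pytest.approx(1.0, abs=1e-12)
        assert cmp.winner in cmp.log_evidence

    def test_detects_plasma_fraction_when_present(self, aif):
        truth = ExtToftsParams(0.22, 0.3, 0.15)
        clean = ext_tofts_forward(truth, aif)
        rng = np.random.default_rng(10)
        obs = ConcentrationCurve(
            clean.times,
            clean.values + rng.normal(0, 0.01 * clean.values.max(), len(clean)),
        )
        cmp = compare_models(aif, obs, seed=3)
        assert cmp.winner == "ext_tofts"


class TestFitVisit:
    def test_noise_free_visit_recovers_truth(self, protocol, t_minutes):
        from littdce.synthetic_data import population_aif

        ref_aif = population_aif(t_minutes)
        truth = ToftsParams(0.4, 0.3)
        conc = tofts_forward(truth, ref_aif)
        sig = SignalCurve(
            protocol.frame_times(), spgr_signal(conc.values, protocol, m0=600.0)
        )
        fit = fit_visit(sig, ref_aif, protocol, seed=0)
        assert not fit.no_measurement
        assert fit.ktrans == pytest.approx(0.4, rel=0.02)

    def test_flat_signal_flags_no_measurement(self, protocol, aif):
        base = spgr_signal(0.0, protocol, m0=600.0)
        sig = SignalCurve(protocol.frame_times(), np.full(protocol.n_frames, base))
        fit = fit_visit(sig, aif, protocol, seed=0)
        assert fit.no_measurement
        assert fit.ktrans is None

    def test_estimate_invariant_to_m0_rescaling(self, protocol, t_minutes):
        from littdce.synthetic_data import population_aif

        ref_aif = population_aif(t_minutes)
        conc = tofts_forward(ToftsParams(0.4, 0.3), ref_aif)
        fits = []
        for m0 in (60.0, 600.0):
            sig = SignalCurve(
                protocol.frame_times(), spgr_signal(conc.values, protocol, m0=m0)
            )
            fits.append(fit_visit(sig, ref_aif, protocol, seed=0))
        assert fits[0].ktrans == pytest.approx(fits[1].ktrans, rel=1e-6)
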