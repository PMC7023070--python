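from dataclasses import replace

import numpy as np
import pytest

from lzpk import (
    CohortSpec,
    PopPKModel,
    REFERENCE_PARAMS,
    ValidationError,
    cwres,
    external_validation_bands,
    generate,
    iwres,
    vpc,
)
from lzpk.diagnostics import _fit_objective
from lzpk.estimation import PopPKResults


def _results_at(model, params):
    """A results object pinned at given parameters with conditional-mode etas
    (no optimisation) — convenient for diagnostics at known truth."""
    import pandas as pd
    etas = model.conditional_etas(params)
    return PopPKResults(
        model=model, spec=model.spec, params=params, hepatic_betas={},
        estimates={}, ofv=float("nan"), se={}, rse={},
        etas=pd.DataFrame({"ID": model._pk.ids, "eta_cl": etas[:, 0],
                           "eta_v1": etas[:, 1]}),
        shrinkage={}, converged=True, boundary=False, nfev=0)


class TestIWRES:
    def test_zero_when_observation_equals_prediction(self, study_fit):
        """Forcing DV = IPRED in the packed data gives identically zero IWRES."""
        model = study_fit.model
        obj = _fit_objective(model, study_fit)
        etas = study_fit.etas[["eta_cl", "eta_v1"]].to_numpy()
        f = obj.individual_pred(etas)
        saved = model._pk.logy.copy()
        try:
            model._pk.logy = np.where(model._pk.mask, np.log(np.where(f > 0, f, 1.0)), 0.0)
            res = iwres(model, study_fit)
            assert np.allclose(res["IWRES"], 0.0, atol=1e-12)
        finally:
            model._pk.logy = saved

    def test_doubling_sigma_halves_residuals(self, study_fit):
        base = iwres(study_fit.model, study_fit)["IWRES"].to_numpy()
        inflated = replace(
            study_fit,
            params=replace(study_fit.params,
                           sigma_add=2 * study_fit.params.sigma_add,
                           sigma_prop=2 * study_fit.params.sigma_prop),
        )
        doubled = iwres(study_fit.model, inflated)["IWRES"].to_numpy()
        np.testing.assert_allclose(doubled, base / 2.0, rtol=1e-12)


class TestCWRES:
    def test_degenerate_covariance_reduces_to_eta_zero_iwres(self, small_ds):
        """With omega = 0 the FOCE covariance is diagonal and CWRES coincides
        with IWRES computed at eta = 0."""
        params = replace(REFERENCE_PARAMS, omega_cl=0.0, omega_v1=0.0)
        model = PopPKModel(small_ds)
        res = _results_at(model, params)
        cw = cwres(model, res)["CWRES"].to_numpy()
        iw = iwres(model, res, etas=np.zeros((small_ds.n_subjects, 2)))["IWRES"].to_numpy()
        np.testing.assert_allclose(cw, iw, rtol=1e-6, atol=1e-8)

    def test_mean_near_zero_on_data_simulated_from_truth(self, study_ds):
        model = PopPKModel(study_ds)
        res = model.fit(compute_rse=False, start=REFERENCE_PARAMS)
        cw = cwres(model, res)["CWRES"]
        assert abs(cw.mean()) < 0.15

    def test_linearised_covariance_matches_monte_carlo_on_one_subject(self, rng):
        """The G Omega G' + diag(v) covariance of the FOCE expansion matches
        a brute-force Monte Carlo covariance of simulated log observations
        on a one-subject toy.

        The comparison isolates the eta-linearisation: the toy's realised
        data sit at eta = 0 (so the expansion point is the population
        centre) and uses a moderate IIV of 20% CV — at the published 60%+
        IIV the marginal log-scale covariance of trough samples is dominated
        by rare high-clearance tail draws and no expansion reproduces it.
        """
        osd = 0.2
        params = replace(REFERENCE_PARAMS, omega_cl=osd**2, omega_v1=osd**2)
        spec = CohortSpec.study(seed=21, n_subjects=1, crrt_fraction=0.0)
        ds = generate(spec, replace(params, omega_cl=0.0, omega_v1=0.0))
        model = PopPKModel(ds)
        obj = model._objective_for(model._theta_from_params(params))
        from lzpk.pkmodel import log_variance
        etas_hat = model.conditional_etas(params)
        fi = obj.individual_pred(etas_hat)[0]
        v_hat = log_variance(fi, params.sigma_add, params.sigma_prop)
        # Monte Carlo over eta and residual noise
        etas = rng.standard_normal((200_000, 1, 2)) * osd
        f = obj.individual_pred(etas)[:, 0, :]
        logy = np.log(f) + np.sqrt(v_hat)[None, :] * rng.standard_normal(f.shape)
        mc_cov = np.cov(logy.T)
        # FOCE linearisation about the conditional etas of the realised data
        h = 1e-5
        grads = []
        for k in range(2):
            ep, em = etas_hat.copy(), etas_hat.copy()
            ep[:, k] += h
            em[:, k] -= h
            grads.append((np.log(obj.individual_pred(ep))
                          - np.log(obj.individual_pred(em)))[0] / (2 * h))
        G = np.column_stack(grads)
        vi = (G * np.array([params.omega_cl, params.omega_v1])) @ G.T + np.diag(v_hat)
        assert np.trace(vi) == pytest.approx(np.trace(mc_cov), rel=0.10)


class TestVPC:
    def test_single_replicate_degenerates_to_its_percentiles(self, study_fit):
        v = vpc(study_fit.model, study_fit, n_sim=1, seed=3)
        for p in (2.5, 50.0, 97.5):
            np.testing.assert_allclose(v.sim_ci[p][0], v.sim_ci[p][1])

    def test_percentile_ordering_everywhere(self, study_fit):
        v = vpc(study_fit.model, study_fit, n_sim=60, seed=3)
        assert np.all(v.observed[2.5] <= v.observed[50.0])
        assert np.all(v.observed[50.0] <= v.observed[97.5])
        for p in (2.5, 50.0, 97.5):
            assert np.all(v.sim_ci[p][0] <= v.sim_ci[p][1] + 1e-12)

    def test_ci_width_estimate_converges_with_more_replicates(self, study_fit):
        """The simulation CI describes across-replicate percentile spread, so
        its width converges (stabilises) as n_sim grows rather than
        shrinking to zero; estimates at large n_sim agree closely."""
        width = lambda v: np.array([np.mean(v.sim_ci[p][1] - v.sim_ci[p][0])
                                    for p in (2.5, 50.0, 97.5)])
        w_small = width(vpc(study_fit.model, study_fit, n_sim=60, seed=5))
        w_big = width(vpc(study_fit.model, study_fit, n_sim=600, seed=5))
        w_big2 = width(vpc(study_fit.model, study_fit, n_sim=600, seed=6))
        # large-n_sim estimates agree with each other better than the
        # small-n_sim estimate agrees with them
        assert np.linalg.norm(w_big - w_big2) < np.linalg.norm(w_small - w_big2)

    def test_observed_percentiles_inside_cis_for_self_simulated_data(self, study_fit):
        """Replacing the observations by replicates simulated from the fit
        puts the observed percentiles inside the 95% CIs in >= 90% of
        (bin, percentile) cells, averaged over a few replicates."""
        model = study_fit.model
        obj = _fit_objective(model, study_fit)
        sds = np.sqrt([study_fit.params.omega_cl, study_fit.params.omega_v1])
        saved = model._pk.logy.copy()
        inside = total = 0
        try:
            for s in (42, 43, 44, 45, 46):
                rng = np.random.default_rng(s)
                etas = rng.standard_normal((model._pk.n, 2)) * sds[None, :]
                f = obj.individual_pred(etas)
                y = (f * (1 + study_fit.params.sigma_prop * rng.standard_normal(f.shape))
                     + study_fit.params.sigma_add * rng.standard_normal(f.shape))
                y = np.where(y > 0, y, 0.01)
                model._pk.logy = np.where(model._pk.mask, np.log(y), saved)
                v = vpc(model, study_fit, n_sim=200, seed=9)
                for p in (2.5, 50.0, 97.5):
                    for b in range(len(v.bins)):
                        inside += int(v.sim_ci[p][0][b] - 1e-12 <= v.observed[p][b]
                                      <= v.sim_ci[p][1][b] + 1e-12)
                        total += 1
        finally:
            model._pk.logy = saved
        assert inside >= 0.9 * total

    def test_rejects_nonpositive_n_sim(self, study_fit):
        with pytest.raises(ValidationError):
            vpc(study_fit.model, study_fit, n_sim=0)


class TestValidationBands:
    def test_noise_free_bands_collapse_to_typical_trajectory(self):
        params = replace(REFERENCE_PARAMS, omega_cl=0.0, omega_v1=0.0,
                         sigma_add=1e-12, sigma_prop=1e-12)
        bands = external_validation_bands(params, clcr_grid=(44.0,), n_subjects=50,
                                          seed=1, times=np.array([24.0, 48.0, 96.0]))
        np.testing.assert_allclose(bands.percentiles[0, 0], bands.percentiles[0, 1],
                                   rtol=1e-6)
        np.testing.assert_allclose(bands.percentiles[0, 1], bands.percentiles[0, 2],
                                   rtol=1e-6)

    def test_median_css_approaches_rate_over_clearance(self):
        bands = external_validation_bands(REFERENCE_PARAMS, clcr_grid=(44.0,),
                                          n_subjects=4000, seed=2,
                                          times=np.array([96.0]))
        # median over lognormal etas = typical value; Css = 50 / 6.97
        assert bands.median_css(44.0) == pytest.approx(50.0 / 6.97, rel=0.05)

    def test_bands_decrease_with_clcr(self):
        bands = external_validation_bands(REFERENCE_PARAMS,
                                          clcr_grid=(40.0, 120.0, 240.0),
                                          n_subjects=1500, seed=3,
                                          times=np.array([48.0, 96.0]))
        med_end = bands.percentiles[:, 1, -1]
        assert med_end[0] > med_end[1] > med_end[2]

    def test_observed_points_scored_for_coverage(self):
        import pandas as pd
        obs = pd.DataFrame({"CLCR": [44.0, 100.0], "TIME": [48.0, 48.0],
                            "DV": [7.0, 1e6]})
        bands = external_validation_bands(REFERENCE_PARAMS, clcr_grid=(40.0, 120.0),
                                          n_subjects=800, seed=4,
                                          times=np.array([24.0, 48.0, 96.0]),
                                          observed=obs)
        assert bands.coverage == pytest.approx(0.5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            external_validation_bands(REFERENCE_PARAMS, clcr_grid=())
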