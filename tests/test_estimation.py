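import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lzpk import (
    CohortSpec,
    DatasetTable,
    ModelSpec,
    PopPKModel,
    REFERENCE_PARAMS,
    bootstrap,
    compare_models,
    concentration,
    generate,
    log_variance,
    scm,
)
from lzpk.estimation import _pack

from _oracles import gauss_hermite_ofv


def _direct_gaussian_m2ll(dataset, params):
    """-2 log-likelihood of log observations when there are no random effects."""
    total = 0.0
    for rec in dataset.subjects():
        from lzpk import IndividualParameters
        ind = IndividualParameters.from_population(params, rec.covariates)
        obs = rec.observations
        obs = obs[(obs["CMT"] == 1) & (obs["BLQ"] == 0) & obs["DV"].notna()]
        f = concentration(ind, rec.doses, obs["TIME"].to_numpy())
        v = log_variance(f, params.sigma_add, params.sigma_prop)
        r = np.log(obs["DV"].to_numpy()) - np.log(f)
        total += float(np.sum(r * r / v + np.log(v) + math.log(2 * math.pi)))
    return total


class TestOFV:
    def test_no_iiv_reduces_to_direct_gaussian(self, small_ds):
        params = replace(REFERENCE_PARAMS, omega_cl=0.0, omega_v1=0.0)
        got = PopPKModel(small_ds).ofv(params)
        assert got == pytest.approx(_direct_gaussian_m2ll(small_ds, params), rel=1e-9)

    def test_subject_with_no_quantifiable_obs_leaves_ofv_unchanged(self, small_ds):
        base = PopPKModel(small_ds).ofv(REFERENCE_PARAMS)
        df = small_ds.df.copy()
        extra = df[df["ID"] == 1].copy()
        extra["ID"] = 999
        extra.loc[extra["EVID"] == 0, "BLQ"] = 1
        extra.loc[extra["EVID"] == 0, "MDV"] = 1
        extra.loc[extra["EVID"] == 0, "DV"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            model = PopPKModel(pd.concat([df, extra], ignore_index=True))
        assert model.ofv(REFERENCE_PARAMS) == pytest.approx(base, rel=1e-12)

    def test_laplace_within_half_unit_of_quadrature_on_toy(self):
        spec = CohortSpec.study(seed=3, n_subjects=3, crrt_fraction=1.0 / 3.0)
        ds = generate(spec, REFERENCE_PARAMS)
        model = PopPKModel(ds)
        lap = model.ofv(REFERENCE_PARAMS)
        agq = gauss_hermite_ofv(model, REFERENCE_PARAMS, n_nodes=21)
        assert abs(lap - agq) < 0.5

    def test_subject_order_invariance(self, small_ds):
        base = PopPKModel(small_ds).ofv(REFERENCE_PARAMS)
        df = small_ds.df.copy()
        df["ID"] = small_ds.df["ID"].map(lambda i: 100 - i)  # reverse packing order
        df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
        assert PopPKModel(df).ofv(REFERENCE_PARAMS) == pytest.approx(base, rel=1e-9)


class TestFit:
    def test_fixed_effects_recovered_at_vanishing_noise(self):
        truth = replace(REFERENCE_PARAMS, omega_cl=0.0, omega_v1=0.0,
                        sigma_add=1e-3, sigma_prop=2e-3)
        spec = replace(CohortSpec.study(seed=5), loq_plasma=0.0, loq_effluent=0.0)
        ds = generate(spec, truth)
        res = PopPKModel(ds).fit(
            compute_rse=False,
            fix={"omega_sd_cl": 1e-5, "omega_sd_v1": 1e-5,
                 "sigma_add": 1e-3, "sigma_prop": 2e-3},
        )
        for name, true_val in (("cl_nr", 2.62), ("cl_r_slope", 4.35), ("v1", 16.2),
                               ("q", 71.7), ("v2", 29.0)):
            assert res.estimates[name] == pytest.approx(true_val, rel=0.01), name

    def test_fit_reports_uncertainty_etas_and_shrinkage(self, small_ds):
        res = PopPKModel(small_ds).fit()
        assert res.converged
        assert len(res.etas) == small_ds.n_subjects
        finite_rse = [v for v in res.rse.values() if np.isfinite(v)]
        assert len(finite_rse) >= 6 and all(v > 0 for v in finite_rse)
        assert all(0.0 <= v <= 100.0 for v in res.shrinkage.values())
        text = res.summary()
        assert "IIV_CL" in text and "OFV" in text

    def test_ofv_at_estimate_not_above_truth(self, study_fit):
        model = study_fit.model
        assert study_fit.ofv <= model.ofv(REFERENCE_PARAMS) + 1e-6

    def test_dropping_renal_covariate_inflates_iiv_cl(self, study_ds, study_fit):
        base = PopPKModel(study_ds, ModelSpec(clcr_on_cl=False)).fit(compute_rse=False)
        assert base.estimates["omega_sd_cl"] > study_fit.estimates["omega_sd_cl"]


class TestModelComparison:
    @pytest.mark.parametrize("drop, df, expected", [
        (3.84, 1, 0.05), (0.0, 1, 1.0), (6.63, 1, 0.01),
    ])
    def test_chi_square_thresholds(self, drop, df, expected):
        assert compare_models(100.0, 100.0 - drop, df) == pytest.approx(expected, abs=0.001)

    def test_negative_drop_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="higher OFV"):
            assert compare_models(100.0, 101.0, 1) == 1.0


class TestSCM:
    def test_empty_candidate_set_returns_base(self, small_ds):
        result = scm(small_ds, base_spec=ModelSpec(clcr_on_cl=False), candidates=(),
                     final_rse=False)
        assert result.selected == ()
        assert result.final.spec == ModelSpec(clcr_on_cl=False)

    def test_renal_effect_is_detected_and_survives_backward(self, small_ds):
        # small_ds was generated WITH the Clcr effect on CL
        result = scm(small_ds, base_spec=ModelSpec(clcr_on_cl=False),
                     candidates=("clcr",), final_rse=False)
        assert "clcr" in result.selected
        forward = [s for s in result.steps if s.phase == "forward" and s.name == "clcr"]
        assert forward[0].included and forward[0].delta_ofv < -3.84

    def test_constant_candidate_skipped_with_warning(self, small_ds):
        df = small_ds.df.copy()
        df["BILI"] = 1.0
        df["GOT"] = 20.0
        df["GPT"] = 20.0
        sexes = df["SEX"].copy()
        df["SEX"] = "M"
        with pytest.warns(UserWarning, match="constant"):
            result = scm(df, base_spec=ModelSpec(clcr_on_cl=True),
                         candidates=("hep_ge1",), final_rse=False)
        assert result.selected == ("clcr",)


class TestBootstrap:
    def test_single_unique_subject_gives_identical_replicates(self, small_ds):
        clones = small_ds.resample_subjects([1, 1, 1, 1])
        res = bootstrap(clones, b=3, seed=4)
        assert res.n_failed == 0
        est = res.estimates
        for col in est.columns:
            assert est[col].nunique() == 1

    def test_fixed_seed_reproducible(self, small_ds):
        r1 = bootstrap(small_ds, b=2, seed=9)
        r2 = bootstrap(small_ds, b=2, seed=9)
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)

    def test_percentile_summary_shape(self, small_ds):
        res = bootstrap(small_ds, b=2, seed=1)
        assert set(res.summary.columns) == {"median", "p5", "p95"}
        assert (res.summary["p5"] <= res.summary["p95"]).all()
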