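"""Compartmental model predictions, ML fitting, model selection, derived
parameters, and the dose-conservation / recovery invariants."""

import math

import numpy as np
import pytest

from arcpk.exceptions import DomainError, InsufficientDataError
from arcpk.pk import (
    IVBolusModel,
    PKParameters,
    derived_parameters,
    exclude_blq,
    fit_profile,
    predict_concentration,
    select_model,
)
from tests.conftest import SCHEDULE, make_profile


class TestPredictConcentration:
    def test_initial_concentration_is_dose_over_volume(self):
        p = PKParameters(1, cl_tot=4.0, v1=500.0)
        assert predict_concentration(p, 7.5, 0.0) == pytest.approx(15.0)

    def test_monoexponential_decay_value(self):
        # k = 60*4/500 = 0.48 h^-1 -> C(1 h) = 15*exp(-0.48)
        p = PKParameters(1, cl_tot=4.0, v1=500.0)
        assert predict_concentration(p, 7.5, 1.0) == pytest.approx(
            15.0 * math.exp(-0.48), rel=1e-12)

    def test_two_compartment_degenerates_to_one(self):
        p1 = PKParameters(1, cl_tot=4.0, v1=500.0)
        p2 = PKParameters(2, cl_tot=4.0, v1=500.0, q=1e-9, v2=1e-6)
        t = np.linspace(0, 10, 50)
        np.testing.assert_allclose(predict_concentration(p2, 7.5, t),
                                   predict_concentration(p1, 7.5, t), atol=1e-8)

    def test_strictly_decreasing_and_vanishing(self):
        p = PKParameters(2, cl_tot=3.55, v1=250.0, q=3.0, v2=140.0)
        t = np.linspace(0, 48, 200)
        c = predict_concentration(p, 64.7, t)
        assert np.all(np.diff(c) < 0)
        assert c[-1] < 1e-3 * c[0]

    def test_rejects_negative_time_and_bad_params(self):
        p = PKParameters(1, cl_tot=4.0, v1=500.0)
        with pytest.raises(DomainError):
            predict_concentration(p, 7.5, -1.0)
        with pytest.raises(DomainError):
            PKParameters(1, cl_tot=-4.0, v1=500.0)

    def test_alpha_beta_ordering(self):
        alpha, beta = PKParameters(2, 3.55, 250.0, 3.0, 140.0).macro_constants()
        assert alpha > beta > 0


class TestExcludeBlq:
    def test_censored_tail_removed(self):
        p = PKParameters(2, 24.3, 294.0, 24.3, 196.0)  # fast PAH-like kinetics
        prof = make_profile(p, 10.0, analyte="pah")
        n_blq = sum(r.blq for r in prof.records)
        assert n_blq >= 2
        filtered = exclude_blq(prof)
        assert len(filtered.records) == len(prof.records) - n_blq
        assert not any(r.blq for r in filtered.records)

    def test_identity_when_nothing_censored(self):
        prof = make_profile(PKParameters(2, 3.55, 250.0, 3.0, 140.0), 64.7)
        assert exclude_blq(prof).records == prof.records

    def test_all_blq_is_insufficient(self):
        prof = make_profile(PKParameters(1, 50.0, 100.0), 0.001, lloq=10.0)
        with pytest.raises(InsufficientDataError):
            exclude_blq(prof)


class TestFitting:
    TRUTH = PKParameters(2, cl_tot=3.55, v1=250.0, q=3.0, v2=140.0)

    def test_noise_free_two_compartment_recovery(self):
        """All four structural parameters recovered to 0.1 % on clean data."""
        prof = make_profile(self.TRUTH, 64.7)
        fit = fit_profile(prof, 2, "proportional")
        assert fit.converged
        np.testing.assert_allclose(fit.params.as_array(), self.TRUTH.as_array(),
                                   rtol=1e-3)

    def test_noise_free_sigma_is_zero(self):
        prof = make_profile(PKParameters(1, 4.0, 500.0), 7.5)
        fit = fit_profile(prof, 1, "proportional")
        assert fit.sigma < 1e-6

    def test_additive_noise_free_recovery(self):
        prof = make_profile(self.TRUTH, 10.0)
        fit = fit_profile(prof, 2, "additive")
        np.testing.assert_allclose(fit.params.as_array(), self.TRUTH.as_array(),
                                   rtol=1e-3)

    def test_too_few_points_is_precondition_error(self):
        prof = make_profile(self.TRUTH, 64.7, times=[0.5, 1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            fit_profile(prof, 2)

    def test_dose_conservation_invariant(self):
        """AUC·CL·60/1e6 equals the dose for every converged fit."""
        for seed in range(5):
            prof = make_profile(self.TRUTH, 64.7, noise_sd=0.07, seed=seed)
            fit = fit_profile(prof, 2, "proportional")
            assert fit.auc_inf * fit.params.cl_tot * 60.0 / 1e6 == pytest.approx(
                64.7, rel=1e-9)

    def test_monotonicity_cl_vs_auc(self):
        aucs = []
        for cl in (2.0, 3.0, 4.0, 5.0):
            prof = make_profile(PKParameters(2, cl, 250.0, 3.0, 140.0), 64.7)
            aucs.append(fit_profile(prof, 2).auc_inf)
        assert all(a > b for a, b in zip(aucs, aucs[1:]))

    def test_parameter_recovery_median_bias(self):
        """Median CL bias < 1 % over 200 noisy profiles at the study schedule."""
        rel_err = []
        for seed in range(200):
            prof = make_profile(self.TRUTH, 64.7, noise_sd=0.05, seed=seed)
            fit = fit_profile(prof, 2, "proportional")
            rel_err.append(fit.params.cl_tot / self.TRUTH.cl_tot - 1.0)
        assert abs(np.median(rel_err)) < 0.01

    def test_cv_reported_and_small_for_clean_data(self):
        prof = make_profile(self.TRUTH, 64.7)
        fit = fit_profile(prof, 2)
        assert fit.cv_pct is not None
        assert all(v < 0.01 for v in fit.cv_pct.values())
        assert fit.precision_acceptable(50.0)

    def test_summary_renders(self):
        fit = fit_profile(make_profile(self.TRUTH, 64.7), 2)
        text = fit.summary()
        assert "cl_tot" in text and "AUC" in text


class TestSelectModel:
    def test_biexponential_data_keeps_two_compartments(self):
        prof = make_profile(PKParameters(2, 3.7, 228.0, 3.7, 152.0), 64.7,
                            noise_sd=0.05, seed=1)
        fit = select_model(prof)
        assert fit.n_compartments == 2

    def test_degenerate_profile_falls_back_to_one_compartment(self):
        # q*v2 negligible -> the 2-comp parameters are unidentifiable and the
        # precision rule must push the fit down to one compartment
        prof = make_profile(PKParameters(2, 3.7, 380.0, 1e-4, 0.05), 64.7,
                            noise_sd=0.05, seed=2)
        fit = select_model(prof)
        assert fit.n_compartments == 1
        assert fit.precision_acceptable(50.0)

    def test_amikacin_is_always_two_compartment(self):
        prof = make_profile(PKParameters(2, 3.6, 312.0, 3.6, 208.0), 7.5,
                            analyte="amikacin", lloq=0.5, noise_sd=0.05, seed=3)
        assert select_model(prof).n_compartments == 2

    def test_pah_fallback_uses_additive_error(self):
        prof = make_profile(PKParameters(2, 24.3, 490.0, 1e-4, 0.05), 10.0,
                            analyte="pah", noise_sd=0.05, seed=4)
        fit = select_model(prof)
        assert fit.n_compartments == 1
        assert fit.error_model == "additive"


class TestDerivedParameters:
    def test_amikacin_table_value(self):
        prof = make_profile(PKParameters(2, 4.06, 323.5, 4.06, 215.7), 7.5)
        vss, auc = derived_parameters(fit_profile(prof, 2))
        assert auc == pytest.approx(7.5e6 / (4.06 * 60.0), rel=1e-6)  # 30,788
        assert vss == pytest.approx(539.2, rel=1e-3)

    def test_iohexol_table_value(self):
        prof = make_profile(PKParameters(2, 4.25, 247.3, 4.25, 164.9), 64.7)
        _, auc = derived_parameters(fit_profile(prof, 2))
        assert auc == pytest.approx(64.7e6 / (4.25 * 60.0), rel=1e-6)  # 253,725

    def test_one_compartment_vss_is_v1(self):
        fit = fit_profile(make_profile(PKParameters(1, 4.0, 500.0), 7.5), 1)
        vss, _ = derived_parameters(fit)
        assert vss == pytest.approx(500.0, rel=1e-4)
        assert vss >= fit.params.v1
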