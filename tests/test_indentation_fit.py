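"""Contact detection, SLS fitting and validity checks on synthetic records."""

import numpy as np
import pytest

from ivdmech.indentation import (
    check_validity,
    derived_moduli,
    detect_contact,
    fit_sls,
)
from ivdmech.models import (
    AmbiguousContactError,
    ContactPoint,
    IndentProfile,
    IndentationRecord,
    InsufficientDataError,
    NoContactError,
    SLSParams,
)
from ivdmech.synthetic import SyntheticIndentSpec, generate_indent_curve

ZERO_CONTACT = ContactPoint(index=0, t0=0.0, h0=0.0, P0=0.0, threshold_used=0.0)


class TestDetectContact:
    def test_threshold_is_max_of_absolute_and_relative(self, af_control_params):
        # force rise ~0.59 uN: relative criterion 0.5 % gives ~0.003 uN, so
        # the applied threshold is max(0.003, 0.005 * rise)
        rec = generate_indent_curve(
            SyntheticIndentSpec(params=af_control_params, baseline_duration=1.0)
        )
        contact = detect_contact(rec)
        rise = rec.P.max()  # detector uses the smoothed rise, ~0.2 % lower
        assert contact.threshold_used == pytest.approx(max(0.003, 0.005 * rise), rel=0.01)
        # and with a small rise the absolute floor of 0.003 uN applies
        attenuated = generate_indent_curve(
            SyntheticIndentSpec(
                params=SLSParams(2.0, 1.0, 2.0), baseline_duration=1.0
            )
        )
        assert detect_contact(attenuated).threshold_used == pytest.approx(0.003)

    def test_noiseless_contact_found_at_first_force_rise(self, clean_record):
        truth = clean_record.metadata["ground_truth"]["contact_index"]
        contact = detect_contact(clean_record)
        assert abs(contact.index - truth) <= 1
        assert contact.t0 == pytest.approx(clean_record.t[truth], abs=0.02)

    def test_noisy_contact_within_ten_samples(self, af_control_params):
        for seed in range(5):
            rec = generate_indent_curve(
                SyntheticIndentSpec(
                    params=af_control_params,
                    baseline_duration=5.0,
                    noise_sd=0.0005,
                    seed=seed,
                )
            )
            truth = rec.metadata["ground_truth"]["contact_index"]
            assert abs(detect_contact(rec).index - truth) <= 10

    def test_no_contact_error_on_flat_curve(self):
        t = np.arange(200) / 100.0
        rec = IndentationRecord(t=t, h=np.zeros_like(t), P=np.zeros_like(t))
        with pytest.raises(NoContactError):
            detect_contact(rec)

    def test_ambiguous_when_curve_starts_in_contact(self, clean_record):
        # slice away the baseline and early ramp: the record opens mid-ramp,
        # already far above any contact threshold
        start = 150
        rec = IndentationRecord(
            t=clean_record.t[start:],
            h=clean_record.h[start:],
            P=clean_record.P[start:],
        )
        with pytest.raises(AmbiguousContactError):
            detect_contact(rec)


class TestFitSLS:
    def test_noise_free_round_trip_within_one_percent(self, default_profile):
        truth = SLSParams(18.0, 6.0, 2.0)
        rec = generate_indent_curve(
            SyntheticIndentSpec(
                params=truth, baseline_duration=0.0, include_unload=False
            )
        )
        fit = fit_sls(rec, ZERO_CONTACT)
        assert fit.converged
        assert fit.params.E0 == pytest.approx(18.0, rel=0.01)
        assert fit.params.E1 == pytest.approx(6.0, rel=0.01)
        assert fit.params.tau1 == pytest.approx(2.0, rel=0.01)

    def test_purely_elastic_gives_unit_elastic_fraction(self):
        rec = generate_indent_curve(
            SyntheticIndentSpec(
                params=SLSParams(40.0, 0.0, 2.0),
                baseline_duration=0.0,
                include_unload=False,
            )
        )
        fit = fit_sls(rec, ZERO_CONTACT)
        assert fit.f == pytest.approx(1.0, abs=0.01)

    def test_pure_maxwell_gives_zero_elastic_fraction(self):
        rec = generate_indent_curve(
            SyntheticIndentSpec(
                params=SLSParams(0.0, 40.0, 2.0),
                baseline_duration=0.0,
                include_unload=False,
            )
        )
        fit = fit_sls(rec, ZERO_CONTACT)
        assert fit.f == pytest.approx(0.0, abs=0.02)

    def test_full_pipeline_round_trip_table_values(self, clean_record):
        """Synthesize at E_ins = 24 kPa, f = 0.74; detect contact; refit."""
        contact = detect_contact(clean_record)
        fit = fit_sls(clean_record, contact)
        assert fit.E_ins == pytest.approx(24.0, rel=0.01)
        assert fit.f == pytest.approx(0.74, abs=0.01)

    def test_scale_equivariance(self, clean_record):
        contact = detect_contact(clean_record)
        fit1 = fit_sls(clean_record, contact)
        scaled = IndentationRecord(
            t=clean_record.t,
            h=clean_record.h,
            P=clean_record.P * 3.0,
            tip_radius=clean_record.tip_radius,
            poisson_ratio=clean_record.poisson_ratio,
        )
        fit2 = fit_sls(scaled, detect_contact(scaled))
        assert fit2.params.E0 == pytest.approx(3.0 * fit1.params.E0, rel=1e-4)
        assert fit2.params.E1 == pytest.approx(3.0 * fit1.params.E1, rel=1e-4)
        assert fit2.params.tau1 == pytest.approx(fit1.params.tau1, rel=1e-4)
        assert fit2.f == pytest.approx(fit1.f, abs=1e-5)

    def test_noisy_recovery_median_error_below_five_percent(self, af_control_params):
        """Median relative error of E_ins and f < 5 % at 1 % force noise."""
        p_max = 0.6  # approximate peak force, uN
        errs_E, errs_f = [], []
        for seed in range(50):
            rec = generate_indent_curve(
                SyntheticIndentSpec(
                    params=af_control_params,
                    baseline_duration=1.0,
                    noise_sd=0.01 * p_max,
                    seed=seed,
                )
            )
            fit = fit_sls(rec, detect_contact(rec))
            assert 0.0 <= fit.f <= 1.0
            errs_E.append(abs(fit.E_ins - 24.0) / 24.0)
            errs_f.append(abs(fit.f - 0.74) / 0.74)
        assert np.median(errs_E) < 0.05
        assert np.median(errs_f) < 0.05

    def test_insufficient_data_rejected(self):
        t = np.arange(10) / 100.0
        rec = IndentationRecord(t=t, h=t * 2, P=t)
        with pytest.raises(InsufficientDataError):
            fit_sls(rec, ZERO_CONTACT)


class TestDerivedModuli:
    def test_arithmetic(self):
        E_ins, E_eq, f = derived_moduli(SLSParams(18.0, 6.0, 2.0))
        assert (E_ins, E_eq, f) == (24.0, 18.0, 0.75)

    def test_elastic_limit(self):
        assert derived_moduli(SLSParams(10.0, 0.0, 1.0))[2] == 1.0

    def test_undefined_for_zero_moduli(self):
        with pytest.raises(ZeroDivisionError):
            derived_moduli(SLSParams(0.0, 0.0, 1.0))


class TestValidity:
    def test_study_geometry_is_valid(self):
        """R = 42 um, h = 2 um on 25 um sections passes both criteria."""
        report = check_validity(2.0, 42.0, 25.0)
        assert report.representative_strain == pytest.approx(
            0.2 * np.sqrt(84.0) / 42.0, rel=1e-12
        )
        assert report.representative_strain < 0.05
        assert report.depth_to_thickness == pytest.approx(0.08)
        assert report.strain_ok and report.substrate_ok and report.ok

    def test_deep_indent_fails_substrate_criterion(self):
        report = check_validity(3.0, 42.0, 25.0)
        assert report.depth_to_thickness == pytest.approx(0.12)
        assert not report.substrate_ok

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            check_validity(0.0, 42.0, 25.0)
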