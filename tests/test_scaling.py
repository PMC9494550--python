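"""Scaling-law model: prediction, fitting, extrapolation, organ-dose estimate."""

import numpy as np
import pytest

from pbsneutron import scaling
from pbsneutron.scaling import (
    Position,
    PositionCoefficients,
    ScalingModel,
    TreatmentPlan,
    effective_range,
    estimate_organ_dose,
    extrapolate_inverse_square,
    fit_scaling_model,
    predict_h10,
)
from pbsneutron.synthetic_campaign import (
    CampaignDesign,
    default_truth_model,
    generate_campaign,
)


@pytest.fixture
def truth_model():
    return default_truth_model()


class TestTreatmentPlan:
    def test_modulation_beyond_range_rejected(self):
        with pytest.raises(ValueError):
            TreatmentPlan(field_size_cm2=100, range_cm=10, modulation_cm=25)

    def test_out_of_domain_warns_but_constructs(self):
        with pytest.warns(UserWarning):
            plan = TreatmentPlan(field_size_cm2=900, range_cm=15, modulation_cm=10)
        assert plan.field_size_cm2 == 900


class TestEffectiveRange:
    def test_shifter_adds_wet(self):
        plan = TreatmentPlan(100, 10, 5, range_shifter=True, air_gap_cm=10)
        assert effective_range(plan) == pytest.approx(13.1)

    def test_no_shifter_identity(self):
        assert effective_range(TreatmentPlan(100, 10, 5)) == 10.0

    def test_zero_wet_edge(self):
        plan = TreatmentPlan(100, 25, 10, range_shifter=True, air_gap_cm=10, rs_wet_cm=0.0)
        assert effective_range(plan) == 25.0


class TestPredictH10:
    def test_field_size_factor_of_100(self, truth_model):
        with pytest.warns(UserWarning):  # 900 cm2 is outside the campaign domain
            big = TreatmentPlan(900, 15, 10)
        small = TreatmentPlan(9, 15, 10)
        ratio = predict_h10(truth_model, big, "B") / predict_h10(truth_model, small, "B")
        assert ratio == pytest.approx(100.0, rel=1e-12)

    def test_reference_plan_returns_baseline(self, truth_model):
        h = predict_h10(truth_model, scaling.REFERENCE_PLAN, "B")
        assert h == pytest.approx(truth_model.coefficients["B"].a0, rel=1e-12)

    def test_exactly_linear_in_field_size(self, truth_model):
        p1 = TreatmentPlan(50, 20, 5)
        p2 = TreatmentPlan(350, 20, 5)
        r = predict_h10(truth_model, p2, "F") / predict_h10(truth_model, p1, "F")
        assert r == pytest.approx(7.0, rel=1e-12)

    def test_range_shifter_increases_dose(self, truth_model):
        on = TreatmentPlan(100, 12, 5, range_shifter=True, air_gap_cm=10)
        off = TreatmentPlan(100, 12, 5)
        assert predict_h10(truth_model, on, "B") > predict_h10(truth_model, off, "B")

    def test_flat_factor_mode(self, truth_model):
        model = ScalingModel(
            coefficients=truth_model.coefficients,
            rs_mode="flat_factor",
            flat_factor=2.0,
        )
        on = TreatmentPlan(100, 12, 5, range_shifter=True, air_gap_cm=10)
        off = TreatmentPlan(100, 12, 5)
        assert predict_h10(model, on, "B") == pytest.approx(
            2.0 * predict_h10(model, off, "B"), rel=1e-12
        )

    def test_unknown_position_rejected(self, truth_model):
        with pytest.raises(KeyError):
            predict_h10(truth_model, TreatmentPlan(100, 15, 10), "Z")

    def test_invalid_coefficients_raise_model_validity_error(self):
        model = ScalingModel(
            coefficients={"B": PositionCoefficients(a0=1.0, c_range=-0.2, c_mod1=0, c_mod2=0)}
        )
        with pytest.raises(ValueError):
            predict_h10(model, TreatmentPlan(100, 25, 3), "B")  # range term goes negative


class TestFitScalingModel:
    def test_exact_recovery_on_noise_free_campaign(self, truth_model):
        _, true_table, _ = generate_campaign(
            CampaignDesign(noise_sigma=0.0, seed=3), truth_model
        )
        fit = fit_scaling_model(true_table)
        for pos, c_true in truth_model.coefficients.items():
            c = fit.model.coefficients[pos]
            assert c.a0 == pytest.approx(c_true.a0, rel=1e-6)
            assert c.c_range == pytest.approx(c_true.c_range, rel=1e-6, abs=1e-9)
            assert c.c_mod1 == pytest.approx(c_true.c_mod1, rel=1e-6, abs=1e-9)
            assert c.c_mod2 == pytest.approx(c_true.c_mod2, rel=1e-4, abs=1e-9)

    def test_noisy_recovery_within_three_standard_errors(self, truth_model):
        measured, _, _ = generate_campaign(
            CampaignDesign(noise_sigma=0.15, seed=11), truth_model
        )
        fit = fit_scaling_model(measured)
        for pos, c_true in truth_model.coefficients.items():
            c = fit.model.coefficients[pos]
            se = fit.diagnostics[pos]["stderr"]
            assert fit.diagnostics[pos]["n_rows"] >= 60
            assert abs(np.log(c.a0) - np.log(c_true.a0)) < 3 * se["log_a0"]
            assert abs(c.c_range - c_true.c_range) < 3 * se["c_range"]
            assert abs(c.c_mod1 - c_true.c_mod1) < 3 * se["c_mod1"]
            assert abs(c.c_mod2 - c_true.c_mod2) < 3 * se["c_mod2"]

    def test_row_permutation_invariance(self, truth_model):
        _, true_table, _ = generate_campaign(
            CampaignDesign(noise_sigma=0.0, seed=3), truth_model
        )
        shuffled = scaling.CampaignTable(
            true_table.rows.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        f1 = fit_scaling_model(true_table)
        f2 = fit_scaling_model(shuffled)
        for pos in f1.model.coefficients:
            assert f1.model.coefficients[pos] == f2.model.coefficients[pos]

    def test_single_field_size_rejected_naming_axis(self, truth_model):
        _, true_table, _ = generate_campaign(
            CampaignDesign(field_sizes_cm2=(100.0,), noise_sigma=0.0, seed=3),
            truth_model,
        )
        with pytest.raises(ValueError, match="field_size"):
            fit_scaling_model(true_table)

    def test_too_few_modulations_rejected(self, truth_model):
        _, true_table, _ = generate_campaign(
            CampaignDesign(modulations_cm=(5.0, 10.0), noise_sigma=0.0, seed=3),
            truth_model,
        )
        with pytest.raises(ValueError, match="modulation"):
            fit_scaling_model(true_table)


class TestInverseSquare:
    @pytest.mark.parametrize(
        "d_ref,d_target,factor", [(1.0, 1.0, 1.0), (1.0, 0.5, 4.0), (1.0, 0.1, 100.0)]
    )
    def test_closed_form(self, d_ref, d_target, factor):
        assert extrapolate_inverse_square(10.0, d_ref, d_target) == pytest.approx(
            10.0 * factor, rel=1e-12
        )

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_inverse_square(10.0, 1.0, 0.0)


class TestEstimateOrganDose:
    def test_field_size_correction_factor_of_three(self, truth_model):
        """100 -> 33 cm^2 gives a field factor of 0.33, i.e. division by ~3."""
        ref_plan = TreatmentPlan(100, 20, 5)
        target_plan = TreatmentPlan(33, 18, 5)
        est = estimate_organ_dose(
            reference_h10=50.0,
            reference_plan=ref_plan,
            target_plan=target_plan,
            position=Position("B", 1.0, 0.0),
            target_distance_m=0.5,
            model=truth_model,
        )
        assert est.factors["field_size"] == pytest.approx(0.33, rel=1e-12)
        assert 1.0 / est.factors["field_size"] == pytest.approx(3.03, abs=0.005)

    def test_identity_chain(self, truth_model):
        plan = TreatmentPlan(100, 20, 5)
        est = estimate_organ_dose(
            reference_h10=42.0,
            reference_plan=plan,
            target_plan=plan,
            position=Position("F", 1.5, 90.0),
            target_distance_m=1.5,
            model=truth_model,
        )
        assert est.dose_uSv_per_Gy == pytest.approx(42.0, rel=1e-12)
        assert all(f == pytest.approx(1.0, rel=1e-12) for f in est.factors.values())

    def test_inverse_square_only(self, truth_model):
        plan = TreatmentPlan(100, 20, 5)
        est = estimate_organ_dose(
            reference_h10=10.0,
            reference_plan=plan,
            target_plan=plan,
            position=Position("B", 1.0, 0.0),
            target_distance_m=0.5,
            model=truth_model,
        )
        assert est.dose_uSv_per_Gy == pytest.approx(40.0, rel=1e-12)

    def test_factorization_identity(self, truth_model):
        est = estimate_organ_dose(
            reference_h10=17.0,
            reference_plan=TreatmentPlan(100, 20, 5),
            target_plan=TreatmentPlan(33, 18, 8, range_shifter=True, air_gap_cm=12),
            position=Position("B", 1.0, 0.0),
            target_distance_m=0.1,
            model=truth_model,
        )
        product = 17.0
        for f in est.factors.values():
            product *= f
        assert est.dose_uSv_per_Gy == pytest.approx(product, rel=1e-12)


class TestRangeShifterBound:
    def test_rs_ratio_bounded_at_non_d_positions(self, truth_model):
        """RS-on/off ratio stays within [1, 2.5] except at the position in
        line of sight of the shifter."""
        for pos in "ABCEF":
            for r in (8.0, 10.0, 15.0, 20.0, 25.0):
                for m in (3.0, 5.0):
                    on = TreatmentPlan(100, r, m, range_shifter=True, air_gap_cm=10)
                    off = TreatmentPlan(100, r, m)
                    ratio = predict_h10(truth_model, on, pos) / predict_h10(
                        truth_model, off, pos
                    )
                    assert 1.0 <= ratio <= 2.5

    def test_rs_ratio_can_exceed_bound_at_d(self, truth_model):
        on = TreatmentPlan(100, 8, 3, range_shifter=True, air_gap_cm=10)
        off = TreatmentPlan(100, 8, 3)
        assert predict_h10(truth_model, on, "D") / predict_h10(truth_model, off, "D") > 2.5
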