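import math

import numpy as np
import pytest

from electrodyne import (
    ElectrodeGeometry,
    ExcursionDataset,
    ExcursionModel,
    PulseWaveform,
    SafetyLimits,
    UnitsDecl,
    UnitsMismatchError,
    ValidationError,
    check_pulse,
    compare_to_shannon,
    current_limit_from_model,
    current_limit_vs_diameter,
    fit_excursion_model,
    gen_excursion_dataset,
    predict_excursion,
    shannon_limit,
    NoiseSpec,
)


class TestPredictExcursion:
    def test_zero_current_gives_zero_excursion(self, truth_excursion_model):
        assert predict_excursion(truth_excursion_model, 0.0, 100.0, 30.0) == 0.0

    def test_scalar_arithmetic_oracle(self):
        # a*ln(b*I^k2*t^k4*Z^k6 + 1) with everything 1 except b=2: 0.5*ln(3)
        model = ExcursionModel(0.5, 2.0, 1.0, 0.5, 0.5)
        assert predict_excursion(model, 1.0, 1.0, 1.0) == pytest.approx(0.5 * math.log(3.0))

    def test_small_argument_linearization(self):
        model = ExcursionModel(0.5, 1e-6, 1.0, 1.0, 1.0)
        v = predict_excursion(model, 1.0, 1.0, 1.0)  # arg = 1e-6
        assert v == pytest.approx(0.5 * 1e-6, rel=1e-4)

    def test_strictly_increasing_in_each_input(self, truth_excursion_model):
        base = predict_excursion(truth_excursion_model, 100.0, 200.0, 30.0)
        assert predict_excursion(truth_excursion_model, 150.0, 200.0, 30.0) > base
        assert predict_excursion(truth_excursion_model, 100.0, 300.0, 30.0) > base
        assert predict_excursion(truth_excursion_model, 100.0, 200.0, 45.0) > base

    def test_units_mismatch_raises_instead_of_converting(self, truth_excursion_model):
        other = UnitsDecl(current="mA", time="ms", impedance="ohm")
        with pytest.raises(UnitsMismatchError):
            predict_excursion(truth_excursion_model, 1.0, 1.0, 1.0, units=other)


class TestCurrentLimit:
    def test_round_trip_inversion(self, truth_excursion_model):
        i = current_limit_from_model(truth_excursion_model, -0.6, 200.0, 30.0)
        v = predict_excursion(truth_excursion_model, i, 200.0, 30.0)
        assert v == pytest.approx(0.6, rel=1e-10)

    def test_inverse_of_predict_oracle(self):
        model = ExcursionModel(0.5, 2.0, 1.0, 0.5, 0.5)
        assert current_limit_from_model(model, 0.5 * math.log(3.0), 1.0, 1.0) == pytest.approx(
            1.0, rel=1e-10
        )

    def test_monotone_decreasing_in_pulse_width_and_impedance(self, truth_excursion_model):
        t_grid = np.logspace(1, 3.5, 60)
        i_t = [current_limit_from_model(truth_excursion_model, -0.6, t, 30.0) for t in t_grid]
        assert np.all(np.diff(i_t) < 0)
        z_grid = np.logspace(0, 3, 60)
        i_z = [current_limit_from_model(truth_excursion_model, -0.6, 200.0, z) for z in z_grid]
        assert np.all(np.diff(i_z) < 0)

    def test_in_vivo_impedance_rise_lowers_the_limit(self, truth_excursion_model):
        # media ordering: higher interface impedance in tissue than benchtop saline
        benchtop = current_limit_from_model(truth_excursion_model, -0.6, 200.0, 20.0)
        in_vivo = current_limit_from_model(truth_excursion_model, -0.6, 200.0, 60.0)
        assert in_vivo < benchtop


class TestDiameterScaledLimit:
    def test_algebraic_identity_with_direct_substitution(self, truth_excursion_model):
        # the diameter-scaled closed form must equal evaluating the base
        # inversion at z = alpha*D^-d1 on randomized parameter draws
        rng = np.random.default_rng(3)
        for _ in range(10):
            model = ExcursionModel(
                a_scale=rng.uniform(0.1, 1.0),
                b_coeff=10 ** rng.uniform(-4, -1),
                k2_exp=rng.uniform(0.5, 1.5),
                k4_exp=rng.uniform(0.2, 0.8),
                k6_exp=rng.uniform(0.3, 1.2),
            )
            alpha, d1 = 10 ** rng.uniform(-3, -1), rng.uniform(0.5, 2.0)
            limits = SafetyLimits(e_mc=-rng.uniform(0.3, 1.0), alpha_coeff=alpha, d1_exp=d1)
            d = rng.uniform(10e-6, 1e-3)
            i_scaled = current_limit_vs_diameter(limits, model, d, 200.0)
            z_kohm = alpha * d**-d1 / 1e3
            i_direct = current_limit_from_model(model, limits.e_mc, 200.0, z_kohm)
            assert i_scaled == pytest.approx(i_direct, rel=1e-10)

    def test_larger_diameter_allows_more_current(self, truth_excursion_model):
        limits = SafetyLimits(e_mc=-0.6, alpha_coeff=1e-2, d1_exp=1.5)
        i_small = current_limit_vs_diameter(limits, truth_excursion_model, 30e-6, 200.0)
        i_large = current_limit_vs_diameter(limits, truth_excursion_model, 300e-6, 200.0)
        assert i_large > i_small

    def test_missing_scaling_is_an_instructive_error(self, truth_excursion_model):
        with pytest.raises(ValidationError, match="fit_diameter_scaling"):
            current_limit_vs_diameter(SafetyLimits(), truth_excursion_model, 30e-6, 200.0)


class TestShannonLimit:
    def test_matches_charge_density_derivation(self):
        # independent oracle: Q^2/A = 10^k (Q in uC, A in cm^2) on a disc
        for d_m, t_s, k in [(200e-6, 200e-6, 1.85), (1e-3, 500e-6, 1.5), (30e-6, 100e-6, 2.0)]:
            d_cm = d_m * 100
            area = math.pi * d_cm**2 / 4
            q_uc = math.sqrt(area * 10**k)
            expected_a = q_uc / t_s * 1e-6
            assert shannon_limit(d_m, t_s, k) == pytest.approx(expected_a, rel=1e-12)

    def test_worked_example_200um_200us(self):
        # Q = 0.01*sqrt(pi*10^1.85) uC ~= 0.1491 uC -> I ~= 746 uA
        i = shannon_limit(200e-6, 200e-6, 1.85)
        q_uc = i * 200e-6 * 1e6
        assert q_uc == pytest.approx(0.01 * math.sqrt(math.pi * 10**1.85), rel=1e-12)
        assert i == pytest.approx(745.7e-6, rel=1e-3)

    def test_linear_in_diameter_and_inverse_in_pulse_width(self):
        base = shannon_limit(100e-6, 200e-6)
        assert shannon_limit(200e-6, 200e-6) == pytest.approx(2 * base, rel=1e-12)
        assert shannon_limit(100e-6, 400e-6) == pytest.approx(base / 2, rel=1e-12)


class TestFitExcursionModel:
    def test_noise_free_identifiability(self, truth_excursion_model, excursion_grids):
        data = gen_excursion_dataset(truth_excursion_model, *excursion_grids, NoiseSpec(sigma=0.0))
        init = ExcursionModel(0.5, 0.01, 1.0, 0.5, 0.5)
        fitted, diag = fit_excursion_model(data, init, seed=0)
        for name in ("a_scale", "b_coeff", "k2_exp", "k4_exp", "k6_exp"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(truth_excursion_model, name), rel=1e-3
            ), name
        assert diag.rmse < 1e-6

    def test_five_millivolt_noise_recovery_within_fifteen_percent(
        self, truth_excursion_model, excursion_grids
    ):
        data = gen_excursion_dataset(
            truth_excursion_model,
            *excursion_grids,
            NoiseSpec(kind="additive_gaussian", sigma=0.005, seed=11),
        )
        assert len(data) == 60
        fitted, diag = fit_excursion_model(data, ExcursionModel(0.5, 0.01, 1.0, 0.5, 0.5), seed=11)
        for name in ("a_scale", "b_coeff", "k2_exp", "k4_exp", "k6_exp"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(truth_excursion_model, name), rel=0.15
            ), name

    def test_rank_deficient_design_rejected(self, truth_excursion_model):
        data = ExcursionDataset(
            i_inj=np.full(25, 100.0),  # single current level
            t_pw=np.tile(np.logspace(1, 3, 5), 5),
            z_imag_mag=np.full(25, 30.0),
            v_elec=np.linspace(0.1, 0.5, 25),
        )
        with pytest.raises(ValidationError, match="i_inj"):
            fit_excursion_model(data, truth_excursion_model, seed=0)

    def test_too_few_rows_rejected(self, truth_excursion_model):
        data = gen_excursion_dataset(
            truth_excursion_model, [10.0, 200.0], [50.0, 600.0], [30.0], NoiseSpec()
        )
        with pytest.raises(ValidationError, match="20"):
            fit_excursion_model(data, truth_excursion_model, seed=0)


class TestCompareToShannon:
    def test_grid_shape_and_determinism(self, truth_excursion_model):
        limits = SafetyLimits(e_mc=-0.6, alpha_coeff=1e-2, d1_exp=1.5)
        d = np.array([30e-6, 100e-6, 300e-6])
        t = np.array([100e-6, 200e-6])
        a = compare_to_shannon(truth_excursion_model, limits, d, t)
        b = compare_to_shannon(truth_excursion_model, limits, d, t)
        assert len(a) == 6
        assert a.equals(b)

    def test_model_can_exceed_shannon(self, truth_excursion_model):
        # a low-impedance parameterization yields ratio > 1 somewhere
        limits = SafetyLimits(e_mc=-0.9, alpha_coeff=1e-3, d1_exp=1.2, shannon_k=1.5)
        table = compare_to_shannon(
            truth_excursion_model, limits, [100e-6, 300e-6], [100e-6, 200e-6]
        )
        assert (table["ratio"] > 1).any()
        np.testing.assert_allclose(
            table["ratio"], table["i_limit_model_a"] / table["i_limit_shannon_a"]
        )


class TestCheckPulse:
    def test_micro_contact_at_four_nanocoulomb_limit(self):
        # 20 uA x 200 us = 4 nC exactly: flagged AT the micro limit
        geom = ElectrodeGeometry(diameter=30e-6, separation=50e-6, contact_class="micro")
        wave = PulseWaveform(amplitude=-20e-6, t_pw=200e-6)
        report = check_pulse(geom, wave, SafetyLimits())
        assert report.charge_per_phase_c == pytest.approx(4e-9, rel=1e-12)
        assert report.charge_status == "at_limit"
        assert report.passed

    def test_macro_contact_at_thirty_microcoulomb_per_cm2(self):
        d = 2.3e-3
        geom = ElectrodeGeometry(diameter=d, separation=5e-3, contact_class="macro")
        area_cm2 = math.pi * (d * 100) ** 2 / 4
        q_c = 30.0 * area_cm2 * 1e-6  # charge that hits 30 uC/cm^2 exactly
        t_pw = 500e-6
        wave = PulseWaveform(amplitude=-q_c / t_pw, t_pw=t_pw)
        report = check_pulse(geom, wave, SafetyLimits())
        assert report.charge_density_uc_cm2 == pytest.approx(30.0, rel=1e-12)
        assert report.charge_status == "at_limit"

    def test_zero_amplitude_consumes_no_margin(self):
        geom = ElectrodeGeometry(diameter=30e-6, separation=50e-6)
        wave = PulseWaveform(amplitude=0.0, t_pw=200e-6)
        report = check_pulse(geom, wave, SafetyLimits())
        assert report.charge_status == "pass"
        assert report.charge_margin == 0.0

    def test_excursion_check_runs_when_model_supplied(self, truth_excursion_model):
        geom = ElectrodeGeometry(diameter=30e-6, separation=50e-6)
        wave = PulseWaveform(amplitude=-2e-6, t_pw=100e-6)
        report = check_pulse(
            geom, wave, SafetyLimits(e_mc=-0.6), model=truth_excursion_model, z_imag_mag=30.0
        )
        expected = predict_excursion(truth_excursion_model, 2.0, 100.0, 30.0)
        assert report.excursion_v == pytest.approx(expected)
        assert report.excursion_status in ("pass", "at_limit", "fail")

    def test_missing_model_downgrades_with_notice(self):
        geom = ElectrodeGeometry(diameter=30e-6, separation=50e-6)
        report = check_pulse(geom, PulseWaveform(amplitude=-1e-6, t_pw=100e-6), SafetyLimits())
        assert report.excursion_v is None
        assert any("charge-only" in n for n in report.notes)
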