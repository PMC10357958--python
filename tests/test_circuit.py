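import math

import numpy as np
import pytest

from electrodyne import (
    CPEParams,
    ImpedanceSpectrum,
    InterfaceCircuit,
    PulseWaveform,
    ValidationError,
    cpe_impedance,
    interface_impedance,
    spreading_resistance,
)


class TestCPE:
    def test_ideal_capacitor_at_unit_angular_frequency(self):
        # n=1 -> Z = 1/(jwC); at w = 1 rad/s with C = 1 uF, Z = -j*1e6
        z = cpe_impedance(CPEParams(q_coeff=1e-6, n_exp=1.0), 1.0 / (2 * math.pi))
        assert z == pytest.approx(-1e6j)

    @pytest.mark.parametrize("n_exp", [0.3, 0.5, 0.8, 1.0])
    def test_phase_is_minus_n_times_90_deg_at_any_frequency(self, n_exp):
        for f in (0.1, 1e3, 1e6):
            z = cpe_impedance(CPEParams(q_coeff=3e-8, n_exp=n_exp), f)
            assert np.degrees(np.angle(z)) == pytest.approx(-n_exp * 90.0, abs=1e-9)

    def test_magnitude_matches_closed_form(self):
        # |Z| = 1/(Q*(2*pi*f)^n), evaluated independently by scalar arithmetic
        q, n, f = 1e-7, 0.8, 1000.0
        expected = 1.0 / (q * (2 * math.pi * f) ** n)
        assert abs(cpe_impedance(CPEParams(q, n), f)) == pytest.approx(expected, rel=1e-12)

    def test_cpe_to_capacitor_limit_across_log_grid(self):
        # n=1 equals 1/(jwC) to machine precision on 50 log-spaced frequencies
        c = 2.2e-9
        freqs = np.logspace(-1, 6, 50)
        z = cpe_impedance(CPEParams(q_coeff=c, n_exp=1.0), freqs)
        np.testing.assert_allclose(z, 1.0 / (1j * 2 * np.pi * freqs * c), rtol=1e-14)

    def test_invalid_fields_name_the_offender(self):
        with pytest.raises(ValidationError, match="q_coeff"):
            CPEParams(q_coeff=-1.0, n_exp=0.8)
        with pytest.raises(ValidationError, match="n_exp"):
            CPEParams(q_coeff=1e-6, n_exp=1.5)
        with pytest.raises(ValidationError, match="freq"):
            cpe_impedance(CPEParams(1e-6, 0.8), -5.0)


class TestInterfaceImpedance:
    def test_high_frequency_limit_is_series_resistance(self):
        circ = InterfaceCircuit(
            c_dl=CPEParams(1e-7, 0.9), r_ct=math.inf, c_f=None, r_spread=900.0, r_bulk=100.0
        )
        # find a frequency where |Z_CPE| < r_series/100; Z must equal r_series within 1%
        f = 1e9
        assert abs(cpe_impedance(circ.c_dl, f)) < circ.r_series / 100
        z = interface_impedance(circ, [f]).z_complex[0]
        assert abs(z) == pytest.approx(1000.0, rel=0.01)

    def test_purely_capacitive_reduces_to_series_plus_cpe(self):
        cpe = CPEParams(1e-7, 0.85)
        circ = InterfaceCircuit(c_dl=cpe, r_ct=math.inf, c_f=None, r_spread=500.0, r_bulk=50.0)
        freqs = np.logspace(0, 5, 20)
        z = interface_impedance(circ, freqs).z_complex
        np.testing.assert_allclose(z, 550.0 + cpe_impedance(cpe, freqs), rtol=1e-14)

    def test_resistor_only_circuit_is_flat(self):
        circ = InterfaceCircuit(c_dl=None, r_ct=5000.0, c_f=None, r_spread=300.0, r_bulk=200.0)
        z = interface_impedance(circ, np.logspace(-1, 6, 30)).z_complex
        np.testing.assert_allclose(z, 5500.0 + 0j, rtol=1e-14)

    def test_low_frequency_dominated_by_faradaic_branch(self, truth_circuit):
        # at f -> 0 the double-layer CPE blocks; |Z| approaches the faradaic branch
        f = 1e-6
        z = interface_impedance(truth_circuit, [f]).z_complex[0]
        z_f = truth_circuit.r_ct + cpe_impedance(truth_circuit.c_f, f)
        z_dl = cpe_impedance(truth_circuit.c_dl, f)
        expected = truth_circuit.r_series + z_dl * z_f / (z_dl + z_f)
        assert z == pytest.approx(expected, rel=1e-12)
        assert abs(z) < abs(z_dl)  # parallel branch below the blocking CPE alone

    def test_empty_grid_rejected(self, truth_circuit):
        with pytest.raises(ValidationError):
            interface_impedance(truth_circuit, [])

    def test_infinite_rct_requires_double_layer_branch(self):
        with pytest.raises(ValidationError, match="r_ct"):
            InterfaceCircuit(c_dl=None, r_ct=math.inf, c_f=None, r_spread=1.0, r_bulk=0.0)


class TestSpreadingResistance:
    def test_disc_access_formula(self):
        # rho/(2D) with rho = 0.7 ohm*m (gray matter scale), D = 30 um
        assert spreading_resistance(0.7, 30e-6) == pytest.approx(0.7 / (2 * 30e-6))

    def test_inverse_diameter_scaling(self):
        assert spreading_resistance(0.7, 60e-6) == pytest.approx(
            spreading_resistance(0.7, 30e-6) / 2
        )

    @pytest.mark.parametrize("rho,d", [(0.0, 1e-5), (0.7, 0.0), (-1.0, 1e-5)])
    def test_nonpositive_inputs_rejected(self, rho, d):
        with pytest.raises(ValidationError):
            spreading_resistance(rho, d)


class TestImpedanceSpectrum:
    def test_magnitude_and_phase_views_consistent(self):
        freqs = np.logspace(0, 4, 10)
        z = (1 + 1j) * 100.0 * np.ones(10)
        spec = ImpedanceSpectrum(freqs=freqs, z_complex=z)
        np.testing.assert_allclose(spec.magnitude, np.abs(z))
        np.testing.assert_allclose(
            spec.magnitude * np.exp(1j * np.radians(spec.phase_deg)), z, rtol=1e-12
        )

    def test_validation_rejects_bad_spectra(self):
        with pytest.raises(ValidationError):
            ImpedanceSpectrum(freqs=[1.0, 2.0], z_complex=[1 + 0j])  # length mismatch
        with pytest.raises(ValidationError):
            ImpedanceSpectrum(freqs=[2.0, 1.0], z_complex=[1 + 0j, 1 + 0j])  # unsorted
        with pytest.raises(ValidationError):
            ImpedanceSpectrum(freqs=[1.0, 2.0], z_complex=[np.nan + 0j, 1 + 0j])


class TestPulseWaveform:
    def test_charge_per_phase_exact(self):
        wave = PulseWaveform(amplitude=-20e-6, t_pw=200e-6)
        assert wave.charge_per_phase == 20e-6 * 200e-6

    def test_biphasic_current_shape(self):
        wave = PulseWaveform(
            amplitude=-1e-6, t_pw=1e-3, interphase_gap=2e-4, biphasic=True, dt=1e-5
        )
        t = np.array([5e-4, 1.1e-3, 1.3e-3, 2.3e-3])
        np.testing.assert_allclose(wave.current(t), [-1e-6, 0.0, 1e-6, 0.0])

    def test_dt_resolution_floor_enforced(self):
        with pytest.raises(ValidationError, match="dt"):
            PulseWaveform(amplitude=1e-6, t_pw=1e-3, dt=1e-3 / 10)
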