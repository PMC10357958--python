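"""Recording-side forward models for scaled electrode contacts.

Covers the signal path from electrode surface to digitizer: the
voltage-divider coupling coefficient against the amplifier input
impedance, Johnson-Nyquist thermal noise of the interface resistance,
axonal conduction delay between contacts, a capacitive-crosstalk bound,
and the raw acquisition data-rate budget of a channel array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "RecordingFrontEnd",
    "coupling_coefficient",
    "thermal_noise_rms",
    "conduction_delay",
    "data_rate",
    "crosstalk_bound",
    "flicker_noise_psd",
]

BOLTZMANN = 1.380649e-23  # J/K, exact (SI)


@dataclass(frozen=True)
class RecordingFrontEnd:
    """Amplifier front end and digitizer of one recording channel array."""

    r_in: float = 16e6  # input resistance, ohm (16 Mohm at 1 kHz)
    c_in: float = 1e-12  # amplifier input capacitance, F
    c_parasitic: float = 1e-12  # lead shunt / inter-lead capacitance, F
    bandwidth: float = 10e3  # Hz
    sample_rate: float = 30e3  # Hz
    bit_depth: int = 16
    n_channels: int = 4096

    def __post_init__(self):
        for name in ("r_in", "c_in", "c_parasitic", "bandwidth", "sample_rate"):
            if not (getattr(self, name) > 0):
                raise ValidationError(name, "must be > 0")
        if self.bit_depth < 1 or self.n_channels < 1:
            raise ValidationError("bit_depth/n_channels", "must be >= 1")

    @property
    def nyquist_ok(self) -> bool:
        """Whether the sample rate satisfies Nyquist for the analog bandwidth."""
        return self.sample_rate >= 2 * self.bandwidth

    def input_shunt_impedance(self, freq: float) -> complex:
        """r_in in parallel with the total shunt capacitance, at *freq*."""
        if not (freq > 0):
            raise ValidationError("freq", "must be > 0")
        y = 1.0 / self.r_in + 1j * 2 * math.pi * freq * (self.c_in + self.c_parasitic)
        return 1.0 / y


def coupling_coefficient(z_elec: complex, fe: RecordingFrontEnd, freq: float) -> float:
    """Recorded-over-source amplitude ratio of the electrode/amplifier divider.

    CC = |Z_shunt| / |Z_shunt + Z_elec| with Z_shunt the amplifier input
    resistance in parallel with all shunt capacitance. Equals 1 only for
    a zero-impedance electrode and decreases as the electrode impedance
    grows, which is why high-impedance contacts attenuate (and
    high-pass-distort) the recorded signal.
    """
    z_shunt = fe.input_shunt_impedance(freq)
    return abs(z_shunt) / abs(z_shunt + z_elec)


def thermal_noise_rms(freqs, re_z, temperature: float = 310.0) -> float:
    """Johnson-Nyquist noise v_rms = sqrt(4*k_B*T*integral(Re Z df)), volts.

    *freqs* is the integration band: either a (f_lo, f_hi) pair with a
    scalar (flat) *re_z*, or an ascending frequency grid matched by a
    Re{Z(f)} profile (trapezoid integration). For flat resistance the
    closed form sqrt(4*k_B*T*R*B) is recovered exactly.
    """
    freqs = np.asarray(freqs, dtype=float)
    re_z_arr = np.asarray(re_z, dtype=float)
    if freqs.ndim != 1 or freqs.size < 2:
        raise ValidationError("freqs", "need at least (f_lo, f_hi)")
    if not np.all(np.isfinite(freqs)) or not np.all(freqs >= 0) or np.any(np.diff(freqs) <= 0):
        raise ValidationError("freqs", "must be finite, nonnegative, ascending")
    if not (temperature > 0):
        raise ValidationError("temperature", "must be > 0")
    if re_z_arr.ndim == 0:
        re_z_arr = np.full_like(freqs, float(re_z_arr))
    if re_z_arr.shape != freqs.shape:
        raise ValidationError("re_z", "profile must match the frequency grid")
    if np.any(re_z_arr < 0):
        raise ValidationError("re_z", "negative Re{Z} is non-physical")
    integral = float(np.trapezoid(re_z_arr, freqs))
    return math.sqrt(4.0 * BOLTZMANN * temperature * integral)


def flicker_noise_psd(freqs, amplitude: float, beta: float = 1.0) -> np.ndarray:
    """Optional empirical 1/f (flicker) noise PSD A/f**beta, V^2/Hz.

    Disabled unless explicitly invoked with a user-supplied amplitude;
    the package ships no default flicker magnitude.
    """
    freqs = np.asarray(freqs, dtype=float)
    if not np.all(freqs > 0):
        raise ValidationError("freqs", "must be > 0")
    if amplitude < 0:
        raise ValidationError("amplitude", "must be >= 0")
    return amplitude / freqs**beta


def conduction_delay(separation: float, speed: float) -> float:
    """Propagation delay (s) of a neural signal across *separation* (m).

    Typical propagation speeds are 0.2-1 m/s; 50 um at 1 m/s gives the
    50 us worst-case inter-contact delay for adjacent microcontacts.
    """
    if not (separation > 0):
        raise ValidationError("separation", "must be > 0")
    if not (speed > 0):
        raise ValidationError("speed", "must be > 0")
    return separation / speed


def data_rate(fe: RecordingFrontEnd) -> int:
    """Raw acquisition rate in bits/s: channels x sample rate x bit depth.

    Exact integer arithmetic (sample rate is rounded to an integer Hz);
    divide by 1e9 for decimal Gbps.
    """
    return fe.n_channels * int(round(fe.sample_rate)) * fe.bit_depth


def crosstalk_bound(z_elec: float, c_interlead: float, freq: float) -> float:
    """Upper-bound fraction of a neighbor's signal coupled through lead capacitance.

    Divider bound |Z_elec| / (|Z_elec| + |1/(j*w*C)|): grows with
    electrode impedance and with inter-lead capacitance, so
    high-impedance contacts on dense arrays are the most susceptible.
    """
    if not (freq > 0):
        raise ValidationError("freq", "must be > 0")
    if c_interlead < 0:
        raise ValidationError("c_interlead", "must be >= 0")
    z_mag = abs(z_elec)
    if c_interlead == 0:
        return 0.0
    z_c = 1.0 / (2 * math.pi * freq * c_interlead)
    return z_mag / (z_mag + z_c)
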