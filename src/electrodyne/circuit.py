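"""Equivalent-circuit model of the electrode-tissue interface.

The interface is modeled as a Randles-like network: a double-layer
constant-phase element (CPE) in parallel with a faradaic branch (charge
transfer resistance in series with a second CPE), the whole in series
with the spreading resistance of the tissue near the contact and the
bulk conduction resistance,

    Z(f) = R_bulk + R_spread + [ Z_CDL || (R_CT + Z_CF) ].

A CPE is the standard-electrochemistry non-ideal capacitor

    Z_CPE(omega) = 1 / (Q * (j*omega)**n),     0 < n <= 1,

whose phase is -n*90 degrees at every frequency; n = 1 recovers an ideal
capacitor of capacitance Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "CPEParams",
    "InterfaceCircuit",
    "ImpedanceSpectrum",
    "PulseWaveform",
    "cpe_impedance",
    "interface_impedance",
    "spreading_resistance",
]


@dataclass(frozen=True)
class CPEParams:
    """Constant-phase element.

    Parameters
    ----------
    q_coeff
        CPE magnitude coefficient in S*s^n (admittance at omega = 1 rad/s).
    n_exp
        Fractional exponent in (0, 1]; 1 is an ideal capacitor.
    """

    q_coeff: float
    n_exp: float

    def __post_init__(self):
        if not (self.q_coeff > 0):
            raise ValidationError("q_coeff", f"must be > 0, got {self.q_coeff}")
        if not (0 < self.n_exp <= 1):
            raise ValidationError("n_exp", f"must be in (0, 1], got {self.n_exp}")


@dataclass(frozen=True)
class InterfaceCircuit:
    """Full electrode-tissue interface network.

    ``r_ct=math.inf`` flags a purely capacitive interface (no faradaic
    path); it is an explicit flag, never a large float, to avoid
    conditioning artifacts. ``c_dl``/``c_f`` may be ``None`` to disable
    the corresponding branch (resistor-only degenerate circuits are used
    in tests and sanity checks).
    """

    c_dl: CPEParams | None
    r_ct: float
    c_f: CPEParams | None
    r_spread: float
    r_bulk: float
    label: str = ""

    def __post_init__(self):
        for name in ("r_spread", "r_bulk"):
            v = getattr(self, name)
            if not (v >= 0) or math.isinf(v) or math.isnan(v):
                raise ValidationError(name, f"must be finite and >= 0, got {v}")
        if math.isnan(self.r_ct) or self.r_ct < 0:
            raise ValidationError("r_ct", f"must be >= 0 (inf allowed), got {self.r_ct}")
        if self.c_dl is None and math.isinf(self.r_ct):
            raise ValidationError("r_ct", "cannot be infinite when the double-layer branch is absent")

    @property
    def r_series(self) -> float:
        """Series (spreading + bulk) resistance, the high-frequency limit."""
        return self.r_spread + self.r_bulk

    @property
    def purely_capacitive(self) -> bool:
        return math.isinf(self.r_ct)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Frequency-indexed complex impedance.

    Frequencies are strictly positive and ascending; values carry no
    NaN/inf after construction. ``meta`` records provenance (label,
    measurement condition, noise spec of a synthetic spectrum, ...).
    """

    freqs: np.ndarray
    z_complex: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        z = np.asarray(self.z_complex, dtype=complex)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "z_complex", z)
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValidationError("freqs", "must be a nonempty 1-D array")
        if z.shape != freqs.shape:
            raise ValidationError("z_complex", "length must match freqs")
        if not np.all(freqs > 0):
            raise ValidationError("freqs", "must be strictly positive")
        if not np.all(np.diff(freqs) > 0):
            raise ValidationError("freqs", "must be strictly ascending")
        if not (np.all(np.isfinite(freqs)) and np.all(np.isfinite(z))):
            raise ValidationError("z_complex", "NaN/inf entries are not allowed")

    def __len__(self) -> int:
        return self.freqs.size

    @property
    def magnitude(self) -> np.ndarray:
        """|Z| in ohm."""
        return np.abs(self.z_complex)

    @property
    def phase_deg(self) -> np.ndarray:
        """Phase in degrees, capacitive negative."""
        return np.degrees(np.angle(self.z_complex))

    def at(self, freq: float) -> complex:
        """Interpolated complex impedance at *freq* (log-frequency, linear Re/Im)."""
        lf = np.log10(self.freqs)
        x = math.log10(freq)
        re = np.interp(x, lf, self.z_complex.real)
        im = np.interp(x, lf, self.z_complex.imag)
        return complex(re, im)


@dataclass(frozen=True)
class PulseWaveform:
    """Current-clamped rectangular stimulation pulse train.

    Cathodic-first sign convention: ``amplitude`` is the first-phase
    current and is negative for cathodic-first stimulation. For biphasic
    pulses a charge-balanced opposite phase of equal width follows the
    interphase gap. Charge per phase is exactly ``|amplitude| * t_pw``.
    """

    amplitude: float
    t_pw: float
    interphase_gap: float = 0.0
    biphasic: bool = True
    n_pulses: int = 1
    dt: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if not (self.t_pw > 0):
            raise ValidationError("t_pw", f"must be > 0, got {self.t_pw}")
        if self.dt is None:
            object.__setattr__(self, "dt", self.t_pw / 200)
        if not (self.dt > 0):
            raise ValidationError("dt", f"must be > 0, got {self.dt}")
        if self.dt > self.t_pw / 50:
            raise ValidationError("dt", f"must be <= t_pw/50 = {self.t_pw / 50:g} for phase resolution")
        if self.interphase_gap < 0:
            raise ValidationError("interphase_gap", "must be >= 0")
        if self.n_pulses < 1:
            raise ValidationError("n_pulses", "must be >= 1")

    @property
    def charge_per_phase(self) -> float:
        """|amplitude| * t_pw, coulomb."""
        return abs(self.amplitude) * self.t_pw

    @property
    def period(self) -> float:
        """Duration of one pulse (both phases + gap for biphasic)."""
        if self.biphasic:
            return 2 * self.t_pw + self.interphase_gap
        return self.t_pw

    @property
    def duration(self) -> float:
        return self.n_pulses * self.period

    def current(self, t: np.ndarray) -> np.ndarray:
        """Injected current sampled at times *t* (half-open phases [start, end))."""
        t = np.asarray(t, dtype=float)
        tau = np.mod(t, self.period)
        i = np.zeros_like(t)
        in_train = (t >= 0) & (t < self.duration)
        phase1 = in_train & (tau < self.t_pw)
        i[phase1] = self.amplitude
        if self.biphasic:
            start2 = self.t_pw + self.interphase_gap
            phase2 = in_train & (tau >= start2) & (tau < start2 + self.t_pw)
            i[phase2] = -self.amplitude
        return i


def cpe_impedance(cpe: CPEParams, freq):
    """Complex impedance of a CPE at frequency *freq* (Hz).

    Z = 1/(Q*(j*2*pi*f)**n); |Z| = 1/(Q*(2*pi*f)**n), phase = -n*90 deg.
    """
    freq = np.asarray(freq, dtype=float)
    if not np.all(freq > 0):
        raise ValidationError("freq", "must be > 0")
    omega = 2 * np.pi * freq
    z = np.asarray(1.0 / (cpe.q_coeff * (1j * omega) ** cpe.n_exp))
    if z.ndim == 0:
        return complex(z)
    return z


def interface_impedance(circ: InterfaceCircuit, freqs) -> ImpedanceSpectrum:
    """Impedance spectrum of the full interface network over *freqs* (Hz)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.size == 0:
        raise ValidationError("freqs", "empty frequency grid")
    if not np.all(freqs > 0):
        raise ValidationError("freqs", "must be strictly positive")

    z_f = np.zeros_like(freqs, dtype=complex)  # faradaic branch r_ct + Z_CF
    z_f += 0.0 if math.isinf(circ.r_ct) else circ.r_ct
    if circ.c_f is not None:
        z_f = z_f + cpe_impedance(circ.c_f, freqs)

    if circ.c_dl is None:
        z_par = z_f
    elif circ.purely_capacitive:
        z_par = cpe_impedance(circ.c_dl, freqs)
    else:
        z_dl = cpe_impedance(circ.c_dl, freqs)
        z_par = z_dl * z_f / (z_dl + z_f)

    z = circ.r_series + z_par
    return ImpedanceSpectrum(freqs=freqs, z_complex=z, meta={"label": circ.label})


def spreading_resistance(resistivity: float, diameter: float) -> float:
    """Access (spreading) resistance of a disc contact: R = rho / (2*D).

    Current crowding at the contact perimeter makes this scale as 1/D,
    which is why the 1 kHz impedance of microcontacts is dominated by
    edge effects rather than area.
    """
    if not (resistivity > 0):
        raise ValidationError("resistivity", f"must be > 0, got {resistivity}")
    if not (diameter > 0):
        raise ValidationError("diameter", f"must be > 0, got {diameter}")
    return resistivity / (2.0 * diameter)
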