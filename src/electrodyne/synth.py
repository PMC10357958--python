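"""Synthetic benchtop data: EIS spectra, excursion sweeps, material presets.

Every generator is deterministic under its :class:`NoiseSpec` seed and,
at zero noise, inverts exactly to the corresponding forward model, so
fitters can be validated end to end against known ground truth. A single
global seed can be fanned out to independent per-generator child seeds
with :func:`child_seeds` (SeedSequence spawning).

The material presets emulate the benchtop 1 kHz impedance magnitudes of
common contact materials at 30 um diameter: titanium 1.5 Mohm, planar
platinum 400 kohm, PEDOT:PSS 30 kohm. The platinum-nanorod preset is a
plausible low-impedance coating value (25 kohm) rather than a published
figure. Calibration fixes the CPE exponent and a series resistance of
10% of the target, then solves the CPE magnitude coefficient in closed
form so that |Z(1 kHz)| matches the target exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import CPEParams, ImpedanceSpectrum, InterfaceCircuit, interface_impedance
from .errors import ValidationError
from .safety import ExcursionDataset, ExcursionModel, predict_excursion
from .units import UnitsDecl

__all__ = [
    "NoiseSpec",
    "child_seeds",
    "gen_eis",
    "gen_excursion_dataset",
    "gen_diameter_series",
    "material_presets",
]

NOISE_KINDS = ("multiplicative_complex_gaussian", "additive_gaussian", "lognormal")

# 1 kHz impedance-magnitude targets (ohm); PtNR is a synthetic stand-in value.
PRESET_TARGETS_OHM = {
    "Ti": 1.5e6,
    "Pt_planar": 400e3,
    "PEDOT_PSS": 30e3,
    "PtNR": 25e3,
}
PRESET_N_EXP = {"Ti": 0.9, "Pt_planar": 0.9, "PEDOT_PSS": 0.95, "PtNR": 0.95}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for a synthetic generator.

    ``multiplicative_complex_gaussian``: z * (1 + sigma*(eps_re + j*eps_im)),
    sigma relative. ``additive_gaussian``: absolute sigma added per
    component. ``lognormal``: magnitude scaled by exp(sigma*eps).
    """

    kind: str = "multiplicative_complex_gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValidationError("kind", f"must be one of {NOISE_KINDS}")
        if self.sigma < 0:
            raise ValidationError("sigma", "must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan a global seed out to *n* independent 31-bit child seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def gen_eis(
    circ: InterfaceCircuit,
    f_lo: float,
    f_hi: float,
    n_points: int,
    noise: NoiseSpec = NoiseSpec(),
) -> ImpedanceSpectrum:
    """Noisy impedance spectrum of *circ* on a log-spaced frequency grid."""
    if not (0 < f_lo < f_hi):
        raise ValidationError("f_lo", "need 0 < f_lo < f_hi")
    if n_points < 2:
        raise ValidationError("n_points", "need >= 2 points")
    freqs = np.logspace(math.log10(f_lo), math.log10(f_hi), n_points)
    clean = interface_impedance(circ, freqs)
    z = clean.z_complex.copy()
    if noise.sigma > 0:
        rng = noise.rng()
        if noise.kind == "multiplicative_complex_gaussian":
            z = z * (1.0 + noise.sigma * (rng.standard_normal(z.size) + 1j * rng.standard_normal(z.size)))
        elif noise.kind == "additive_gaussian":
            z = z + noise.sigma * (rng.standard_normal(z.size) + 1j * rng.standard_normal(z.size))
        else:  # lognormal magnitude scaling
            z = z * np.exp(noise.sigma * rng.standard_normal(z.size))
    meta = {"label": circ.label, "noise_kind": noise.kind, "noise_sigma": noise.sigma, "seed": noise.seed}
    return ImpedanceSpectrum(freqs=freqs, z_complex=z, meta=meta)


def gen_excursion_dataset(
    model: ExcursionModel,
    i_grid,
    t_grid,
    z_values,
    noise: NoiseSpec = NoiseSpec(kind="additive_gaussian"),
) -> ExcursionDataset:
    """Full-factorial excursion sweep from a known excursion model.

    Grids are in the model's declared units; noise (additive sigma in
    volts, by default) perturbs the excursion magnitudes, floored at 0.
    Metadata records the generating parameters.
    """
    i_grid = np.asarray(i_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    z_values = np.asarray(z_values, dtype=float)
    if i_grid.size == 0 or t_grid.size == 0 or z_values.size == 0:
        raise ValidationError("grids", "must be nonempty")
    ii, tt, zz = (a.ravel() for a in np.meshgrid(i_grid, t_grid, z_values, indexing="ij"))
    v = predict_excursion(model, ii, tt, zz)
    if noise.sigma > 0:
        rng = noise.rng()
        if noise.kind == "additive_gaussian":
            v = v + noise.sigma * rng.standard_normal(v.size)
        elif noise.kind == "multiplicative_complex_gaussian":
            v = v * (1.0 + noise.sigma * rng.standard_normal(v.size))
        else:
            v = v * np.exp(noise.sigma * rng.standard_normal(v.size))
        v = np.maximum(v, 0.0)
    meta = {
        "generating_params": model.to_dict(),
        "noise_kind": noise.kind,
        "noise_sigma": noise.sigma,
        "seed": noise.seed,
    }
    return ExcursionDataset(
        i_inj=ii, t_pw=tt, z_imag_mag=zz, v_elec=v, units_decl=model.units_decl, meta=meta
    )


def gen_diameter_series(
    alpha_coeff: float,
    d1_exp: float,
    diameters,
    noise: NoiseSpec = NoiseSpec(kind="lognormal"),
) -> list[tuple[float, float]]:
    """(diameter, |Z_imag|) pairs from a known power law alpha*D**(-d1)."""
    diameters = np.asarray(diameters, dtype=float)
    if not np.all(diameters > 0):
        raise ValidationError("diameters", "must be > 0")
    z = alpha_coeff * diameters ** (-d1_exp)
    if noise.sigma > 0:
        rng = noise.rng()
        z = z * np.exp(noise.sigma * rng.standard_normal(z.size))
    return list(zip(diameters.tolist(), z.tolist()))


def _calibrate_cpe(target_ohm: float, n_exp: float, r_series: float, freq: float = 1000.0) -> float:
    """Solve the CPE Q so |r_series + Z_CPE(freq)| equals *target_ohm*.

    With M = |Z_CPE| and theta = n*pi/2 the magnitude condition is the
    quadratic M^2 + 2*r*cos(theta)*M + r^2 - T^2 = 0; the positive root
    gives Q = 1/(M*omega^n). Deterministic, no iteration.
    """
    theta = n_exp * math.pi / 2.0
    r = r_series
    disc = r**2 * math.cos(theta) ** 2 - r**2 + target_ohm**2
    m = -r * math.cos(theta) + math.sqrt(disc)
    omega = 2 * math.pi * freq
    return 1.0 / (m * omega**n_exp)


def material_presets() -> dict[str, InterfaceCircuit]:
    """Named interface circuits calibrated to benchtop 1 kHz magnitudes.

    Each preset is purely capacitive (infinite charge-transfer
    resistance) with a fixed CPE exponent and a series resistance of 10%
    of the 1 kHz target; only the 1 kHz magnitude is anchored to
    published values (except PtNR, a synthetic stand-in).
    """
    presets = {}
    for name, target in PRESET_TARGETS_OHM.items():
        n_exp = PRESET_N_EXP[name]
        r_series = 0.1 * target
        q = _calibrate_cpe(target, n_exp, r_series)
        presets[name] = InterfaceCircuit(
            c_dl=CPEParams(q_coeff=q, n_exp=n_exp),
            r_ct=math.inf,
            c_f=None,
            r_spread=r_series,
            r_bulk=0.0,
            label=name,
        )
    return presets
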