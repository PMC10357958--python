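"""Complex nonlinear least-squares (CNLS) fitting of interface circuits.

Fits the Randles-like interface network of :mod:`electrodyne.circuit` to
an impedance spectrum by minimizing stacked (Re, Im) residuals, and fits
the power-law diameter scaling |Z_imag| = alpha * D**(-d1) that feeds
the diameter-scaled current-limit equation.

Implementation notes
--------------------
* Magnitude-like parameters (Q, R) are fitted as log10 to enforce
  positivity and equalize scales across the decades an EIS spectrum
  spans; CPE exponents are bounded to [0.3, 1.0] by default to avoid
  Warburg-like degeneracy (override via ``n_bounds``).
* Spreading and bulk resistance enter the impedance only through their
  sum and are not separately identifiable; r_bulk is held at its
  initial value and r_spread absorbs the fitted series resistance.
* A seeded 5-way multistart (log-uniform x1/3..x3 jitter of the initial
  guess) guards against local minima; ties are broken by residual, then
  iteration count, then lexicographic parameter order. Results are
  deterministic given (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np

from .circuit import CPEParams, ImpedanceSpectrum, InterfaceCircuit, interface_impedance
from .errors import ValidationError

__all__ = ["FitResult", "DiameterScaling", "fit_interface", "fit_diameter_scaling"]

WEIGHTINGS = ("modulus", "unit", "proportional")
N_MULTISTART = 5
_JITTER_LO, _JITTER_HI = 1.0 / 3.0, 3.0


@dataclass(frozen=True)
class FitResult:
    """Outcome of a CNLS interface fit."""

    circuit: InterfaceCircuit
    residual_norm: float
    params: dict = field(default_factory=dict)  # name -> {"value", "stderr"}
    converged: bool = True
    n_iter: int = 0
    weighting: str = "modulus"

    def to_dict(self) -> dict:
        return {
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "weighting": self.weighting,
            "params": self.params,
        }


@dataclass(frozen=True)
class DiameterScaling:
    """Power law |Z_imag|(D) = alpha * D**(-d1) at a reference frequency.

    ``alpha_coeff`` carries units Ohm * m**d1 when diameters are in
    meters (the convention used throughout this package).
    """

    alpha_coeff: float
    d1_exp: float
    r_squared: float
    n_points: int
    ref_freq: float = 1000.0

    def __post_init__(self):
        if not (self.alpha_coeff > 0):
            raise ValidationError("alpha_coeff", "must be > 0")
        if not math.isfinite(self.d1_exp):
            raise ValidationError("d1_exp", "must be finite")

    def z_imag_mag(self, diameter: float) -> float:
        """Predicted |Z_imag| (Ohm) at the reference frequency for *diameter* (m)."""
        if not (diameter > 0):
            raise ValidationError("diameter", "must be > 0")
        return self.alpha_coeff * diameter ** (-self.d1_exp)


def _spectrum_weights(spec: ImpedanceSpectrum, weighting: str) -> np.ndarray:
    """Per-point weights for stacked (Re, Im) residuals."""
    if weighting == "modulus":
        w = 1.0 / np.abs(spec.z_complex)
        return np.concatenate([w, w])
    if weighting == "unit":
        return np.ones(2 * len(spec))
    if weighting == "proportional":
        re = np.maximum(np.abs(spec.z_complex.real), 1e-300)
        im = np.maximum(np.abs(spec.z_complex.imag), 1e-300)
        return np.concatenate([1.0 / re, 1.0 / im])
    raise ValidationError("weighting", f"must be one of {WEIGHTINGS}, got {weighting!r}")


def _make_params(init: InterfaceCircuit, n_bounds: tuple[float, float]) -> lmfit.Parameters:
    p = lmfit.Parameters()
    n_lo, n_hi = n_bounds
    if init.c_dl is not None:
        p.add("log_q_dl", value=math.log10(init.c_dl.q_coeff), min=-12, max=0)
        p.add("n_dl", value=float(np.clip(init.c_dl.n_exp, n_lo, n_hi)), min=n_lo, max=n_hi)
    if not init.purely_capacitive and (init.c_f is not None or init.r_ct > 0):
        p.add("log_r_ct", value=math.log10(max(init.r_ct, 1e-3)), min=-3, max=12)
    if init.c_f is not None and not init.purely_capacitive:
        p.add("log_q_f", value=math.log10(init.c_f.q_coeff), min=-12, max=0)
        p.add("n_f", value=float(np.clip(init.c_f.n_exp, n_lo, n_hi)), min=n_lo, max=n_hi)
    p.add("log_r_spread", value=math.log10(max(init.r_spread, 1e-6)), min=-6, max=12)
    return p


def _circuit_from_params(p, init: InterfaceCircuit) -> InterfaceCircuit:
    vals = {k: float(p[k].value) for k in p}
    c_dl = (
        CPEParams(q_coeff=10 ** vals["log_q_dl"], n_exp=vals["n_dl"])
        if init.c_dl is not None
        else None
    )
    c_f = (
        CPEParams(q_coeff=10 ** vals["log_q_f"], n_exp=vals["n_f"])
        if ("log_q_f" in vals)
        else None
    )
    r_ct = math.inf if init.purely_capacitive else 10 ** vals.get("log_r_ct", -300)
    return InterfaceCircuit(
        c_dl=c_dl,
        r_ct=r_ct,
        c_f=c_f,
        r_spread=10 ** vals["log_r_spread"],
        r_bulk=init.r_bulk,
        label=init.label,
    )


def fit_interface(
    spec: ImpedanceSpectrum,
    init: InterfaceCircuit,
    weighting: str = "modulus",
    seed: int = 0,
    n_bounds: tuple[float, float] = (0.3, 1.0),
) -> FitResult:
    """Fit an :class:`InterfaceCircuit` to a measured/synthetic spectrum.

    Parameters
    ----------
    spec
        At least 8 frequency points spanning at least two decades.
    init
        Initial guess; also fixes which branches are present (a ``None``
        CPE or an infinite r_ct in the guess disables that branch).
    weighting
        ``modulus`` (default; residuals scaled by 1/|Z| per point),
        ``unit`` or ``proportional``.
    seed
        Seeds the multistart jitter; identical inputs and seed give
        identical results.
    """
    if len(spec) < 8:
        raise ValidationError("spec", f"need >= 8 frequency points, got {len(spec)}")
    decades = math.log10(spec.freqs[-1] / spec.freqs[0])
    if decades < 2:
        raise ValidationError("spec", f"frequency span must cover >= 2 decades, got {decades:.2f}")

    weights = _spectrum_weights(spec, weighting)
    data = np.concatenate([spec.z_complex.real, spec.z_complex.imag])

    def residual(p):
        circ = _circuit_from_params(p, init)
        z = interface_impedance(circ, spec.freqs).z_complex
        model = np.concatenate([z.real, z.imag])
        return (model - data) * weights

    base = _make_params(init, n_bounds)
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(N_MULTISTART):
        jittered = base.copy()
        for name in jittered:
            par = jittered[name]
            if name.startswith("log_"):
                shift = math.log10(_JITTER_LO) + rng.random() * math.log10(_JITTER_HI / _JITTER_LO)
                par.value = float(np.clip(par.value + shift, par.min, par.max))
            else:  # CPE exponents: uniform jitter inside bounds
                par.value = float(np.clip(par.value + rng.uniform(-0.1, 0.1), par.min, par.max))
        starts.append(jittered)

    best = None
    for start in starts:
        try:
            res = lmfit.minimize(residual, start, method="leastsq")
        except Exception:
            continue
        key = (
            float(np.sum(res.residual**2)),
            int(res.nfev),
            tuple(float(res.params[k].value) for k in sorted(res.params)),
        )
        if best is None or key < best[0]:
            best = (key, res)

    if best is None:
        init_norm = float(np.linalg.norm(residual(base)))
        return FitResult(
            circuit=init, residual_norm=init_norm, converged=False, weighting=weighting
        )

    res = best[1]
    circuit = _circuit_from_params(res.params, init)
    params = {
        k: {
            "value": float(res.params[k].value),
            "stderr": (float(res.params[k].stderr) if res.params[k].stderr is not None else None),
        }
        for k in res.params
    }
    return FitResult(
        circuit=circuit,
        residual_norm=float(np.sqrt(np.sum(res.residual**2))),
        params=params,
        converged=bool(res.success),
        n_iter=int(res.nfev),
        weighting=weighting,
    )


def fit_diameter_scaling(
    pairs: Iterable[Sequence[float]], ref_freq: float = 1000.0
) -> DiameterScaling:
    """Fit |Z_imag| = alpha * D**(-d1) from (diameter, |Z_imag|) pairs.

    Ordinary least squares on (log D, log |Z_imag|); needs >= 3 distinct
    positive diameters. *ref_freq* is recorded metadata: the frequency
    (Hz) at which the imaginary impedances were taken (1 kHz by
    convention).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("pairs", "need >= 3 (diameter, |Z_imag|) pairs")
    d, z = arr[:, 0], arr[:, 1]
    if not (np.all(d > 0) and np.all(z > 0)):
        raise ValidationError("pairs", "diameters and impedances must be > 0")
    if np.unique(d).size < 3:
        raise ValidationError("pairs", "need >= 3 distinct diameters (degenerate design)")

    x, y = np.log(d), np.log(z)
    slope, intercept = np.polyfit(x, y, 1)
    y_hat = slope * x + intercept
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DiameterScaling(
        alpha_coeff=float(np.exp(intercept)),
        d1_exp=float(-slope),
        r_squared=r2,
        n_points=arr.shape[0],
        ref_freq=ref_freq,
    )
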