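"""Electrochemical stimulation safety: excursion model and current limits.

The interface potential that builds up during a current-clamped pulse is
described by the empirical five-parameter law

    V_elec = a * ln( b * |I_inj|**k2 * t_pw**k4 * |Z_imag|**k6 + 1 ),

with a in volts and b absorbing the units of current, pulse width and
impedance (hence every model carries an explicit unit declaration).
Setting V_elec equal to the magnitude of the cathodal electrolysis limit
E_mc and solving for the current gives the injectable-current limit; and
substituting the diameter power law |Z_imag| = alpha * D**(-d1) yields
the diameter-scaled form

    |I_limit| = [ alpha**k6 * D**(-d1*k6) / (b * t_pw**k4) * (e**(|E_mc|/a) - 1) ]**(1/k2).

Shannon's charge-density criterion log10(Q/A) = k - log10(Q) is provided
for comparison: on a disc of diameter D it bounds the charge per phase at
Q = (D/2) * sqrt(pi * 10**k) (Q in uC, D in cm), i.e. I = Q / t_pw.

Charge-based screening uses the empirical thresholds of 30 uC/cm^2
(geometric charge density, macro contacts) and 4 nC per phase (micro
contacts).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable

import lmfit
import numpy as np
import pandas as pd

from .circuit import PulseWaveform
from .eisfit import DiameterScaling
from .errors import ValidationError
from .units import UnitsDecl

__all__ = [
    "ExcursionModel",
    "SafetyLimits",
    "ExcursionDataset",
    "ElectrodeGeometry",
    "ExcursionFitDiagnostics",
    "predict_excursion",
    "current_limit_from_model",
    "current_limit_vs_diameter",
    "shannon_limit",
    "fit_excursion_model",
    "compare_to_shannon",
    "check_pulse",
    "PulseSafetyReport",
]

Q_DENSITY_MACRO_UC_CM2 = 30.0  # empirical macro-contact limit, uC/cm^2
Q_PER_PHASE_MICRO_NC = 4.0  # empirical micro-contact limit, nC per phase


@dataclass(frozen=True)
class ExcursionModel:
    """Five-parameter empirical excursion-potential model.

    All parameters are strictly positive; ``units_decl`` records the
    units in which current, pulse width and impedance were expressed
    when ``b_coeff`` was determined (``b`` is meaningless without it).
    """

    a_scale: float
    b_coeff: float
    k2_exp: float
    k4_exp: float
    k6_exp: float
    units_decl: UnitsDecl = field(default_factory=UnitsDecl)

    def __post_init__(self):
        for name in ("a_scale", "b_coeff", "k2_exp", "k4_exp", "k6_exp"):
            if not (getattr(self, name) > 0):
                raise ValidationError(name, f"must be > 0, got {getattr(self, name)}")

    def to_dict(self) -> dict:
        return {
            "a_scale_v": self.a_scale,
            "b_coeff": self.b_coeff,
            "k2_exp": self.k2_exp,
            "k4_exp": self.k4_exp,
            "k6_exp": self.k6_exp,
            "units": self.units_decl.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExcursionModel":
        return cls(
            a_scale=d["a_scale_v"],
            b_coeff=d["b_coeff"],
            k2_exp=d["k2_exp"],
            k4_exp=d["k4_exp"],
            k6_exp=d["k6_exp"],
            units_decl=UnitsDecl.from_dict(d.get("units", {})),
        )


@dataclass(frozen=True)
class SafetyLimits:
    """Bundle of safety-relevant constants for an electrode family.

    ``e_mc`` is the cathodal electrolysis (water-window) limit from
    cyclic voltammetry, stored signed (negative, cathodal by
    convention); all comparisons use its magnitude. ``alpha_coeff`` /
    ``d1_exp`` come from a fitted :class:`~electrodyne.eisfit.DiameterScaling`
    and may be absent until that fit has been run.
    """

    e_mc: float = -0.6
    alpha_coeff: float | None = None
    d1_exp: float | None = None
    shannon_k: float = 1.85
    q_density_macro: float = Q_DENSITY_MACRO_UC_CM2
    q_per_phase_micro: float = Q_PER_PHASE_MICRO_NC

    def __post_init__(self):
        if self.e_mc == 0:
            raise ValidationError("e_mc", "electrolysis limit cannot be zero")
        if not (self.q_density_macro > 0):
            raise ValidationError("q_density_macro", "must be > 0")
        if not (self.q_per_phase_micro > 0):
            raise ValidationError("q_per_phase_micro", "must be > 0")

    @classmethod
    def from_scaling(cls, scaling: DiameterScaling, **kwargs) -> "SafetyLimits":
        return cls(alpha_coeff=scaling.alpha_coeff, d1_exp=scaling.d1_exp, **kwargs)

    def to_dict(self) -> dict:
        return {
            "e_mc_v": self.e_mc,
            "alpha_coeff_ohm_md1": self.alpha_coeff,
            "d1_exp": self.d1_exp,
            "shannon_k": self.shannon_k,
            "q_density_macro_uc_cm2": self.q_density_macro,
            "q_per_phase_micro_nc": self.q_per_phase_micro,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SafetyLimits":
        return cls(
            e_mc=d["e_mc_v"],
            alpha_coeff=d.get("alpha_coeff_ohm_md1"),
            d1_exp=d.get("d1_exp"),
            shannon_k=d.get("shannon_k", 1.85),
            q_density_macro=d.get("q_density_macro_uc_cm2", Q_DENSITY_MACRO_UC_CM2),
            q_per_phase_micro=d.get("q_per_phase_micro_nc", Q_PER_PHASE_MICRO_NC),
        )


@dataclass(frozen=True)
class ExcursionDataset:
    """Rows of (injected current, pulse width, |Z_imag|, measured excursion).

    Values are expressed in ``units_decl`` units; ``v_elec`` is the
    magnitude of the cathodal excursion.
    """

    i_inj: np.ndarray
    t_pw: np.ndarray
    z_imag_mag: np.ndarray
    v_elec: np.ndarray
    units_decl: UnitsDecl = field(default_factory=UnitsDecl)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arrays = {}
        for name in ("i_inj", "t_pw", "z_imag_mag", "v_elec"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = arrays["i_inj"].size
        for name, a in arrays.items():
            if a.ndim != 1 or a.size != n:
                raise ValidationError(name, "all columns must be 1-D and equal length")
        for name in ("i_inj", "t_pw", "z_imag_mag"):
            if not np.all(arrays[name] > 0):
                raise ValidationError(name, "must be strictly positive")
        if not np.all(arrays["v_elec"] >= 0):
            raise ValidationError("v_elec", "excursion magnitudes must be >= 0")

    def __len__(self) -> int:
        return self.i_inj.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i_inj": self.i_inj,
                "t_pw": self.t_pw,
                "z_imag_ohm": self.z_imag_mag,
                "v_elec": self.v_elec,
            }
        )


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Disc contact geometry for a bipolar stimulation pair."""

    diameter: float
    separation: float
    contact_class: str = "micro"  # "micro" | "macro"

    def __post_init__(self):
        if not (self.diameter > 0):
            raise ValidationError("diameter", "must be > 0")
        if self.separation < self.diameter:
            raise ValidationError("separation", "must be >= diameter for a bipolar pair")
        if self.contact_class not in ("micro", "macro"):
            raise ValidationError("contact_class", "must be 'micro' or 'macro'")

    @property
    def area_cm2(self) -> float:
        """Geometric disc area pi*D^2/4 in cm^2."""
        d_cm = self.diameter * 100.0
        return math.pi * d_cm**2 / 4.0


def predict_excursion(
    model: ExcursionModel,
    i_inj: float,
    t_pw: float,
    z_imag_mag: float,
    units: UnitsDecl | None = None,
) -> float:
    """Excursion potential V = a*ln(b*|I|^k2 * t^k4 * |Z|^k6 + 1), volts.

    Inputs are interpreted in the model's declared units; passing a
    *units* record that differs from ``model.units_decl`` raises rather
    than silently converting.
    """
    if units is not None:
        model.units_decl.require_same(units)
    i = np.abs(np.asarray(i_inj, dtype=float))
    t = np.asarray(t_pw, dtype=float)
    z = np.asarray(z_imag_mag, dtype=float)
    if not np.all(t > 0):
        raise ValidationError("t_pw", "must be > 0")
    if not np.all(z > 0):
        raise ValidationError("z_imag_mag", "must be > 0")
    arg = model.b_coeff * i**model.k2_exp * t**model.k4_exp * z**model.k6_exp
    v = model.a_scale * np.log1p(arg)
    return float(v) if v.ndim == 0 else v


def current_limit_from_model(
    model: ExcursionModel,
    e_mc: float,
    t_pw: float,
    z_imag_mag: float,
    units: UnitsDecl | None = None,
) -> float:
    """Injectable-current limit: the current whose excursion reaches |E_mc|.

    Closed-form inversion of the excursion law; returns the current in
    the model's declared current unit. Round-trips through
    :func:`predict_excursion` to ~1e-15 relative.
    """
    if units is not None:
        model.units_decl.require_same(units)
    if e_mc == 0:
        raise ValidationError("e_mc", "electrolysis limit cannot be zero")
    t = np.asarray(t_pw, dtype=float)
    z = np.asarray(z_imag_mag, dtype=float)
    if not np.all(t > 0):
        raise ValidationError("t_pw", "must be > 0")
    if not np.all(z > 0):
        raise ValidationError("z_imag_mag", "must be > 0")
    num = math.expm1(abs(e_mc) / model.a_scale)
    i = (num / (model.b_coeff * t**model.k4_exp * z**model.k6_exp)) ** (1.0 / model.k2_exp)
    return float(i) if np.ndim(i) == 0 else i


def current_limit_vs_diameter(
    limits: SafetyLimits,
    model: ExcursionModel,
    diameter: float,
    t_pw: float,
) -> float:
    """Diameter-scaled current limit using the fitted |Z_imag| power law.

    Evaluates the closed-form limit at z = alpha * D**(-d1) (converted
    from ohm into the model's impedance unit), which is algebraically
    identical to substituting the power law into the inverted excursion
    law. *diameter* in meters, *t_pw* in the model's time unit.
    """
    if limits.alpha_coeff is None or limits.d1_exp is None:
        raise ValidationError(
            "limits", "alpha_coeff/d1_exp missing; run fit_diameter_scaling first"
        )
    if not (diameter > 0):
        raise ValidationError("diameter", "must be > 0")
    z_ohm = limits.alpha_coeff * diameter ** (-limits.d1_exp)
    z_model_units = z_ohm / model.units_decl.factor("impedance")
    return current_limit_from_model(model, limits.e_mc, t_pw, z_model_units)


def shannon_limit(diameter: float, t_pw: float, shannon_k: float = 1.85) -> float:
    """Shannon charge-density current limit for a disc contact, amperes.

    From log10(Q/A) = k - log10(Q) with Q in uC and A in cm^2:
    Q^2 = A*10^k, so on a disc A = pi*D^2/4 the per-phase charge bound is
    Q = (D/2)*sqrt(pi*10^k) uC (D in cm) and I = Q/t_pw. *diameter* is in
    meters and *t_pw* in seconds; the result is converted to amperes.
    """
    if not (diameter > 0):
        raise ValidationError("diameter", "must be > 0")
    if not (t_pw > 0):
        raise ValidationError("t_pw", "must be > 0")
    d_cm = diameter * 100.0
    q_uc = (d_cm / 2.0) * math.sqrt(math.pi * 10.0**shannon_k)
    i_ua = q_uc / t_pw
    return i_ua * 1e-6


@dataclass(frozen=True)
class ExcursionFitDiagnostics:
    rmse: float
    n_points: int
    converged: bool
    n_iter: int
    params: dict = field(default_factory=dict)  # name -> {"value", "stderr"}


def fit_excursion_model(
    data: ExcursionDataset,
    init: ExcursionModel,
    seed: int = 0,
) -> tuple[ExcursionModel, ExcursionFitDiagnostics]:
    """Fit (a, b, k2, k4, k6) to measured excursions by nonlinear least squares.

    Parameters are fitted in log space to enforce positivity; a seeded
    5-way multistart (log-uniform x1/3..x3 jitter) guards against local
    minima, ties broken by residual then lexicographic parameter order.
    Requires >= 20 rows spanning at least one decade in both current and
    pulse width.
    """
    if len(data) < 20:
        raise ValidationError("data", f"need >= 20 rows, got {len(data)}")
    for name, col in (("i_inj", data.i_inj), ("t_pw", data.t_pw)):
        if np.unique(col).size < 2:
            raise ValidationError(name, "rank-deficient design: only one distinct value")
        if col.max() / col.min() < 10.0:
            raise ValidationError(name, "must span at least one decade")
    data.units_decl.require_same(init.units_decl)

    names = ("a_scale", "b_coeff", "k2_exp", "k4_exp", "k6_exp")

    def residual(p):
        model = ExcursionModel(
            *(math.exp(p[f"ln_{n}"].value) for n in names), units_decl=data.units_decl
        )
        return predict_excursion(model, data.i_inj, data.t_pw, data.z_imag_mag) - data.v_elec

    base = lmfit.Parameters()
    for n in names:
        base.add(f"ln_{n}", value=math.log(getattr(init, n)), min=-30, max=30)

    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(5):
        jittered = base.copy()
        for name in jittered:
            par = jittered[name]
            shift = rng.uniform(math.log(1.0 / 3.0), math.log(3.0))
            par.value = float(np.clip(par.value + shift, par.min, par.max))
        starts.append(jittered)

    best = None
    for start in starts:
        try:
            res = lmfit.minimize(residual, start, method="leastsq")
        except Exception:
            continue
        key = (
            float(np.sum(res.residual**2)),
            tuple(float(res.params[k].value) for k in sorted(res.params)),
        )
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise ValidationError("data", "excursion fit failed from every start")

    res = best[1]
    fitted = ExcursionModel(
        *(math.exp(res.params[f"ln_{n}"].value) for n in names), units_decl=data.units_decl
    )
    rmse = float(np.sqrt(np.mean(res.residual**2)))
    params = {}
    for n in names:
        p = res.params[f"ln_{n}"]
        value = math.exp(p.value)
        stderr = value * float(p.stderr) if p.stderr is not None else None  # delta method
        params[n] = {"value": value, "stderr": stderr}
    diag = ExcursionFitDiagnostics(
        rmse=rmse,
        n_points=len(data),
        converged=bool(res.success),
        n_iter=int(res.nfev),
        params=params,
    )
    return fitted, diag


def compare_to_shannon(
    model: ExcursionModel,
    limits: SafetyLimits,
    diameters: Iterable[float],
    t_pws: Iterable[float],
) -> pd.DataFrame:
    """Dense grid of model vs Shannon current limits.

    *diameters* in meters, *t_pws* in seconds. The model limit uses the
    fitted diameter scaling in ``limits``; ratio = model / Shannon (> 1
    where the electrochemical model permits more current than Shannon's
    damage criterion).
    """
    t_factor = UnitsDecl(time="s").factor("time") / model.units_decl.factor("time")
    i_factor = model.units_decl.factor("current")
    rows = []
    for d, t in itertools.product(diameters, t_pws):
        i_model = current_limit_vs_diameter(limits, model, d, t * t_factor) * i_factor
        i_shannon = shannon_limit(d, t, limits.shannon_k)
        rows.append(
            {
                "diameter_m": d,
                "t_pw_s": t,
                "i_limit_model_a": i_model,
                "i_limit_shannon_a": i_shannon,
                "ratio": i_model / i_shannon,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PulseSafetyReport:
    """Outcome of the charge/excursion screening of one pulse protocol."""

    charge_per_phase_c: float
    charge_density_uc_cm2: float
    contact_class: str
    charge_status: str  # "pass" | "at_limit" | "fail"
    charge_margin: float  # fraction of the applicable limit consumed
    excursion_v: float | None = None
    excursion_status: str | None = None
    notes: tuple = ()

    @property
    def passed(self) -> bool:
        ok = self.charge_status != "fail"
        if self.excursion_status is not None:
            ok = ok and self.excursion_status != "fail"
        return ok

    def to_dict(self) -> dict:
        return {
            "charge_per_phase_c": self.charge_per_phase_c,
            "charge_density_uc_cm2": self.charge_density_uc_cm2,
            "contact_class": self.contact_class,
            "charge_status": self.charge_status,
            "charge_margin": self.charge_margin,
            "excursion_v": self.excursion_v,
            "excursion_status": self.excursion_status,
            "notes": list(self.notes),
        }


def _status(consumed: float, rel_tol: float = 1e-9) -> str:
    if consumed > 1.0 + rel_tol:
        return "fail"
    if consumed >= 1.0 - rel_tol:
        return "at_limit"
    return "pass"


def check_pulse(
    geom: ElectrodeGeometry,
    wave: PulseWaveform,
    limits: SafetyLimits,
    model: ExcursionModel | None = None,
    z_imag_mag: float | None = None,
) -> PulseSafetyReport:
    """Screen a pulse protocol against charge and (optionally) excursion limits.

    Charge per phase is checked against 4 nC for micro contacts; the
    geometric charge density (disc area pi*D^2/4) against 30 uC/cm^2 for
    macro contacts. If an excursion model and an impedance magnitude (in
    the model's units) are supplied, the predicted excursion is compared
    with |E_mc| as well; otherwise the report carries a notice that only
    charge checks ran.
    """
    q_c = wave.charge_per_phase
    q_density = (q_c * 1e6) / geom.area_cm2  # uC/cm^2
    notes = []
    if geom.contact_class == "micro":
        consumed = (q_c * 1e9) / limits.q_per_phase_micro
    else:
        consumed = q_density / limits.q_density_macro
    if q_c == 0:
        consumed = 0.0

    excursion_v = None
    excursion_status = None
    if model is not None and z_imag_mag is not None:
        i_model_units = abs(wave.amplitude) / model.units_decl.factor("current")
        t_model_units = wave.t_pw / model.units_decl.factor("time")
        excursion_v = predict_excursion(model, i_model_units, t_model_units, z_imag_mag)
        excursion_status = _status(excursion_v / abs(limits.e_mc)) if excursion_v else "pass"
    else:
        notes.append("no excursion model supplied; charge-only checks performed")

    return PulseSafetyReport(
        charge_per_phase_c=q_c,
        charge_density_uc_cm2=q_density,
        contact_class=geom.contact_class,
        charge_status=_status(consumed),
        charge_margin=consumed,
        excursion_v=excursion_v,
        excursion_status=excursion_status,
        notes=tuple(notes),
    )
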