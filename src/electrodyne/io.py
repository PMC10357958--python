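"""Readers/writers for spectra, circuits, models, limits, and run configs.

Columnar files are plain CSV with '#' comment lines and a mandatory
header; two spectrum dialects are supported:

* ``complex``: columns ``freq_hz, z_real_ohm, z_imag_ohm``
* ``bode``:    columns ``freq_hz, z_mag_ohm, z_phase_deg`` (degrees,
  capacitive phase negative)

Excursion datasets carry a mandatory ``# units: uA,us,kohm,V`` comment
line because the excursion model's ``b`` coefficient is unit-convention
dependent. All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import io as _io
import json
import math
import os
import tempfile
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import CPEParams, ImpedanceSpectrum, InterfaceCircuit
from .errors import ValidationError
from .safety import ExcursionDataset, ExcursionModel, SafetyLimits
from .units import UnitsDecl

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_circuit",
    "write_circuit",
    "read_excursion_dataset",
    "write_excursion_dataset",
    "read_excursion_model",
    "write_excursion_model",
    "read_safety_limits",
    "write_safety_limits",
    "atomic_write_text",
    "RunConfig",
    "load_run_config",
]

SPECTRUM_DIALECTS = {
    "complex": ["freq_hz", "z_real_ohm", "z_imag_ohm"],
    "bode": ["freq_hz", "z_mag_ohm", "z_phase_deg"],
}


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write *text* to *path* atomically (temp file in same dir + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_table(path: str | Path, expected_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise ValidationError("header", f"{path}: missing column(s) {missing}")
    for i, row in df.iterrows():
        bad = [c for c in expected_cols if not np.isfinite(row[c])]
        if bad:
            # +2: header line plus 1-based indexing
            raise ValidationError("row", f"{path}: non-finite value in {bad} at data line {i + 2}")
    return df


def read_spectrum(path: str | Path, dialect: str = "complex") -> ImpedanceSpectrum:
    """Read an impedance spectrum file in the given dialect."""
    if dialect not in SPECTRUM_DIALECTS:
        raise ValidationError("dialect", f"must be one of {tuple(SPECTRUM_DIALECTS)}")
    df = _read_table(path, SPECTRUM_DIALECTS[dialect])
    freqs = df["freq_hz"].to_numpy(dtype=float)
    if dialect == "complex":
        z = df["z_real_ohm"].to_numpy(dtype=float) + 1j * df["z_imag_ohm"].to_numpy(dtype=float)
    else:
        phase = np.radians(df["z_phase_deg"].to_numpy(dtype=float))
        z = df["z_mag_ohm"].to_numpy(dtype=float) * np.exp(1j * phase)
    order = np.argsort(freqs)
    if not np.all(order == np.arange(freqs.size)):
        warnings.warn(f"{path}: frequencies not ascending; sorting", stacklevel=2)
        freqs, z = freqs[order], z[order]
    return ImpedanceSpectrum(freqs=freqs, z_complex=z, meta={"path": str(path), "dialect": dialect})


def write_spectrum(spec: ImpedanceSpectrum, path: str | Path, dialect: str = "complex") -> None:
    if dialect not in SPECTRUM_DIALECTS:
        raise ValidationError("dialect", f"must be one of {tuple(SPECTRUM_DIALECTS)}")
    buf = _io.StringIO()
    label = spec.meta.get("label", "")
    if label:
        buf.write(f"# label: {label}\n")
    if dialect == "complex":
        df = pd.DataFrame(
            {
                "freq_hz": spec.freqs,
                "z_real_ohm": spec.z_complex.real,
                "z_imag_ohm": spec.z_complex.imag,
            }
        )
    else:
        df = pd.DataFrame(
            {"freq_hz": spec.freqs, "z_mag_ohm": spec.magnitude, "z_phase_deg": spec.phase_deg}
        )
    df.to_csv(buf, index=False, float_format="%.17g")
    atomic_write_text(path, buf.getvalue())


def _cpe_to_dict(cpe: CPEParams | None) -> dict | None:
    if cpe is None:
        return None
    return {"q_coeff_s_sn": cpe.q_coeff, "n_exp": cpe.n_exp}


def _cpe_from_dict(d: dict | None) -> CPEParams | None:
    if d is None:
        return None
    return CPEParams(q_coeff=d["q_coeff_s_sn"], n_exp=d["n_exp"])


def write_circuit(circ: InterfaceCircuit, path: str | Path) -> None:
    obj = {
        "c_dl": _cpe_to_dict(circ.c_dl),
        "r_ct_ohm": "inf" if math.isinf(circ.r_ct) else circ.r_ct,
        "c_f": _cpe_to_dict(circ.c_f),
        "r_spread_ohm": circ.r_spread,
        "r_bulk_ohm": circ.r_bulk,
        "label": circ.label,
    }
    atomic_write_text(path, json.dumps(obj, indent=2) + "\n")


def read_circuit(path: str | Path) -> InterfaceCircuit:
    with open(path) as fh:
        obj = json.load(fh)
    r_ct = obj["r_ct_ohm"]
    return InterfaceCircuit(
        c_dl=_cpe_from_dict(obj.get("c_dl")),
        r_ct=math.inf if r_ct == "inf" else float(r_ct),
        c_f=_cpe_from_dict(obj.get("c_f")),
        r_spread=obj["r_spread_ohm"],
        r_bulk=obj["r_bulk_ohm"],
        label=obj.get("label", ""),
    )


def write_excursion_dataset(data: ExcursionDataset, path: str | Path) -> None:
    u = data.units_decl
    buf = _io.StringIO()
    buf.write(f"# units: {u.current},{u.time},{u.impedance},{u.voltage}\n")
    df = pd.DataFrame(
        {"i_inj": data.i_inj, "t_pw": data.t_pw, "z_imag_ohm": data.z_imag_mag, "v_elec": data.v_elec}
    )
    df.to_csv(buf, index=False, float_format="%.17g")
    atomic_write_text(path, buf.getvalue())


def read_excursion_dataset(path: str | Path) -> ExcursionDataset:
    units = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "units:" in line:
                parts = [p.strip() for p in line.split("units:", 1)[1].split(",")]
                if len(parts) != 4:
                    raise ValidationError("units", f"{path}: malformed units line")
                units = UnitsDecl(current=parts[0], time=parts[1], impedance=parts[2], voltage=parts[3])
                break
    if units is None:
        raise ValidationError("units", f"{path}: missing mandatory '# units: ...' line")
    df = _read_table(path, ["i_inj", "t_pw", "z_imag_ohm", "v_elec"])
    return ExcursionDataset(
        i_inj=df["i_inj"].to_numpy(),
        t_pw=df["t_pw"].to_numpy(),
        z_imag_mag=df["z_imag_ohm"].to_numpy(),
        v_elec=df["v_elec"].to_numpy(),
        units_decl=units,
        meta={"path": str(path)},
    )


def write_excursion_model(model: ExcursionModel, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(model.to_dict(), indent=2) + "\n")


def read_excursion_model(path: str | Path) -> ExcursionModel:
    with open(path) as fh:
        return ExcursionModel.from_dict(json.load(fh))


def write_safety_limits(limits: SafetyLimits, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(limits.to_dict(), indent=2) + "\n")


def read_safety_limits(path: str | Path) -> SafetyLimits:
    with open(path) as fh:
        return SafetyLimits.from_dict(json.load(fh))


@dataclass(frozen=True)
class RunConfig:
    """Validated TOML run configuration (unknown keys rejected)."""

    input: str | None = None
    output: str | None = None
    seed: int = 0
    verbosity: int = 0
    units: UnitsDecl = field(default_factory=UnitsDecl)
    tolerances: dict = field(default_factory=dict)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {"input", "output", "seed", "verbosity", "units", "tolerances"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError("config", f"unknown key(s): {sorted(unknown)}")
    units = UnitsDecl.from_dict(raw["units"]) if "units" in raw else UnitsDecl()
    return RunConfig(
        input=raw.get("input"),
        output=raw.get("output"),
        seed=raw.get("seed", 0),
        verbosity=raw.get("verbosity", 0),
        units=units,
        tolerances=raw.get("tolerances", {}),
    )
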