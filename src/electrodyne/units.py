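"""Unit conventions and suffixed-quantity parsing.

Physical quantities cross the CLI boundary as strings with explicit,
case-sensitive unit suffixes ("200us", "1.5Mohm", "20uA"); bare numbers
are rejected so that no physical input is ever ambiguous. Inside the
library everything is SI unless an object carries an explicit
:class:`UnitsDecl` (the excursion model does, because its coefficient
``b`` is unit-convention dependent).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import UnitsMismatchError, ValidationError

# suffix -> (dimension, factor to SI base unit)
_SUFFIXES: dict[str, tuple[str, float]] = {
    # length -> m
    "nm": ("length", 1e-9),
    "um": ("length", 1e-6),
    "mm": ("length", 1e-3),
    "cm": ("length", 1e-2),
    "m": ("length", 1.0),
    # time -> s
    "ns": ("time", 1e-9),
    "us": ("time", 1e-6),
    "ms": ("time", 1e-3),
    "s": ("time", 1.0),
    # resistance/impedance -> ohm
    "ohm": ("impedance", 1.0),
    "kohm": ("impedance", 1e3),
    "Mohm": ("impedance", 1e6),
    "Gohm": ("impedance", 1e9),
    # current -> A
    "nA": ("current", 1e-9),
    "uA": ("current", 1e-6),
    "mA": ("current", 1e-3),
    "A": ("current", 1.0),
    # charge -> C
    "pC": ("charge", 1e-12),
    "nC": ("charge", 1e-9),
    "uC": ("charge", 1e-6),
    "C": ("charge", 1.0),
    # voltage -> V
    "uV": ("voltage", 1e-6),
    "mV": ("voltage", 1e-3),
    "V": ("voltage", 1.0),
    # capacitance -> F
    "pF": ("capacitance", 1e-12),
    "nF": ("capacitance", 1e-9),
    "uF": ("capacitance", 1e-6),
    "F": ("capacitance", 1.0),
    # frequency -> Hz
    "Hz": ("frequency", 1.0),
    "kHz": ("frequency", 1e3),
    "MHz": ("frequency", 1e6),
}

_QUANTITY_RE = re.compile(r"^\s*([+-]?[\d.]+(?:[eE][+-]?\d+)?)\s*([a-zA-Z]+)\s*$")


def parse_quantity(text: str, dimension: str | None = None) -> float:
    """Parse ``"200us"`` → ``2e-4`` (SI).

    Parameters
    ----------
    text
        Number plus case-sensitive unit suffix. Bare numbers are rejected.
    dimension
        If given, the suffix must belong to this dimension
        (``"time"``, ``"length"``, ``"impedance"``, ...).
    """
    m = _QUANTITY_RE.match(text)
    if m is None:
        raise ValidationError("quantity", f"cannot parse {text!r}; expected e.g. '200us', '1.5Mohm'")
    value, suffix = float(m.group(1)), m.group(2)
    if suffix not in _SUFFIXES:
        raise ValidationError("quantity", f"unknown unit suffix {suffix!r} in {text!r}")
    dim, factor = _SUFFIXES[suffix]
    if dimension is not None and dim != dimension:
        raise ValidationError(
            "quantity", f"{text!r} has dimension {dim!r}, expected {dimension!r}"
        )
    return value * factor


@dataclass(frozen=True)
class UnitsDecl:
    """Unit convention under which an excursion model was fitted.

    The empirical coefficient ``b`` of the excursion-potential law absorbs
    the units of current, pulse width and impedance, so every fitted model
    must carry this record and inputs must be supplied in the same
    convention (no silent conversion).
    """

    current: str = "uA"
    time: str = "us"
    impedance: str = "kohm"
    voltage: str = "V"

    _DIMS = {"current": "current", "time": "time", "impedance": "impedance", "voltage": "voltage"}

    def __post_init__(self):
        for field_name, dim in self._DIMS.items():
            suffix = getattr(self, field_name)
            if suffix not in _SUFFIXES or _SUFFIXES[suffix][0] != dim:
                raise ValidationError(field_name, f"{suffix!r} is not a {dim} unit")

    def require_same(self, other: "UnitsDecl") -> None:
        if self != other:
            raise UnitsMismatchError(
                f"unit conventions differ: {self.as_tuple()} vs {other.as_tuple()}"
            )

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.current, self.time, self.impedance, self.voltage)

    def to_dict(self) -> dict[str, str]:
        return {
            "current": self.current,
            "time": self.time,
            "impedance": self.impedance,
            "voltage": self.voltage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnitsDecl":
        return cls(**d)

    def factor(self, field_name: str) -> float:
        """SI multiplier for this convention's unit of *field_name*."""
        return _SUFFIXES[getattr(self, field_name)][1]
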