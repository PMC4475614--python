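"""Concentration unit handling.

All doses inside one plate share a unit; cross-drug quantities (IC50
equivalents) are dimensionless ratios of same-unit concentrations, so units
are normalised to molar only when two quantities must be compared.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# canonical unit -> scale factor to molar
_UNIT_SCALE = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
}

_ALIASES = {
    "m": "M",
    "mm": "mM",
    "um": "uM",
    "µm": "uM",  # micro sign
    "μm": "uM",  # greek mu
    "nm": "nM",
}

_QUANTITY_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(\S+)\s*$")


class UnitError(ValueError):
    """Unknown or mismatched concentration unit."""


def canonical_unit(unit: str) -> str:
    """Normalise a unit spelling (``μM``, ``uM``, ``µM`` ...) to one of
    M, mM, uM, nM."""
    key = unit.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise UnitError(f"unknown concentration unit: {unit!r}")


def to_molar(value: float, unit: str) -> float:
    return value * _UNIT_SCALE[canonical_unit(unit)]


@dataclass(frozen=True)
class Quantity:
    """A concentration with its display unit."""

    value: float
    unit: str

    @property
    def molar(self) -> float:
        return to_molar(self.value, self.unit)

    def __str__(self) -> str:
        return f"{self.value:g}{self.unit}"


def parse_quantity(text: str) -> Quantity:
    """Parse strings like ``133.1uM`` or ``4.07 mM`` into a Quantity."""
    m = _QUANTITY_RE.match(text)
    if not m:
        raise UnitError(f"cannot parse concentration: {text!r}")
    value = float(m.group(1))
    return Quantity(value, canonical_unit(m.group(2)))
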