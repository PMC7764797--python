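"""Unit parsing and conversion to the package's canonical internal units.

Canonical units: concentration µM, amount µmol, time min, volume L,
rate 1/min, clearance L/min, intrinsic clearance L/min/µmol enzyme,
Vmax µmol/min/µmol enzyme (numerically 1/min), mass mg, molar mass g/mol.

Configuration files carry explicit unit strings ("3.6 nM", "40 mg",
"0.4 L/min/µmol"); bare numbers are taken to already be canonical.
"""

from __future__ import annotations

import re

__all__ = ["UnitError", "parse_quantity", "convert"]


class UnitError(ValueError):
    """Raised for unknown units or malformed quantity strings."""


def _norm(unit: str) -> str:
    # unify micro sign / greek mu to 'u' and strip whitespace
    return unit.replace("µ", "u").replace("μ", "u").replace(" ", "")


# factor tables: value_in_canonical = value * factor[unit]
_TABLES: dict[str, dict[str, float]] = {
    "concentration": {  # canonical µM
        "M": 1e6, "mM": 1e3, "uM": 1.0, "nM": 1e-3, "pM": 1e-6,
        "umol/L": 1.0, "nmol/L": 1e-3, "mmol/L": 1e3,
    },
    "amount": {  # canonical µmol
        "mol": 1e6, "mmol": 1e3, "umol": 1.0, "nmol": 1e-3, "pmol": 1e-6,
    },
    "mass": {  # canonical mg
        "kg": 1e6, "g": 1e3, "mg": 1.0, "ug": 1e-3, "ng": 1e-6,
    },
    "time": {  # canonical min
        "s": 1.0 / 60.0, "sec": 1.0 / 60.0, "min": 1.0, "h": 60.0,
        "hr": 60.0, "d": 1440.0, "day": 1440.0,
    },
    "volume": {  # canonical L
        "L": 1.0, "l": 1.0, "mL": 1e-3, "ml": 1e-3, "dL": 0.1,
    },
    "rate": {  # canonical 1/min
        "1/min": 1.0, "/min": 1.0, "min^-1": 1.0, "min-1": 1.0,
        "1/h": 1.0 / 60.0, "/h": 1.0 / 60.0, "h^-1": 1.0 / 60.0,
        "1/s": 60.0, "/s": 60.0,
    },
    "clearance": {  # canonical L/min
        "L/min": 1.0, "l/min": 1.0, "mL/min": 1e-3, "ml/min": 1e-3,
        "L/h": 1.0 / 60.0, "l/h": 1.0 / 60.0, "mL/h": 1e-3 / 60.0,
    },
    "cl_int": {  # canonical L/min/µmol enzyme
        "L/min/umol": 1.0, "l/min/umol": 1.0, "mL/min/umol": 1e-3,
        "L/h/umol": 1.0 / 60.0, "L/min/nmol": 1e3,
    },
    "vmax": {  # canonical µmol/min/µmol enzyme == 1/min
        "umol/min/umol": 1.0, "1/min": 1.0, "nmol/min/umol": 1e-3,
        "umol/h/umol": 1.0 / 60.0, "umol/min/nmol": 1e3,
    },
    "molar_mass": {  # canonical g/mol
        "g/mol": 1.0, "kg/mol": 1e3, "mg/mol": 1e-3, "Da": 1.0,
    },
    "amount_rate": {  # canonical µmol/min
        "umol/min": 1.0, "nmol/min": 1e-3, "mmol/min": 1e3,
        "umol/h": 1.0 / 60.0, "nmol/h": 1e-3 / 60.0,
    },
    "dimensionless": {"": 1.0, "1": 1.0, "-": 1.0},
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*)$")


def convert(value: float, unit: str, kind: str) -> float:
    """Convert ``value`` expressed in ``unit`` to the canonical unit of ``kind``."""
    try:
        table = _TABLES[kind]
    except KeyError:
        raise UnitError(f"unknown quantity kind {kind!r}") from None
    u = _norm(unit)
    if u not in table:
        raise UnitError(
            f"unknown {kind} unit {unit!r}; allowed: {sorted(table)}")
    return float(value) * table[u]


def parse_quantity(raw: float | int | str, kind: str) -> float:
    """Parse a number or a ``"<value> <unit>"`` string into canonical units.

    Bare numbers are assumed to already be canonical; idempotent on its
    own output (canonical values re-parse unchanged).
    """
    if isinstance(raw, bool):
        raise UnitError(f"expected a quantity, got boolean {raw!r}")
    if isinstance(raw, (int, float)):
        return float(raw)
    m = _QTY_RE.match(raw)
    if not m:
        raise UnitError(f"cannot parse quantity {raw!r}")
    value, unit = m.groups()
    try:
        v = float(value)
    except ValueError:
        raise UnitError(f"cannot parse quantity {raw!r}") from None
    if unit == "":
        return v
    return convert(v, unit, kind)
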