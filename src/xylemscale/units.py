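"""Unit conversion for the mixed unit conventions of quantitative wood anatomy.

Vessel diameters are conventionally reported in micrometres, vessel lengths
in centimetres, and pit membrane areas in square millimetres, while every
hydraulic formula here is evaluated in strict SI.  Conversions go through a
fixed registry of length and area units; units are always declared
explicitly, never inferred from magnitudes.
"""

from __future__ import annotations

# Scale factor to the SI base unit (m or m2) for every recognised unit.
_REGISTRY: dict[str, float] = {
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    "m2": 1.0,
    "mm2": 1e-6,
    "um2": 1e-12,
    "µm2": 1e-12,
}

_LENGTHS = {"m", "cm", "mm", "um", "µm", "nm"}
_AREAS = {"m2", "mm2", "um2", "µm2"}


def _dimension(unit: str) -> str:
    if unit in _LENGTHS:
        return "length"
    if unit in _AREAS:
        return "area"
    raise ValueError(f"unknown unit {unit!r}; known units: {sorted(_REGISTRY)}")


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same dimension.

    The conversion is an exact ratio of powers of ten, so round trips are
    lossless to full float precision.
    """
    if _dimension(from_unit) != _dimension(to_unit):
        raise ValueError(
            f"cannot convert {from_unit!r} (a {_dimension(from_unit)}) "
            f"to {to_unit!r} (a {_dimension(to_unit)})"
        )
    return value * (_REGISTRY[from_unit] / _REGISTRY[to_unit])


def to_si(value: float, unit: str) -> float:
    """Convert a declared-unit value to SI (m or m2)."""
    base = "m" if _dimension(unit) == "length" else "m2"
    return convert_units(value, unit, base)
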