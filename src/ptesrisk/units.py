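"""Concentration unit handling.

Two dimension classes are supported and never crossed:

* mass/mass  — tissue concentrations: ``mg/kg`` (≡ µg/g), wet-weight basis
* mass/volume — dissolved concentrations: ``µg/L`` and ``mg/L``

Conversions are exact powers of ten; composing a conversion with its
inverse is the identity.
"""

from __future__ import annotations

# factor relative to the class base unit (mg/kg and mg/L respectively)
_MASS_MASS = {"mg/kg": 1.0, "µg/g": 1.0, "ug/g": 1.0}
_MASS_VOLUME = {"mg/L": 1.0, "µg/L": 1e-3, "ug/L": 1e-3}


class UnitError(ValueError):
    """Raised for unknown units or cross-dimension conversion requests."""


def _dimension(unit: str) -> str:
    if unit in _MASS_MASS:
        return "mass/mass"
    if unit in _MASS_VOLUME:
        return "mass/volume"
    raise UnitError(
        f"unknown unit {unit!r}; supported: "
        f"{sorted(_MASS_MASS) + sorted(_MASS_VOLUME)}"
    )


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a concentration between units of the same dimension class.

    Parameters
    ----------
    value : float
        Concentration in ``from_unit``.
    from_unit, to_unit : str
        One of ``mg/kg``, ``µg/g`` (mass/mass) or ``µg/L``, ``mg/L``
        (mass/volume). ASCII spellings ``ug/g`` / ``ug/L`` are accepted.

    Raises
    ------
    UnitError
        If either unit is unknown or the dimension classes differ
        (a mass/mass value cannot be expressed per litre).
    """
    dim_from, dim_to = _dimension(from_unit), _dimension(to_unit)
    if dim_from != dim_to:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    table = _MASS_MASS if dim_from == "mass/mass" else _MASS_VOLUME
    return value * table[from_unit] / table[to_unit]


def canonical_unit(medium: str) -> str:
    """Canonical unit for a sampling medium: fish mg/kg-ww, water µg/L."""
    if medium == "fish":
        return "mg/kg"
    if medium == "water":
        return "µg/L"
    raise ValueError(f"unknown medium {medium!r}; expected 'fish' or 'water'")
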