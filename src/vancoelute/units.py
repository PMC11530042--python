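"""Unit handling.

The package works in one canonical unit system everywhere inside the solvers:

* length mm, time h, mass µg
* concentration µg/mL (= µg/cm³; 1 µg/mL = 1e-3 µg/mm³)
* mass flux µg·mm⁻²·h⁻¹
* diffusivity mm²/h

Geometry is mm-scale and the antibacterial / toxicity thresholds are printed in
µg/mL, so conversions happen only at the system boundary (config loading,
report writing). Because concentration is per mL while geometry is in mm, any
term that turns a mass flux or a cell mass into a concentration carries the
factor ``UG_PER_ML_PER_UG_PER_MM3`` below.
"""

from __future__ import annotations

from .errors import ValidationError

#: multiply µg/mm³ by this to get µg/mL
UG_PER_ML_PER_UG_PER_MM3 = 1000.0

# diffusivity units, expressed as a factor to mm²/h
_DIFFUSIVITY_TO_MM2_H = {
    "cm^2/s": 100.0 * 3600.0,
    "cm^2/h": 100.0,
    "mm^2/s": 3600.0,
    "mm^2/h": 1.0,
}

# accepted spelling variants
_ALIASES = {
    "cm2/s": "cm^2/s",
    "cm2/h": "cm^2/h",
    "mm2/s": "mm^2/s",
    "mm2/h": "mm^2/h",
    "cm²/s": "cm^2/s",
    "cm²/h": "cm^2/h",
    "mm²/s": "mm^2/s",
    "mm²/h": "mm^2/h",
}


def _canonical_unit(unit: str) -> str:
    u = _ALIASES.get(unit, unit)
    if u not in _DIFFUSIVITY_TO_MM2_H:
        raise ValidationError(
            f"unknown diffusivity unit {unit!r}; expected one of "
            f"{sorted(_DIFFUSIVITY_TO_MM2_H)}"
        )
    return u


def convert_diffusivity(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a diffusivity between cm²/s, cm²/h, mm²/s and mm²/h.

    Pure factor conversion; round-trips are exact to floating precision.
    """
    f = _canonical_unit(from_unit)
    t = _canonical_unit(to_unit)
    if f == t:
        return value
    return value * _DIFFUSIVITY_TO_MM2_H[f] / _DIFFUSIVITY_TO_MM2_H[t]


def mass_from_concentration(c_ug_ml: float, volume_mm3: float) -> float:
    """Mass (µg) held by ``volume_mm3`` at concentration ``c_ug_ml``."""
    return c_ug_ml * volume_mm3 / UG_PER_ML_PER_UG_PER_MM3


def concentration_from_mass(mass_ug: float, volume_mm3: float) -> float:
    """Concentration (µg/mL) of ``mass_ug`` spread over ``volume_mm3``."""
    return mass_ug * UG_PER_ML_PER_UG_PER_MM3 / volume_mm3
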