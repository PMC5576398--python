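"""Closed-form Hertzian contact width for a cylinder pressed on a flat.

For frictionless elastic line contact the true contact strip width is

    W_O = sqrt( (8 F D_cyl) / (pi L_cyl) * [ (1-nu_cyl^2)/E_cyl
                                            + (1-nu_flat^2)/E_flat ] )

with F the compressive force, D_cyl the cylinder diameter and L_cyl the
engaged cylinder length.  The interface works in the units the study
parameters are quoted in (N, mm, GPa); the formula is evaluated in SI
internally and the width returned in mm.

The theory assumes quasi-static normal load, smooth frictionless
nonconforming surfaces and small elastic deformation (W_O << D_cyl);
a :class:`HertzValidityWarning` is emitted when W_O exceeds 10% of the
cylinder diameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .materials import CORTICAL_BONE, STEEL, UHMWPE, Material

__all__ = [
    "ContactCase",
    "ComboSpec",
    "COMBOS",
    "HertzValidityWarning",
    "hertz_width",
    "combo_case",
]

_GPA_TO_PA = 1e9
_MM_TO_M = 1e-3


class HertzValidityWarning(UserWarning):
    """Contact width is no longer small relative to the cylinder diameter."""


@dataclass(frozen=True)
class ContactCase:
    """One cylinder-on-flat loading configuration.

    Parameters
    ----------
    F : float
        Compressive force, N (``F >= 0``).
    D_cyl : float
        Cylinder diameter, mm (``D_cyl >= 0``).
    L_cyl : float
        Engaged cylinder length, mm (``L_cyl > 0``).
    cylinder, flat : Material
        Elastic constants of the two bodies.
    """

    F: float
    D_cyl: float
    L_cyl: float
    cylinder: Material
    flat: Material

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError(f"force must be >= 0 N, got {self.F}")
        if self.D_cyl < 0:
            raise ValueError(f"cylinder diameter must be >= 0 mm, got {self.D_cyl}")
        if not self.L_cyl > 0:
            raise ValueError(f"engaged cylinder length must be > 0 mm, got {self.L_cyl}")


def hertz_width(case: ContactCase) -> float:
    """True (film-free) contact width W_O in mm for `case`.

    Returns 0 for zero force or zero diameter (a zero-diameter cylinder
    makes zero-width contact, by continuity).
    """
    if case.F == 0 or case.D_cyl == 0:
        return 0.0
    compliance_per_pa = (case.cylinder.compliance + case.flat.compliance) / _GPA_TO_PA
    geometry = (8.0 * case.F * case.D_cyl * _MM_TO_M) / (math.pi * case.L_cyl * _MM_TO_M)
    w_m = math.sqrt(geometry * compliance_per_pa)
    w_mm = w_m / _MM_TO_M
    if w_mm > 0.1 * case.D_cyl:
        warnings.warn(
            f"contact width {w_mm:.3g} mm exceeds 10% of the cylinder diameter "
            f"{case.D_cyl:.3g} mm; the small-deformation Hertz assumption is strained",
            HertzValidityWarning,
            stacklevel=2,
        )
    return w_mm


@dataclass(frozen=True)
class ComboSpec:
    """Default materials and engaged length for a named material pairing."""

    name: str
    cylinder: Material
    flat: Material
    L_cyl: float  # mm


# Steel cylinders throughout; engaged length 75 mm on the metal plate,
# 50 mm on the (narrower) polymer and bone plates.
COMBOS: dict[str, ComboSpec] = {
    "MOM": ComboSpec("MOM", STEEL, STEEL, 75.0),
    "MOP": ComboSpec("MOP", STEEL, UHMWPE, 50.0),
    "MOB": ComboSpec("MOB", STEEL, CORTICAL_BONE, 50.0),
}


def combo_case(combo: str, F: float, D_cyl: float, L_cyl: float | None = None) -> ContactCase:
    """Build a :class:`ContactCase` from a registered material pairing."""
    key = combo.upper()
    if key not in COMBOS:
        raise KeyError(f"unknown material combination {combo!r}; known: {', '.join(COMBOS)}")
    spec = COMBOS[key]
    return ContactCase(
        F=F,
        D_cyl=D_cyl,
        L_cyl=spec.L_cyl if L_cyl is None else L_cyl,
        cylinder=spec.cylinder,
        flat=spec.flat,
    )
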