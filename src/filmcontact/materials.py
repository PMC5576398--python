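"""Elastic material constants used in contact-width calculations.

The registry ships the four materials of the cylinder-on-flat study:
steel (cylinders and the metal plate), UHMWPE (the bearing polymer of
joint replacements), a glass-filled-epoxy cortical-bone analogue, and
CoCr (femoral implant alloy, modelled with steel's constants).  Users
can override or extend the registry from a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "Material",
    "STEEL",
    "UHMWPE",
    "CORTICAL_BONE",
    "COCR",
    "DEFAULT_MATERIALS",
    "load_materials",
    "get_material",
]


@dataclass(frozen=True)
class Material:
    """A linear-elastic, isotropic material.

    Parameters
    ----------
    name : str
        Registry label.
    E : float
        Elastic (Young's) modulus in GPa.
    nu : float
        Poisson's ratio (dimensionless, ``0 <= nu < 0.5``).
    """

    name: str
    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"elastic modulus must be positive, got E={self.E}")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError(f"Poisson's ratio must satisfy 0 <= nu < 0.5, got nu={self.nu}")

    @property
    def compliance(self) -> float:
        """Plane-strain compliance ``(1 - nu**2) / E`` in 1/GPa."""
        return (1.0 - self.nu**2) / self.E


STEEL = Material("steel", E=210.0, nu=0.31)
UHMWPE = Material("uhmwpe", E=0.9, nu=0.4)
CORTICAL_BONE = Material("cortical_bone", E=16.7, nu=0.3)
# CoCr femoral-implant alloy; treated with steel's elastic constants.
COCR = Material("cocr", E=210.0, nu=0.31)

DEFAULT_MATERIALS: dict[str, Material] = {
    m.name: m for m in (STEEL, UHMWPE, CORTICAL_BONE, COCR)
}


def load_materials(
    path: str | Path, base: dict[str, Material] | None = None
) -> dict[str, Material]:
    """Load a material registry from YAML, overriding/extending `base`.

    The file maps ``name -> {E: <GPa>, nu: <ratio>}``.  Entries replace
    same-named defaults; unknown names are added.
    """
    registry = dict(DEFAULT_MATERIALS if base is None else base)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"material config must be a mapping, got {type(raw).__name__}")
    for name, entry in raw.items():
        registry[str(name)] = Material(str(name), E=float(entry["E"]), nu=float(entry["nu"]))
    return registry


def get_material(name: str, registry: dict[str, Material] | None = None) -> Material:
    """Look up a material by name (case-insensitive) in `registry`."""
    registry = DEFAULT_MATERIALS if registry is None else registry
    key = name.lower()
    if key not in registry:
        raise KeyError(
            f"unknown material {name!r}; known: {', '.join(sorted(registry))}"
        )
    return registry[key]
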