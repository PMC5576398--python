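"""Thickness-error ratio W_F / W_O swept over diameter and force.

The headline statistic of the analysis: the factor by which the
film-measured contact width overestimates the true Hertzian width, as a
function of cylinder diameter and compressive force for each material
pairing.  Because both widths scale as power laws, the ratio behaves as
``D**(c - 1/2) * F**(b - 1/2)`` up to a constant — for all three fitted
models b, c < 1/2, so the ratio falls monotonically in both variables
and flattens toward a plateau at large diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .film_model import FILM_MODELS, PowerLawModel, predict_width
from .hertz import HertzValidityWarning, combo_case, hertz_width

__all__ = [
    "ErrorCurve",
    "TESTED_D_RANGE",
    "TESTED_F_RANGE",
    "error_ratio",
    "sweep_error_curves",
    "curves_to_frame",
    "default_diameter_grid",
]

#: Diameter and force ranges actually covered by the indentation tests, in mm / N.
TESTED_D_RANGE = (1.6, 76.2)
TESTED_F_RANGE = (750.0, 3000.0)


@dataclass(frozen=True)
class ErrorCurve:
    """Error ratio versus diameter at one force for one material pairing.

    ``extrapolated`` flags grid points outside the tested diameter range
    (or a force outside the tested force range); the power-law film
    model is being used beyond its calibration domain there.
    """

    combo: str
    F: float  # N
    D_grid: np.ndarray  # mm, strictly increasing, all > 0
    W_O: np.ndarray  # mm
    W_F: np.ndarray  # mm
    ratio: np.ndarray  # dimensionless
    extrapolated: np.ndarray  # bool per grid point

    def __post_init__(self) -> None:
        d = np.asarray(self.D_grid, dtype=float)
        if np.any(d <= 0):
            raise ValueError("error-ratio grid requires strictly positive diameters")
        if np.any(np.diff(d) <= 0):
            raise ValueError("diameter grid must be strictly increasing")


def _hertz_width_quiet(case) -> float:
    # Sweeps legitimately reach small diameters where the Hertz
    # small-deformation warning fires at every point; silence it here
    # and let `extrapolated` carry the caveat instead.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", HertzValidityWarning)
        return hertz_width(case)


def error_ratio(
    combo: str,
    F: float,
    D: float,
    model: PowerLawModel | None = None,
    L_cyl: float | None = None,
) -> float:
    """W_F / W_O for one (combo, force, diameter) point.

    Uses the combo's registered film model, default materials and
    engaged length (75 mm MOM; 50 mm MOP/MOB) unless overridden.
    Undefined at D = 0 where both widths vanish.
    """
    if not F > 0:
        raise ValueError(f"force must be > 0 N, got {F}")
    if D == 0:
        raise ValueError("error ratio is undefined at D = 0: both contact widths are 0")
    if D < 0:
        raise ValueError(f"diameter must be > 0 mm, got {D}")
    key = combo.upper()
    if model is None:
        model = FILM_MODELS[key]
    w_o = _hertz_width_quiet(combo_case(key, F, D, L_cyl=L_cyl))
    w_f = predict_width(model, F, D)
    return w_f / w_o


def default_diameter_grid(step: float = 0.5, d_max: float = 80.0) -> np.ndarray:
    """Diameters from `step` to `d_max` inclusive; D = 0 is excluded
    because the ratio diverges there."""
    n = int(round(d_max / step))
    return np.arange(1, n + 1) * step


def sweep_error_curves(
    combos: tuple[str, ...] = ("MOM", "MOP", "MOB"),
    forces: tuple[float, ...] = (750.0, 3000.0),
    D_grid: np.ndarray | None = None,
) -> list[ErrorCurve]:
    """One :class:`ErrorCurve` per (combo, force) over the diameter grid."""
    grid = default_diameter_grid() if D_grid is None else np.asarray(D_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("all diameters in the sweep grid must be > 0 mm")
    curves = []
    for combo in combos:
        key = combo.upper()
        model = FILM_MODELS[key]
        for F in forces:
            w_o = np.array([_hertz_width_quiet(combo_case(key, F, d)) for d in grid])
            w_f = predict_width(model, F, grid)
            out_of_range = (
                (grid < TESTED_D_RANGE[0])
                | (grid > TESTED_D_RANGE[1])
                | (F < TESTED_F_RANGE[0])
                | (F > TESTED_F_RANGE[1])
            )
            curves.append(
                ErrorCurve(
                    combo=key,
                    F=float(F),
                    D_grid=grid,
                    W_O=w_o,
                    W_F=w_f,
                    ratio=w_f / w_o,
                    extrapolated=out_of_range,
                )
            )
    return curves


def curves_to_frame(curves: list[ErrorCurve]) -> pd.DataFrame:
    """Long-format table `combo,force_N,diameter_mm,W_O_mm,W_F_mm,ratio,extrapolated`."""
    parts = [
        pd.DataFrame(
            {
                "combo": c.combo,
                "force_N": c.F,
                "diameter_mm": c.D_grid,
                "W_O_mm": c.W_O,
                "W_F_mm": c.W_F,
                "ratio": c.ratio,
                "extrapolated": c.extrapolated,
            }
        )
        for c in curves
    ]
    return pd.concat(parts, ignore_index=True)
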