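"""Film-thickness area error for one condyle of a total knee replacement.

Each femoral condyle is idealised as a CoCr cylinder of sagittal
curvature diameter D_S and width W_CONDYLE pressed on a flat UHMWPE
tibial layer.  The film overestimates contact width only in the
sagittal plane (W_FS > W_S); coronally the contact spans the full
condyle width (W_C = W_FC = W_CONDYLE).  The contact-area percentage
error is then

    error% = (W_FC * W_FS - W_C * W_S) / (W_C * W_S) * 100
           = (W_FS / W_S - 1) * 100,

with the true sagittal width W_S from Hertzian line-contact theory.
Defaults reproduce a published single-condyle measurement: 335 N at 90
degrees flexion on an Omnifit-type implant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hertz import ContactCase, hertz_width
from .materials import COCR, UHMWPE, Material

__all__ = ["CondyleCase", "condyle_area_error"]


@dataclass(frozen=True)
class CondyleCase:
    """One condyle-on-tibial-layer configuration (lengths mm, force N)."""

    F: float = 335.0
    D_S: float = 36.5  # sagittal curvature diameter
    W_CONDYLE: float = 13.61  # condyle width = engaged cylinder length
    W_FC: float = 13.61  # film-measured coronal width
    W_FS: float = 2.35  # film-measured sagittal width
    cylinder: Material = field(default=COCR)
    flat: Material = field(default=UHMWPE)

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValueError(f"force must be > 0 N, got {self.F}")
        for name in ("D_S", "W_CONDYLE", "W_FC", "W_FS"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 mm, got {getattr(self, name)}")


def condyle_area_error(case: CondyleCase, width_decimals: int | None = 2) -> dict:
    """Sagittal Hertz width and film contact-area percentage error.

    The true sagittal width is computed from the Hertz formula with the
    condyle width as engaged length, then quoted to ``width_decimals``
    decimal places (default 0.01 mm) before the areas are formed — the
    convention under which such widths are reported; pass ``None`` to
    propagate full precision.

    Returns a dict with keys ``W_S_mm`` (the quoted width used in the
    areas), ``W_S_exact_mm``, ``true_area_mm2``, ``film_area_mm2`` and
    ``error_pct``.
    """
    w_s_exact = hertz_width(
        ContactCase(
            F=case.F,
            D_cyl=case.D_S,
            L_cyl=case.W_CONDYLE,
            cylinder=case.cylinder,
            flat=case.flat,
        )
    )
    w_s = w_s_exact if width_decimals is None else round(w_s_exact, width_decimals)
    w_c = case.W_CONDYLE  # coronal width taken as error-free
    true_area = w_c * w_s
    film_area = case.W_FC * case.W_FS
    return {
        "W_S_mm": w_s,
        "W_S_exact_mm": w_s_exact,
        "true_area_mm2": true_area,
        "film_area_mm2": film_area,
        "error_pct": (film_area - true_area) / true_area * 100.0,
    }
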