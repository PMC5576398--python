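"""Empirical power-law model of the film-measured contact width.

The width registered by an interposed pressure-sensitive film follows

    W_F = a * F**b * D**c        (W_F in mm, F in N, D in mm)

The registry carries the fitted coefficients for the three material
pairings of the indentation study; :func:`fit_power_law` recovers
(a, b, c) from indentation records by ordinary least squares on
``ln W = ln a + b ln F + c ln D``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PowerLawModel",
    "IndentationRecord",
    "FitResult",
    "FILM_MODELS",
    "predict_width",
    "fit_power_law",
    "records_to_frame",
    "frame_to_records",
    "read_records_csv",
    "write_records_csv",
]

#: Column order of the indentation-record CSV interchange format.
RECORD_COLUMNS = ("combo", "force_N", "diameter_mm", "replicate", "width_mm")


@dataclass(frozen=True)
class PowerLawModel:
    """Coefficients of ``W_F = a * F**b * D**c`` (F in N, D and W_F in mm)."""

    a: float
    b: float
    c: float
    combo: str = "custom"

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"prefactor a must be positive, got {self.a}")

    def predict(self, F, D):
        """Predicted film-measured width in mm; see :func:`predict_width`."""
        return predict_width(self, F, D)


#: Fitted coefficients for the three tested material pairings.
FILM_MODELS: dict[str, PowerLawModel] = {
    "MOM": PowerLawModel(0.1778, 0.2273, 0.2936, combo="MOM"),
    "MOP": PowerLawModel(0.0449, 0.4664, 0.4201, combo="MOP"),
    "MOB": PowerLawModel(0.1647, 0.2397, 0.3394, combo="MOB"),
}


def predict_width(model: PowerLawModel, F, D):
    """Evaluate ``a * F**b * D**c`` in mm.

    Accepts scalars or numpy arrays; F in N, D in mm.  Zero force or
    diameter gives zero width (for the positive exponents of all fitted
    models).  Negative inputs are rejected.
    """
    F = np.asarray(F, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0 N")
    if np.any(D < 0):
        raise ValueError("diameter must be >= 0 mm")
    w = model.a * F**model.b * D**model.c
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class IndentationRecord:
    """One film-measured width for a (combo, force, diameter, replicate) cell."""

    combo: str
    F: float  # N
    D: float  # mm
    replicate: int
    W: float  # mm

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValueError(f"force must be > 0 N, got {self.F}")
        if not self.D > 0:
            raise ValueError(f"diameter must be > 0 mm, got {self.D}")
        if not self.W > 0:
            raise ValueError(f"width must be > 0 mm, got {self.W}")


@dataclass(frozen=True)
class FitResult:
    """A fitted power law with goodness-of-fit diagnostics.

    ``r_squared`` is computed on the original mm scale against the
    fitted power law; ``r_squared_log`` is the log-space coefficient of
    determination of the underlying linear fit.
    """

    model: PowerLawModel
    r_squared: float
    r_squared_log: float
    n: int

    def to_dict(self) -> dict:
        return {
            "combo": self.model.combo,
            "a": self.model.a,
            "b": self.model.b,
            "c": self.model.c,
            "r_squared": self.r_squared,
            "r_squared_log": self.r_squared_log,
            "n": self.n,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        # Constant data: perfect iff residuals vanish.
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def fit_power_law(records: Sequence[IndentationRecord], combo: str | None = None) -> FitResult:
    """Fit ``W = a * F**b * D**c`` to indentation records.

    Ordinary least squares on ``ln W = ln a + b ln F + c ln D``; the
    solution is exact and deterministic.  Requires at least 3 records
    spanning at least 2 distinct forces and 2 distinct diameters, else
    the corresponding exponent is unidentifiable.

    Parameters
    ----------
    records : sequence of IndentationRecord
    combo : str, optional
        Label for the fitted model; defaults to the records' common
        combo label (or "custom" if mixed).
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"need at least 3 records to fit 3 coefficients, got {len(records)}")
    F = np.array([r.F for r in records])
    D = np.array([r.D for r in records])
    W = np.array([r.W for r in records])
    if np.unique(F).size < 2:
        raise ValueError(
            "degenerate design: all records share one force level; "
            "the force exponent b is unidentifiable"
        )
    if np.unique(D).size < 2:
        raise ValueError(
            "degenerate design: all records share one diameter; "
            "the diameter exponent c is unidentifiable"
        )

    X = np.column_stack([np.ones_like(F), np.log(F), np.log(D)])
    y = np.log(W)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ln_a, b, c = beta

    if combo is None:
        labels = {r.combo for r in records}
        combo = labels.pop() if len(labels) == 1 else "custom"
    model = PowerLawModel(a=math.exp(ln_a), b=float(b), c=float(c), combo=combo)

    fitted_log = X @ beta
    return FitResult(
        model=model,
        r_squared=_r_squared(W, np.exp(fitted_log)),
        r_squared_log=_r_squared(y, fitted_log),
        n=len(records),
    )


def records_to_frame(records: Iterable[IndentationRecord]) -> pd.DataFrame:
    """Indentation records as a long-format DataFrame."""
    return pd.DataFrame(
        [(r.combo, r.F, r.D, r.replicate, r.W) for r in records],
        columns=list(RECORD_COLUMNS),
    )


def frame_to_records(frame: pd.DataFrame) -> list[IndentationRecord]:
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"record table is missing columns: {sorted(missing)}")
    return [
        IndentationRecord(
            combo=str(row.combo),
            F=float(row.force_N),
            D=float(row.diameter_mm),
            replicate=int(row.replicate),
            W=float(row.width_mm),
        )
        for row in frame.itertuples(index=False)
    ]


def read_records_csv(path: str | Path, combo: str | None = None) -> list[IndentationRecord]:
    """Read indentation records, optionally filtering to one combo."""
    frame = pd.read_csv(path)
    if combo is not None:
        frame = frame[frame["combo"] == combo]
    return frame_to_records(frame)


def write_records_csv(records: Iterable[IndentationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
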