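"""Synthetic stand-in for the physical indentation experiments.

The experimental design: five steel cylinder diameters (1.6, 12.7,
25.4, 50.8, 76.2 mm) loaded to 750 and 3000 N (1x and 4x body weight
for a 75 kg person), three replicates per cell, for each of the MOM,
MOP and MOB material pairings — 30 indentations per pairing.  Widths
are drawn from the pairing's fitted power-law model with multiplicative
Gaussian noise at the observed replicate variabilities (9.3% MOM, 3.4%
MOP, 7.9% MOB of the mean).  Each record can additionally be rendered
as a synthetic contact-patch scan so the whole measurement chain —
indent, scan, measure, fit — runs end to end without any physical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .film_model import FILM_MODELS, IndentationRecord, PowerLawModel, predict_width
from .hertz import COMBOS
from .patch_imaging import PatchImage, PatchRenderSpec, render_patch

__all__ = [
    "ExperimentDesign",
    "SimulatedPatch",
    "DEFAULT_CVS",
    "PROTOCOL_METADATA",
    "default_design",
    "simulate_indentation_dataset",
    "simulate_patch_set",
]

#: Replicate variability (relative SD of width) per material pairing.
DEFAULT_CVS: dict[str, float] = {"MOM": 0.093, "MOP": 0.034, "MOB": 0.079}

#: Loading protocol of the indentation tests, carried as metadata only —
#: the width model absorbs any relaxation effect, which was minimal.
PROTOCOL_METADATA: dict[str, float] = {
    "preload_N": 100.0,
    "ramp_rate_N_per_s": 50.0,
    "hold_s": 60.0,
    "film_square_mm": 25.0,
    "film_pressure_threshold_MPa": 0.19,
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Full-factorial indentation design with per-combo noise levels."""

    combos: tuple[str, ...] = ("MOM", "MOP", "MOB")
    diameters: tuple[float, ...] = (1.6, 12.7, 25.4, 50.8, 76.2)  # mm
    forces: tuple[float, ...] = (750.0, 3000.0)  # N
    replicates: int = 3
    cv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CVS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        for combo in self.combos:
            c = self.cv.get(combo, 0.0)
            if not 0.0 <= c < 1.0:
                raise ValueError(f"cv for {combo} must be in [0, 1), got {c}")

    @property
    def n_records(self) -> int:
        return len(self.combos) * len(self.forces) * len(self.diameters) * self.replicates


def default_design(combo: str | None = None, **overrides) -> ExperimentDesign:
    """The standard design, optionally restricted to one material pairing."""
    if combo is not None:
        overrides.setdefault("combos", (combo.upper(),))
    return ExperimentDesign(**overrides)


def simulate_indentation_dataset(
    design: ExperimentDesign,
    models: Mapping[str, PowerLawModel] | None = None,
) -> list[IndentationRecord]:
    """Draw one width per design cell and replicate.

    ``W = predict(model, F, D) * (1 + eps)`` with
    ``eps ~ Normal(0, cv_combo)``, clipped to stay positive (at the
    study noise levels a non-positive draw is essentially impossible).
    Deterministic given ``design.seed``; records are emitted in
    (combo, force, diameter, replicate) loop order.
    """
    models = FILM_MODELS if models is None else models
    for combo in design.combos:
        if combo not in models:
            raise KeyError(f"no power-law model supplied for combo {combo!r}")
    rng = np.random.default_rng(design.seed)
    records: list[IndentationRecord] = []
    for combo in design.combos:
        model = models[combo]
        cv = design.cv.get(combo, 0.0)
        for F in design.forces:
            for D in design.diameters:
                mean_w = predict_width(model, F, D)
                noise = rng.normal(0.0, cv, size=design.replicates) if cv > 0 else np.zeros(design.replicates)
                for rep, eps in enumerate(noise, start=1):
                    w = mean_w * (1.0 + eps)
                    records.append(
                        IndentationRecord(
                            combo=combo,
                            F=float(F),
                            D=float(D),
                            replicate=rep,
                            W=float(max(w, mean_w * 1e-6)),
                        )
                    )
    return records


@dataclass(frozen=True)
class SimulatedPatch:
    """A rendered patch paired with its generating record.

    ``clipped`` marks widths beyond the 25 mm film square, where a real
    patch would run off the film edge.
    """

    record: IndentationRecord
    image: PatchImage
    clipped: bool


def simulate_patch_set(
    records: Sequence[IndentationRecord],
    dpi: float = 1200.0,
    edge_roughness_sd: float = 0.05,
    speck_rate: float = 0.02,
    dropout_rate: float = 0.02,
    patch_length: float = 25.0,
    seed: int = 0,
) -> list[SimulatedPatch]:
    """Render one synthetic scan per record at the record's width.

    Patch length defaults to the 25 mm film square, capped at the
    combo's engaged cylinder length.  Byte-identical output for equal
    seeds; per-record render seeds are derived from `seed`.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31, size=len(records))
    film_square = PROTOCOL_METADATA["film_square_mm"]
    out: list[SimulatedPatch] = []
    for record, sub_seed in zip(records, sub_seeds):
        length = patch_length
        if record.combo in COMBOS:
            length = min(length, COMBOS[record.combo].L_cyl)
        clipped = record.W > film_square
        width = min(record.W, film_square)
        if clipped:
            warnings.warn(
                f"record width {record.W:.2f} mm exceeds the {film_square:.0f} mm "
                "film square; rendered patch is clipped",
                stacklevel=2,
            )
        spec = PatchRenderSpec(
            true_width=width,
            patch_length=length,
            edge_roughness_sd=edge_roughness_sd,
            speck_rate=speck_rate,
            dropout_rate=dropout_rate,
            seed=int(sub_seed),
            raster_width=film_square,
        )
        out.append(SimulatedPatch(record=record, image=render_patch(spec, dpi=dpi), clipped=clipped))
    return out
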