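"""Synthetic film contact-patch rasters and width measurement.

Real stained patches are scanned at a known dpi and the strip width is
read off in pixels at 7 stations spaced 3 mm along the cylinder axis,
then averaged and converted to mm.  This module renders synthetic
stand-ins for such scans — a stained band of known true width with
rough edges, interior dropout and stray exterior specks — and measures
width from any such raster with the same multi-station procedure.

Pixel convention: ``pixels`` holds stain intensity in [0, 1] with 0 =
unstained background; rows (axis 0) run along the cylinder length.
Files are written with the stain dark on a white background, like an
actual scan, and inverted back on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PatchImage",
    "PatchRenderSpec",
    "render_patch",
    "measure_patch_width",
]

_INCH_MM = 25.4


@dataclass(frozen=True)
class PatchImage:
    """A grayscale contact-patch raster with its scan resolution.

    ``length_axis`` names the raster axis that runs along the cylinder
    length (0 = rows, the rendering convention).
    """

    pixels: np.ndarray
    dpi: float
    length_axis: int = 0

    def __post_init__(self) -> None:
        if not self.dpi > 0:
            raise ValueError(f"dpi must be positive, got {self.dpi}")
        if self.pixels.ndim != 2:
            raise ValueError("patch raster must be 2-D grayscale")
        if self.length_axis not in (0, 1):
            raise ValueError("length_axis must be 0 or 1")

    @property
    def mm_per_pixel(self) -> float:
        return _INCH_MM / self.dpi

    def oriented(self) -> np.ndarray:
        """Pixels with the length axis first (rows along the cylinder)."""
        return self.pixels if self.length_axis == 0 else self.pixels.T

    def save(self, path: str | Path) -> None:
        """Write as 8-bit PNG/BMP (stain dark on white) with embedded dpi."""
        arr = np.clip(self.oriented(), 0.0, 1.0)
        img = Image.fromarray(np.round(255 * (1.0 - arr)).astype(np.uint8), mode="L")
        img.save(path, dpi=(self.dpi, self.dpi))

    @classmethod
    def load(cls, path: str | Path, dpi: float | None = None) -> "PatchImage":
        """Read a grayscale scan; dpi from file metadata unless given."""
        with Image.open(path) as img:
            if dpi is None:
                info_dpi = img.info.get("dpi")
                if not info_dpi or not info_dpi[0]:
                    raise ValueError(f"{path}: no dpi in file metadata; pass dpi explicitly")
                dpi = float(info_dpi[0])
            arr = np.asarray(img.convert("L"), dtype=float) / 255.0
        return cls(pixels=1.0 - arr, dpi=dpi, length_axis=0)


@dataclass(frozen=True)
class PatchRenderSpec:
    """Geometry and imperfection parameters for a synthetic patch.

    Parameters
    ----------
    true_width : float
        Nominal stained-band width, mm (> 0).
    patch_length : float
        Raster extent along the cylinder axis, mm.  Defaults to the
        25 mm film square.
    edge_roughness_sd : float
        Per-row Gaussian jitter of each band edge, mm.
    speck_rate : float
        Expected stray (noncontiguous) specks per mm² outside the band.
    dropout_rate : float
        Fraction of interior band pixels left unstained.
    seed : int
        RNG seed; rendering is deterministic given the seed.
    raster_width : float
        Raster extent transverse to the cylinder axis, mm (the film
        square width).
    """

    true_width: float
    patch_length: float = 25.0
    edge_roughness_sd: float = 0.0
    speck_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    raster_width: float = 25.0

    def __post_init__(self) -> None:
        if not self.true_width > 0:
            raise ValueError(f"true_width must be > 0 mm, got {self.true_width}")
        if not self.patch_length > 0:
            raise ValueError(f"patch_length must be > 0 mm, got {self.patch_length}")
        for name in ("edge_roughness_sd", "speck_rate", "dropout_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")


def render_patch(spec: PatchRenderSpec, dpi: float = 1200.0) -> PatchImage:
    """Render a synthetic stained patch.

    The band is centred transversely; a pixel column is stained on a row
    when its centre falls inside the (per-row jittered) band interval,
    so a noiseless band of width equal to an integer number of pixels is
    rendered at exactly that pixel count.
    """
    if spec.true_width > spec.raster_width:
        raise ValueError(
            f"true_width {spec.true_width} mm exceeds the raster width "
            f"{spec.raster_width} mm"
        )
    mmpp = _INCH_MM / dpi
    n_rows = int(round(spec.patch_length / mmpp))
    n_cols = int(round(spec.raster_width / mmpp))
    rng = np.random.default_rng(spec.seed)

    centre = n_cols * mmpp / 2.0
    left = centre - spec.true_width / 2.0
    right = centre + spec.true_width / 2.0
    if spec.edge_roughness_sd > 0:
        lefts = left + rng.normal(0.0, spec.edge_roughness_sd, size=n_rows)
        rights = right + rng.normal(0.0, spec.edge_roughness_sd, size=n_rows)
    else:
        lefts = np.full(n_rows, left)
        rights = np.full(n_rows, right)

    col_centres = (np.arange(n_cols) + 0.5) * mmpp
    band = (col_centres[None, :] >= lefts[:, None]) & (col_centres[None, :] < rights[:, None])
    pixels = band.astype(float)

    if spec.dropout_rate > 0:
        drop = rng.random((n_rows, n_cols)) < spec.dropout_rate
        pixels[band & drop] = 0.0

    if spec.speck_rate > 0:
        area_mm2 = spec.patch_length * spec.raster_width
        n_specks = rng.poisson(spec.speck_rate * area_mm2)
        outside = (col_centres < left) | (col_centres >= right)
        outside_cols = np.flatnonzero(outside)
        if outside_cols.size and n_specks:
            rows = rng.integers(0, n_rows, size=n_specks)
            cols = rng.choice(outside_cols, size=n_specks)
            pixels[rows, cols] = rng.uniform(0.6, 1.0, size=n_specks)

    return PatchImage(pixels=pixels, dpi=dpi, length_axis=0)


def measure_patch_width(
    image: PatchImage,
    n_stations: int = 7,
    spacing_mm: float = 3.0,
    threshold: float = 0.5,
    window_halfwidth_mm: float | None = None,
    window_center_mm: float | None = None,
) -> float:
    """Average contact width in mm measured at `n_stations` profile lines.

    Stations are centred on the patch mid-length and spaced
    ``spacing_mm`` apart along the cylinder axis.  At each station the
    width is the outer extent — last minus first above-threshold pixel
    plus one — of the transverse profile, optionally restricted to a
    search window about ``window_center_mm`` (default: the raster
    centre) so that distant stray specks cannot inflate the reading.
    Station widths in pixels are averaged, then converted to mm.
    Returns 0 when no pixel exceeds the threshold at any station.
    """
    if n_stations < 1:
        raise ValueError(f"need at least one station, got {n_stations}")
    px = image.oriented()
    n_rows, n_cols = px.shape
    mmpp = image.mm_per_pixel

    span_mm = (n_stations - 1) * spacing_mm
    if n_rows * mmpp < span_mm:
        raise ValueError(
            f"patch length {n_rows * mmpp:.2f} mm is shorter than the "
            f"{n_stations}-station span of {span_mm:.2f} mm"
        )

    mid = (n_rows - 1) / 2.0
    spacing_px = spacing_mm / mmpp
    offsets = (np.arange(n_stations) - (n_stations - 1) / 2.0) * spacing_px
    rows = np.round(mid + offsets).astype(int)
    if rows.min() < 0 or rows.max() >= n_rows:
        raise ValueError("stations fall outside the raster")

    lo, hi = 0, n_cols
    if window_halfwidth_mm is not None:
        centre = n_cols * mmpp / 2.0 if window_center_mm is None else window_center_mm
        lo = max(0, int(np.floor((centre - window_halfwidth_mm) / mmpp)))
        hi = min(n_cols, int(np.ceil((centre + window_halfwidth_mm) / mmpp)))

    widths_px = np.empty(n_stations)
    for i, r in enumerate(rows):
        hits = np.flatnonzero(px[r, lo:hi] >= threshold)
        widths_px[i] = 0.0 if hits.size == 0 else hits[-1] - hits[0] + 1
    return float(widths_px.mean() * mmpp)
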