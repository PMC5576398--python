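"""Synthetic contact-patch rendering and multi-station width measurement."""

import numpy as np
import pytest

from filmcontact import (
    PatchImage,
    PatchRenderSpec,
    measure_patch_width,
    render_patch,
)

MMPP_1200 = 25.4 / 1200.0


def test_noiseless_band_is_exact_pixel_rectangle():
    # 2.54 mm = 0.1 inch = exactly 120 px at 1200 dpi
    img = render_patch(PatchRenderSpec(true_width=2.54), dpi=1200)
    per_row = img.pixels.sum(axis=1)
    assert np.all(per_row == 120)
    cols = img.pixels.sum(axis=0)
    assert set(np.unique(cols)) <= {0.0, float(img.pixels.shape[0])}  # sharp edges


def test_rendering_is_deterministic_given_seed():
    spec = PatchRenderSpec(
        true_width=2.5, edge_roughness_sd=0.05, speck_rate=0.05, dropout_rate=0.05, seed=42
    )
    a = render_patch(spec, dpi=600)
    b = render_patch(spec, dpi=600)
    assert np.array_equal(a.pixels, b.pixels)
    c = render_patch(
        PatchRenderSpec(
            true_width=2.5, edge_roughness_sd=0.05, speck_rate=0.05,
            dropout_rate=0.05, seed=43,
        ),
        dpi=600,
    )
    assert not np.array_equal(a.pixels, c.pixels)


def test_noiseless_round_trip_is_exact():
    img = render_patch(PatchRenderSpec(true_width=2.54), dpi=1200)
    assert measure_patch_width(img) == pytest.approx(2.54, abs=1e-12)


def test_all_background_measures_zero():
    img = PatchImage(pixels=np.zeros((1200, 1200)), dpi=1200)
    assert measure_patch_width(img) == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_noisy_patch_recovered_within_calibrated_tolerance(seed):
    """Rough edges + interior dropout: recovery within 1 px + 5%."""
    width = 2.5
    spec = PatchRenderSpec(
        true_width=width, edge_roughness_sd=0.05, dropout_rate=0.10, seed=seed
    )
    measured = measure_patch_width(render_patch(spec, dpi=1200))
    assert abs(measured - width) <= MMPP_1200 + 0.05 * width


def test_distant_specks_ignored_inside_search_window():
    width = 2.54
    clean = render_patch(PatchRenderSpec(true_width=width), dpi=1200)
    dirty = PatchImage(pixels=clean.pixels.copy(), dpi=1200)
    n_cols = dirty.pixels.shape[1]
    centre_mm = n_cols * dirty.mm_per_pixel / 2.0
    # plant specks on every row, > 2x the band width from the band axis
    far_col = int((centre_mm + 2.5 * width) / dirty.mm_per_pixel)
    dirty.pixels[:, far_col] = 1.0
    windowed = measure_patch_width(dirty, window_halfwidth_mm=2 * width)
    assert windowed == measure_patch_width(clean, window_halfwidth_mm=2 * width)
    assert windowed == pytest.approx(width, abs=1e-12)
    # without the window the outer-extent rule is corrupted
    assert measure_patch_width(dirty) > width + 1.0


def test_measured_width_monotone_in_true_width():
    widths = [1.0, 2.0, 3.5, 5.0]
    measured = [
        measure_patch_width(render_patch(PatchRenderSpec(true_width=w), dpi=600))
        for w in widths
    ]
    assert all(b > a for a, b in zip(measured, measured[1:]))


def test_band_wider_than_raster_rejected():
    with pytest.raises(ValueError, match="raster"):
        render_patch(PatchRenderSpec(true_width=30.0, raster_width=25.0))


def test_raster_shorter_than_station_span_rejected():
    # 7 stations x 3 mm need 18 mm; give a 10 mm patch
    img = render_patch(PatchRenderSpec(true_width=2.0, patch_length=10.0), dpi=600)
    with pytest.raises(ValueError, match="station"):
        measure_patch_width(img)
    # fewer stations fit fine
    assert measure_patch_width(img, n_stations=3) == pytest.approx(2.0, abs=25.4 / 600)


def test_render_spec_validation():
    with pytest.raises(ValueError):
        PatchRenderSpec(true_width=0.0)
    with pytest.raises(ValueError):
        PatchRenderSpec(true_width=1.0, dropout_rate=1.5)
    with pytest.raises(ValueError):
        PatchRenderSpec(true_width=1.0, edge_roughness_sd=-0.1)
    with pytest.raises(ValueError):
        PatchImage(pixels=np.zeros((10, 10)), dpi=0.0)


def test_png_round_trip_preserves_raster_and_dpi(tmp_path):
    spec = PatchRenderSpec(
        true_width=2.5, edge_roughness_sd=0.05, speck_rate=0.02, dropout_rate=0.02, seed=5
    )
    img = render_patch(spec, dpi=600)
    path = tmp_path / "patch.png"
    img.save(path)
    back = PatchImage.load(path)
    assert back.dpi == pytest.approx(600, rel=0.01)  # PNG stores dots-per-metre
    # binary-at-threshold content survives the 8-bit round trip
    assert np.array_equal(back.pixels >= 0.5, img.pixels >= 0.5)
    exact = PatchImage.load(path, dpi=600)
    assert measure_patch_width(exact) == measure_patch_width(img)


def test_bmp_round_trip_with_explicit_dpi(tmp_path):
    img = render_patch(PatchRenderSpec(true_width=2.54), dpi=1200)
    path = tmp_path / "patch.bmp"
    img.save(path)
    back = PatchImage.load(path, dpi=1200)
    assert measure_patch_width(back) == pytest.approx(2.54, abs=1e-12)
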