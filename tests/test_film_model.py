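"""Power-law film-width model: prediction, fitting, round trips, IO."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filmcontact import (
    FILM_MODELS,
    IndentationRecord,
    PowerLawModel,
    default_design,
    fit_power_law,
    predict_width,
    read_records_csv,
    simulate_indentation_dataset,
    write_records_csv,
)

GRID_F = (750.0, 3000.0)
GRID_D = (1.6, 12.7, 25.4, 50.8, 76.2)


def grid_records(model, replicates=3):
    """Noise-free records from `model` on the experimental grid."""
    return [
        IndentationRecord(model.combo, F, D, rep, predict_width(model, F, D))
        for F in GRID_F
        for D in GRID_D
        for rep in range(1, replicates + 1)
    ]


@pytest.mark.parametrize(
    "combo, F, D, expected",
    [
        # hand evaluations in log space of the fitted equations
        ("MOM", 750.0, 50.8, 2.5367),
        ("MOP", 3000.0, 76.2, 11.603),
        ("MOB", 750.0, 50.8, 3.0539),
    ],
)
def test_predictions_match_log_space_hand_evaluation(combo, F, D, expected):
    assert predict_width(FILM_MODELS[combo], F, D) == pytest.approx(expected, rel=1e-3)


def test_zero_force_or_diameter_predicts_zero():
    for model in FILM_MODELS.values():
        assert predict_width(model, 0.0, 50.8) == 0.0
        assert predict_width(model, 750.0, 0.0) == 0.0


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        predict_width(FILM_MODELS["MOM"], -1.0, 10.0)
    with pytest.raises(ValueError):
        predict_width(FILM_MODELS["MOM"], 10.0, -1.0)
    with pytest.raises(ValueError):
        PowerLawModel(a=-0.1, b=0.2, c=0.3)


def test_prediction_vectorizes_and_increases_in_force_and_diameter():
    model = FILM_MODELS["MOB"]
    D = np.linspace(1.0, 80.0, 40)
    w = predict_width(model, 750.0, D)
    assert w.shape == D.shape
    assert np.all(np.diff(w) > 0)
    assert np.all(predict_width(model, 3000.0, D) > w)


@pytest.mark.parametrize("combo", ["MOM", "MOP", "MOB"])
def test_round_trip_recovers_registered_coefficients(combo):
    """Noise-free data from each fitted model returns its own coefficients."""
    gen = FILM_MODELS[combo]
    result = fit_power_law(grid_records(gen))
    assert result.model.a == pytest.approx(gen.a, rel=1e-8)
    assert result.model.b == pytest.approx(gen.b, rel=1e-8)
    assert result.model.c == pytest.approx(gen.c, rel=1e-8)
    assert result.r_squared == pytest.approx(1.0, abs=1e-10)
    assert result.model.combo == combo
    assert result.n == 30


def test_constant_widths_fit_to_flat_model():
    records = [
        IndentationRecord("flat", F, D, rep, 1.0)
        for F in GRID_F
        for D in GRID_D
        for rep in (1, 2, 3)
    ]
    result = fit_power_law(records)
    assert result.model.a == pytest.approx(1.0, abs=1e-10)
    assert result.model.b == pytest.approx(0.0, abs=1e-10)
    assert result.model.c == pytest.approx(0.0, abs=1e-10)
    assert result.r_squared == 1.0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(k=st.floats(min_value=0.01, max_value=100.0))
def test_rescaling_widths_rescales_only_the_prefactor(k):
    gen = FILM_MODELS["MOB"]
    scaled = [
        IndentationRecord(r.combo, r.F, r.D, r.replicate, r.W * k)
        for r in grid_records(gen)
    ]
    model = fit_power_law(scaled).model
    assert model.a == pytest.approx(gen.a * k, rel=1e-8)
    assert model.b == pytest.approx(gen.b, rel=1e-8)
    assert model.c == pytest.approx(gen.c, rel=1e-8)


def test_degenerate_designs_raise_naming_the_exponent():
    gen = FILM_MODELS["MOM"]
    one_force = [r for r in grid_records(gen) if r.F == 750.0]
    with pytest.raises(ValueError, match="force exponent b"):
        fit_power_law(one_force)
    one_diameter = [r for r in grid_records(gen) if r.D == 50.8]
    with pytest.raises(ValueError, match="diameter exponent c"):
        fit_power_law(one_diameter)
    with pytest.raises(ValueError, match="at least 3"):
        fit_power_law(one_force[:2])


def test_fit_quality_under_replicate_noise_fixed_seed():
    """3.4% multiplicative noise on the polymer design still fits R^2 > 0.99."""
    records = simulate_indentation_dataset(default_design("MOP", seed=0))
    result = fit_power_law(records)
    assert result.r_squared > 0.99
    assert result.r_squared <= 1.0
    assert result.r_squared_log > result.r_squared - 0.02  # both diagnostics exposed


def test_record_validation():
    with pytest.raises(ValueError):
        IndentationRecord("MOM", 0.0, 10.0, 1, 1.0)
    with pytest.raises(ValueError):
        IndentationRecord("MOM", 10.0, 10.0, 1, -1.0)


def test_csv_round_trip_and_combo_filter(tmp_path):
    records = grid_records(FILM_MODELS["MOM"], replicates=1) + grid_records(
        FILM_MODELS["MOP"], replicates=1
    )
    path = tmp_path / "records.csv"
    write_records_csv(records, path)
    header = path.read_text().splitlines()[0]
    assert header == "combo,force_N,diameter_mm,replicate,width_mm"
    back = read_records_csv(path)
    assert len(back) == len(records)
    for got, want in zip(back, records):
        assert (got.combo, got.F, got.D, got.replicate) == (
            want.combo, want.F, want.D, want.replicate,
        )
        assert got.W == pytest.approx(want.W, rel=1e-12)
    only_mop = read_records_csv(path, combo="MOP")
    assert {r.combo for r in only_mop} == {"MOP"}
    assert len(only_mop) == 10


def test_fit_result_json(tmp_path):
    result = fit_power_law(grid_records(FILM_MODELS["MOB"]))
    out = tmp_path / "fit.json"
    result.to_json(out)
    payload = json.loads(out.read_text())
    assert payload["combo"] == "MOB"
    assert payload["a"] == pytest.approx(0.1647, rel=1e-8)
    assert payload["n"] == 30
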