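#!/usr/bin/env python
"""Fit the film-width power laws W_F = a F^b D^c to the simulated records.

Reads results/indentation_records.csv (run 01 first), fits each
material pairing in log space, and compares the recovered coefficients
with the generating ones.  Writes results/film_model_fits.json.
"""

import argparse
import json
from pathlib import Path

from filmcontact import FILM_MODELS, fit_power_law, read_records_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--records", type=Path, default=RESULTS / "indentation_records.csv"
    )
    args = parser.parse_args()

    fits = {}
    print(f"{'combo':<6}{'a':>10}{'b':>10}{'c':>10}{'R^2':>10}")
    for combo, gen in FILM_MODELS.items():
        result = fit_power_law(read_records_csv(args.records, combo=combo))
        fits[combo] = result.to_dict() | {
            "generating": {"a": gen.a, "b": gen.b, "c": gen.c}
        }
        m = result.model
        print(f"{combo:<6}{m.a:>10.4f}{m.b:>10.4f}{m.c:>10.4f}{result.r_squared:>10.4f}")
        print(f"{'  true':<6}{gen.a:>10.4f}{gen.b:>10.4f}{gen.c:>10.4f}")

    out = RESULTS / "film_model_fits.json"
    out.write_text(json.dumps(fits, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
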