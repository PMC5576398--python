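#!/usr/bin/env python
"""Sweep the thickness-error ratio W_F/W_O over diameter and force.

The headline analysis: how strongly the film overestimates the true
Hertzian contact width across the 0-80 mm diameter range at 750 and
3000 N for all three material pairings.  Writes the long-format table
to results/error_ratio_sweep.csv (optionally a figure with --plot).
"""

import argparse
from pathlib import Path

from filmcontact import curves_to_frame, error_ratio, sweep_error_curves

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--plot", action="store_true", help="also write a PNG figure")
    args = parser.parse_args()

    curves = sweep_error_curves()
    frame = curves_to_frame(curves)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "error_ratio_sweep.csv"
    frame.to_csv(out, index=False)
    print(f"wrote {len(frame)} sweep points -> {out}")

    tested = frame[~frame.extrapolated]
    print("error ratio over the tested domain (1.6-76.2 mm, 750/3000 N):")
    for (combo, F), grp in tested.groupby(["combo", "force_N"]):
        print(
            f"  {combo} @ {F:5.0f} N: ratio {grp.ratio.min():5.2f}-{grp.ratio.max():6.2f}"
            f"  (always > 1: film overestimates everywhere)"
        )
    order = {combo: error_ratio(combo, 750.0, 50.8) for combo in ("MOM", "MOB", "MOP")}
    print(
        f"ordering at 750 N, 50.8 mm: MOM {order['MOM']:.1f} > "
        f"MOB {order['MOB']:.1f} > MOP {order['MOP']:.1f}"
    )

    if args.plot:
        from filmcontact.cli import _plot_curves

        fig_path = RESULTS / "error_ratio_sweep.png"
        _plot_curves(curves, fig_path)
        print(f"wrote {fig_path}")


if __name__ == "__main__":
    main()
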