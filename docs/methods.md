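# Methods

`filmcontact` quantifies the measurement artefact that the ~0.2 mm physical
thickness of pressure-sensitive film (Fujifilm Prescale type) introduces when
it is used to measure contact widths between articulating bodies.  The study
system is cylinder-on-flat line contact — a steel cylinder pressed on a metal
(MOM), UHMWPE polymer (MOP) or cortical-bone-analogue (MOB) flat — plus one
congruent-looking clinical case, a knee-implant condyle on its polyethylene
tibial layer.

## True contact width: Hertzian line contact

Without film, the contact strip width of a frictionless elastic cylinder on a
flat is

    W_O = sqrt( (8 F D_cyl) / (pi L_cyl) * [ (1-nu_cyl^2)/E_cyl + (1-nu_flat^2)/E_flat ] )

with compressive force F, cylinder diameter D_cyl and engaged cylinder length
L_cyl.  Assumptions: quasi-static normal load, smooth frictionless
nonconforming surfaces, small linear-elastic deformation (`W_O << D_cyl`).

Interface units are the ones the study parameters are quoted in — N, mm, GPa —
and conversion to SI happens inside `hertz_width`, so the printed material
constants can be used verbatim.  The registry holds steel (E = 210 GPa,
nu = 0.31), UHMWPE (0.9, 0.4), artificial cortical bone (16.7, 0.3) and CoCr
(treated with steel's constants, as is conventional for contact estimates of
CoCr implant components).  Per-pairing engaged lengths reflect the plate
geometry of the indentation set-up: 75 mm for MOM, 50 mm for MOP and MOB.

Choices:

- `W_O = 0` at `F = 0` or `D_cyl = 0` by continuity rather than an error —
  a zero-diameter cylinder makes zero-width contact.
- Hertz validity is not enforced as a hard error.  When `W_O > 0.1 D_cyl` a
  `HertzValidityWarning` is emitted; small diameters at high force genuinely
  strain the small-deformation assumption, but the analysis still needs values
  there (the error-ratio sweep runs down to sub-millimetre diameters).  The
  sweep silences the warning internally and instead tags out-of-domain grid
  points in its output.

## Film-measured width: the empirical power law

The width the film registers follows `W_F = a F^b D^c` (F in N, D and W_F in
mm).  The registry carries the fitted coefficients for the three pairings:

| pairing | a      | b      | c      |
|---------|--------|--------|--------|
| MOM     | 0.1778 | 0.2273 | 0.2936 |
| MOP     | 0.0449 | 0.4664 | 0.4201 |
| MOB     | 0.1647 | 0.2397 | 0.3394 |

`fit_power_law` estimates (a, b, c) by ordinary least squares on
`ln W = ln a + b ln F + c ln D` — unique, deterministic, and exact on
noise-free power-law data (round trip to ~1e-12 relative).  Fitting in log
space was a design choice: the source analysis reports only "power law
lines-of-best-fit" without naming an algorithm, and log-space OLS is the
standard, reproducible reading.  Likewise the unit convention (N, mm, mm) is
an inference — it is the only convention consistent with the experimental
ranges — not a documented fact.  Goodness of fit is reported as R² on the
original mm scale against the fitted power law; the log-scale R² is exposed
alongside as a diagnostic.  Replicates enter as individual records rather than
cell means; for balanced designs the point estimate is identical and the
residual variance stays interpretable.

Degenerate designs fail loudly: all records at one force make the force
exponent unidentifiable (similarly for diameter), and the error message names
the offending exponent.

## Error ratio

The headline statistic is `W_F / W_O`.  Because both widths are power laws,

    ratio  ∝  F^(b - 1/2) * D^(c - 1/2)

and all three fitted pairings have b, c < 1/2, so the ratio decreases
monotonically in both force and diameter and flattens asymptotically at large
diameters.  On the tested domain (750–3000 N, 1.6–76.2 mm) the ratio stays
well above 1 — the film always overestimates — and is ordered
MOM > MOB > MOP at every point: the stiffer the flat substrate, the smaller
the true contact and hence the larger the relative thickness artefact.

The default sweep grid is 0.5 mm steps over (0, 80]; D = 0 is excluded because
the ratio diverges as D → 0 (W_F ∝ D^c with c < 1/2 shrinks more slowly than
W_O ∝ D^1/2).  Points outside the tested diameter/force ranges are permitted
but flagged `extrapolated` in the output, since the film model is being used
beyond its calibration domain there.

## Synthetic experiments

There is no deposited raw data, so the generator stands in for the physical
campaign and its defaults *are* the study conditions: five cylinder diameters
(1.6, 12.7, 25.4, 50.8, 76.2 mm), two forces (750 and 3000 N — 1x and 4x body
weight for a 75 kg person), three replicates, i.e. 30 indentations per
pairing (matching the 30 single-use polymer and bone plates).  Replicate
scatter is multiplicative Gaussian on the width, `W = W_F(F,D) (1 + eps)`,
`eps ~ N(0, cv)`, with the observed per-pairing variabilities cv = 9.3% (MOM),
3.4% (MOP), 7.9% (MOB).  Multiplicative Gaussian was chosen over lognormal for
transparency; at cv ≤ 9.3% the two are practically indistinguishable.  Draws
are clipped to stay positive (a non-positive draw at these cv's is an
~11-sigma event; the clip exists only to keep the record type's `W > 0`
invariant unconditional).  The loading protocol (100 N preload, 50 N/s ramp,
60 s hold, 0.19 MPa film sensing threshold) is carried as metadata only — no
viscoelastic or film-mechanics model sits behind the generator, which is why
passing tests certify the statistical pipeline, not film chemistry.

The constant-per-pairing cv is itself an assumption: the reported
variabilities are averages across conditions, and the per-condition structure
is unknown.

A note on parameter recovery: with only 30 records on a 2x5 grid, the
prefactor `a` is an extrapolation to F = 1 N, D = 1 mm and carries roughly
2 sigma-log of leverage-amplified uncertainty (se(ln a) ≈ 2 cv), so per-seed
recovery of `a` to within 10% is *not* a property this design can guarantee —
error propagation puts it near 40% failure at the MOM noise level.  The tested
recovery properties are therefore the ones the design does support: grid
predictions of the fitted model within a few percent of the generating model,
exponents within tight absolute bands, and original-scale R² > 0.99 for MOP
(which holds at the default seed and in ≥95% of seeds; measured 98.5% over
200).

## Patch imaging

Real patches are scanned at 1200 dpi and the strip width read off in pixels
at 7 stations spaced 3 mm along the cylinder axis, then averaged and converted
to mm (`mm_per_pixel = 25.4 / dpi`).  The renderer emulates such scans
geometrically: a stained band of nominal width centred in a 25 mm film
square, with

- per-row Gaussian jitter of each edge (`edge_roughness_sd`, default 0.05 mm
  in the pipeline — rough edges),
- interior dropout (unstained pixels inside the band, default 2%),
- stray exterior specks (Poisson, default 0.02 per mm² — noncontiguous
  patches).

These imperfection parameters are invented plumbing chosen to look like
typical scans; the renderer does not model the film's 0.19 MPa pressure
threshold or stain chemistry.  A pixel column is stained when its centre falls
in the half-open band interval, which makes a noiseless band whose width is an
integer number of pixels render at exactly that count (2.54 mm = 120 px at
1200 dpi); a float tie at the interval boundary can shift a general-width band
by one pixel, which is why the round-trip guarantee is "within 1 px".

Measurement at a station takes the outer extent (first-to-last
above-threshold pixel) of the transverse profile, optionally inside a search
window about the band axis.  The binarisation threshold defaults to 0.5 of
full stain; the original procedure's rule is undocumented, so both the
threshold and the outer-extent-in-window rule are package decisions.  The
window matters: a single speck on a station row, however far away, inflates an
unwindowed outer extent.  With a window the measurement is provably invariant
to specks beyond the window; without one, speck corruption is a real (and
realistic) failure mode — calibration over 100 seeds at the default speck rate
put ~7% of unwindowed measurements outside a 5% tolerance, driven entirely by
speck-on-station-row events.  Pipeline code therefore passes a window of twice
the nominal width (capped at the film half-width).  Station placement is
centred on the patch mid-length; stations that do not fit the raster raise.

Noisy-recovery tolerances were frozen from pre-test seed sweeps: rough edges
(0.05 mm) plus ≤10% dropout recover a 2.5 mm band within 1 px + 5% in 100/100
seeds; the full simulate→render→measure→fit chain at 600 dpi recovers MOP grid
predictions within 10% and exponents within 0.03 with R² > 0.98 (10/10 seeds,
margins ~2x).

The end-to-end and pipeline defaults use 600 dpi rather than the nominal
1200 dpi; resolution only enters through the 1-px term of the tolerance, and
the quarter-size rasters keep the full chain fast.

## Knee-implant case study

One CoCr femoral condyle at 90° flexion under 335 N is modelled as a cylinder
(sagittal curvature diameter 36.5 mm, condyle width 13.61 mm) on a flat UHMWPE
layer.  Coronally the film is taken as error-free (`W_C = W_FC = W_CONDYLE`),
so the area error reduces to the sagittal overestimate alone:

    error% = (W_FC·W_FS − W_C·W_S) / (W_C·W_S) × 100 = (W_FS / W_S − 1) × 100

with the measured `W_FS = 2.35 mm` against the Hertzian `W_S`.  The computed
width is `W_S = 1.4646 mm`; `condyle_area_error` quotes it to 0.01 mm
(`width_decimals=2`, configurable, `None` disables) before forming the areas.
That convention matters for the headline number: with the quoted 1.46 mm the
error is 61%; with full precision it is 60.4%.  Widths in this field are
reported to hundredths of a millimetre and downstream arithmetic is done on
the quoted value, so the quoted-width convention is the default; both the
exact width and the full-precision variant remain available.

## Problem sizes and limitations

Everything here is desk-scale: fits are 30-point linear solves, sweeps are a
few hundred closed-form evaluations, and rendered rasters are ≤1181² pixels.
The test suite runs the 200-seed R² property and a 2-seed end-to-end imaging
chain in a few seconds total.

Known limitations: line contact only (no point/ellipse contact, no
ball-in-socket congruence, where the squeeze-film artefact would likely be
worse); no finite-element cross-validation; no film chemistry, shear
sensitivity or pressure-threshold modelling; the synthetic generator inherits
the fitted power laws, so it can validate the pipeline's statistics but cannot
re-derive the coefficients from physics.
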