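# kambin

3D safe-zone morphometry of the lumbar transforaminal working corridor
(L4–L5).  Given per-case anatomical landmarks, the package measures:

- **d** — diameter of the circle inscribed in the right working triangle
  (exiting root = hypotenuse, traversing root = height, upper pedicle
  edge = base), via `base + height − hypotenuse`, with its center **O**;
- **β** — trephine abduction angle between the transverse-plane
  projections of line OD (O to the disc center) and the midline DE
  (disc center to spinous-process center);
- **J** — the wire anchor point where the β-abducted trajectory meets
  the facet plane, with its quadrant label (A = upper-outer, B =
  upper-inner, C = lower-outer, D = lower-inner) from the four-line
  facet segmentation;
- **L1 / L2** — signed clearances from the trephine surface (default
  8 mm diameter) to the exiting and traversing nerve roots; ≥ 0 means
  a sufficient safety margin.

It also ships a synthetic-anatomy generator (including a calibrated
40-case fixture whose forward measurements reproduce the published
cohort's five-number summaries and β mean/SD) and the accompanying
statistics battery (normality-gated summaries, one-sample tests against
trephine diameters, Pearson correlations, quadrant chi-square, and
side/sex/age subgroup comparisons).

## CLI

```sh
# generate the calibrated 40-case cohort (one JSON per case + cohort.csv)
kambin generate --mode paper_fixture --n 40 --seed 1 --out cohort/

# measure every case -> fixed-column CSV
kambin measure --cases cohort/ --out measurements.csv

# statistics battery -> JSON report
kambin stats --measurements measurements.csv --out report.json

# L1/L2 versus abduction angle for one case
kambin sweep --case cohort/P01-R.json --beta 0:60:1 --out sweep.csv
```

`generate --mode parametric` samples unconstrained cohorts from
configurable distributions instead.  All randomness flows from `--seed`;
re-running any command with the same inputs gives identical outputs.

Measurement CSV columns (stable contract):
`case_id, side, sex, age, bmi, d_mm, beta_deg, J_x_mm, J_y_mm, J_z_mm,
quadrant, L1_mm, L2_mm, safe_L1, safe_L2`.

Case files store coordinates in mm in anatomical coordinates; left-sided
cases are mirrored across the midsagittal plane into the canonical
measurement frame (x lateral toward the measured side, y posterior,
z superior) on ingest.

## Conventions worth knowing

- β is a projected (transverse-plane) line angle in degrees; lengths
  are mm everywhere.
- The trephine is modelled as an infinite cylinder through the wire
  anchor (O shifted by the case's stored `wire_offset`, default zero),
  parallel to the disc plane; nerve roots are zero-radius segments, so
  clearances are upper bounds on real-tissue clearance.
- L2 uses the shortest-distance rule, like L1.
- Empirical quartiles use linear interpolation of order statistics
  (numpy's default, "type 7").
- Quadrant border ties go to the upper/outer side; the distance to the
  nearest border is reported so near-boundary cases can be flagged.
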