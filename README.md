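# conedose

Dose calculation and radiochromic-film validation for stereotactic
circular-cone (SRS cone) radiotherapy beams — including flattening
filter-free (FFF) beams, where published small-field data are scarce and
interinstitution variability is notoriously large.

Small circular collimators (4–15 mm diameter here) defeat most dosimetry
instrumentation: detectors are comparable in size to the field, charged
particle equilibrium breaks down, and a 1 mm distance-to-agreement spans a
quarter of the smallest field. `conedose` implements the two halves of a
commissioning-and-validation workflow for a cone planning system:

1. **A TMR-based cone dose engine** built entirely from measured beam data —
   cone output factors, percent depth-dose curves and off-axis ratios — for
   single static beams and discretised arcs, with radiological-depth
   heterogeneity handling.
2. **A film validation pipeline** — per-channel quartic calibration of
   EBT3-style film scans, pixelwise response-to-dose inversion, centroid (or
   fiducial) registration of measured to calculated dose planes, and the
   comparison metrics appropriate for stereotactic fields: profile FWHMs and
   the mean absolute dose over the ≥80%-of-maximum core.

A synthetic-data generator produces every input with known ground truth
(FFF-like commissioning curves, calibration exposures, noisy film scans), so
the whole chain can be exercised as a parameter-recovery experiment.

## The dose model

Dose to a point `p` from a cone beam is a product of five measured factors:

```
D(p) = MU · C_ref · St(cone) · TMR(d_rad(p), cone) · OAR(r(p), cone, SPD) · (SAD/SPD)²
```

* `C_ref` — machine calibration output for the 10×10 cm reference field at
  10 cm depth, 100 cm SSD (Gy/MU);
* `St` — cone output factor, the ratio of the cone reading (at the cone's
  dmax, source–point distance 1000 mm) to that same 10×10 reference reading,
  so `C_ref·St` is the cone dose per MU under reference conditions;
* `TMR` — tissue-maximum ratio at radiological depth `d_rad`, derived from
  the measured PDD via `TMR(d) = PDD(d)/100 · ((SSD+d)/(SSD+dmax))²`;
* `OAR` — off-axis ratio at radius `r` in the plane ⊥ the central axis,
  divergence-scaled back to the measurement plane (925 mm SSD + 75 mm depth);
* `(SAD/SPD)²` — inverse square, referenced to the 1000 mm SAD.

Secondary scatter is assumed negligible at these field sizes and is not
modelled; heterogeneities act only through the radiological depth.
Arcs are sums of equal-MU static segments at segment mid-angles (1°/segment
by default). Machine coordinates are IEC-like: isocenter at the origin,
z up, gantry 0 pointing down, the source at `SAD·(sin g, 0, cos g)`.

## Worked example

`examples/` contains one narrative script per capability. For instance,
`python examples/02_point_dose_and_mu.py` prescribes 7 Gy to the isocenter
at 100 mm depth in a slab phantom with the 7.5 mm cone and prints:

```
monitor units for 7 Gy at the isocenter: 2181.5 MU
central-axis dose at 5 cm depth: 10.27 Gy
central-axis dose at 10 cm depth: 7.00 Gy
central-axis dose at 15 cm depth: 4.77 Gy
```

— over 2000 MU for 7 Gy, the familiar price of a 0.830 output factor and
TMR fall-off at depth, and the expected monotone dose decrease across the
three film planes. `python examples/04_film_comparison.py` pushes a
simulated film (150 counts noise, 0.4 mm setup error) through calibration,
conversion and registration:

```
recovered centroid shift (red): (+0.39, -0.19) mm (applied (0.4, -0.2))
FWHM plan 5.76 mm | red 5.76 mm
mask mean: plan 6.54 Gy, red 6.54 Gy, green 6.53 Gy
dose agreement: red -0.1%, green -0.1%, red/green average -0.1%
```

`examples/05_full_validation_study.py` runs the full 96-film study and
prints a per-energy summary table (plan dose, red/green film dose, plan and
measured FWHM per cone).

A thin CLI wraps the same stages:

```sh
conedose simulate --scenario slab --seed 1 --out study/
conedose report --input study/ --out study/results/
```

## Layout

| path | contents |
| --- | --- |
| `src/conedose/commissioning.py` | beam-data model, FWHM, PDD→TMR, bundle I/O |
| `src/conedose/engine.py` | phantoms, plans, point/plane/arc dose, MU solving |
| `src/conedose/film.py` | film scans, calibration fits, dose conversion |
| `src/conedose/compare.py` | resampling, registration, FWHM/mask metrics |
| `src/conedose/synthetic.py` | beam/film/scenario generators with ground truth |
| `src/conedose/reference_data.py` | measured reference tables (fixtures/defaults) |
| `src/conedose/reporting.py`, `cli.py` | pipeline orchestration, tables, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
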