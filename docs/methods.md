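# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `conedose`, in the spirit of a planning-system white paper:
enough detail that every number the package produces can be traced to a
stated assumption.

## 1. Cone dose engine

### Model

Dose to a point is the five-factor product given in the README. The engine
is a table-driven broad-beam model: all physics lives in the measured (or
generated) commissioning tables, and the engine only interpolates,
divergence-scales and applies inverse square. Assumptions:

* **No explicit secondary-scatter model.** For 4–15 mm apertures the
  phantom-scatter variation between cones is small compared with the
  measurement uncertainties; the depth variation of scatter is carried
  implicitly by each cone's own measured PDD. Consequently no
  phantom-scatter-ratio correction enters the PDD→TMR conversion.
* **Heterogeneities in depth only.** The radiological depth is the
  density-weighted path length from the phantom surface to the point along
  the straight source ray — exact per-slab segment sums for slab stacks,
  chord geometry for the cylinder. Lateral density structure is ignored.
* **St convention.** Output factors are stored as the ratio of the cone
  reading (cone dmax, SPD = 1000 mm) to the 10×10 reading at 10 cm depth /
  100 cm SSD — i.e. referenced directly to the machine-output measurement
  with no daisy chaining. With that convention `C_ref·St` *is* the cone
  dose per MU at dmax and SPD 1000, and the engine's inverse-square factor
  is referenced to SAD. This is a documented package convention for
  self-consistency, not a claim about any vendor's internal definition.

### PDD → TMR

`TMR(d) = PDD(d)/100 · ((SSD+d)/(SSD+dmax))²`, renormalised to exactly 1 at
dmax. One subtlety: for any smooth PDD measured at fixed SSD this conversion
places the true TMR peak ~1 mm *deeper* than the PDD peak (the divergence
factor grows at ≈0.2 %/mm), so the converted table rises by ≲0.2 % just past
dmax before falling. Table validation therefore admits a 0.5 % plateau
tolerance beyond dmax; the tables remain non-increasing at every coarser
scale.

### Geometry and arcs

IEC-like machine coordinates (z up, isocenter origin, source at
`SAD·(sin g, 0, cos g)`, SAD = 1000 mm). Dose planes are horizontal pixel
grids (film planes in both validation geometries are horizontal); the
default export spacing is 0.772 mm, mimicking a CT-voxel-sized dose export.
Arcs are discretised at 1°/segment with MU split equally; a 10° arc then
consists of 10 near-identical segments and converges visibly under step
halving. Arc direction (CW/CCW) cannot affect the summed dose and is kept
only as metadata. The spherical QA phantom that holds the arc film is
approximated as a water-equivalent cylinder (radius 38 mm) whose axis lies
along the gantry rotation axis: the arc spans only ±5° about vertical, so
every ray sees nearly the same chord, and the couch is excluded.

### Interpolation and range policy

All table lookups (TMR vs depth, OAR vs radius) are linear, and **nothing is
extrapolated**: depth queries outside the commissioned range raise a range
error rather than invent beam data. The single exception is the OAR tail —
a query whose divergence-scaled radius lies beyond the table returns 0
(off-beam) with a logged warning, because plane corners legitimately fall
outside ±30 mm.

## 2. Film dosimetry chain

"Response" is the raw mean channel value in scanner counts (16 bits per
channel), not net optical density. Per channel, a degree-4 polynomial
*response(dose)* is least-squares fitted to ≥6 distinct dose levels that
must include an unirradiated film; replicate exposures at a dose level are
averaged (and the averaging logged). A fit that is not strictly monotone
over the dose domain (checked on 1000 evenly spaced points) is rejected,
because it has no single-valued inverse.

Conversion inverts the fitted polynomial: a bracketed root find (tolerance
10⁻⁶ Gy) for scalars, and for whole scans a dense 8193-point monotone lookup
refined by two Newton steps — agreeing with the scalar path to well below
the 10⁻⁴ Gy requirement. Responses outside the attainable range clamp to the
nearest domain edge with the clamped-pixel fraction reported as a QC output:
with realistic noise, roughly a third of *background* pixels clamp at 0 Gy
(noise pushing them brighter than the unirradiated level), which is routine
and harmless because all metrics live in the high-dose core. No smoothing is
ever applied; the output grid is the film pixel grid (25.4/dpi = 0.1693 mm
at 150 dpi). Development-time and lot fields are metadata only — no
darkening-kinetics model.

## 3. Registration and comparison

* The calculated plane is bilinearly upsampled to the film pixel pitch
  first, so the sharper measured penumbra is interpolated only once.
* Registration is translation-only, matching dose-area centroids (pixels
  ≥50 % of max; the threshold is configurable — 50 % is robust to tail noise
  and symmetric for cone fields). This implicitly assumes rotational
  symmetry; a least-squares rigid (Kabsch) fiducial registration is
  available where corner marks exist.
* FWHM is measured on the row/column profiles through the common centre:
  half-maximum crossings located by linear interpolation between bracketing
  samples, taking the outermost crossing on each flank (robust to FFF flat
  tops). Arc films are profiled only perpendicular to gantry travel.
* Absolute dose agreement is the mean over the pixels of the *calculated*
  plane holding ≥80 % of its maximum ("≥" rather than ">" — the boundary
  pixel set is measure-zero) compared with the mean of the same pixels on
  the registered film dose; reported as `100·(meas − calc)/calc`, per
  channel and as the red/green average. Gamma analysis is deliberately
  absent: at stereotactic field sizes any nonzero distance-to-agreement is
  too loose and 0 mm is too tight.
* Reported values are rounded to 0.1 % and 0.1 mm (the conventional printed
  precision); full precision is kept internally.

## 4. Synthetic data generator

The generator emulates the statistical structure the analysis needs, with
the simplest families that have the right qualitative features; parameters
are configurable precisely so it claims to model no particular linac.

* **Off-axis ratios**: flat-top error-function pairs
  `OAR(r) ∝ erf((w/2−r)/σ√2) + erf((w/2+r)/σ√2)` with penumbra
  σ = 0.7 mm (a realistic diode-measured cone penumbra). At these field
  sizes a flattening filter leaves no visible signature, so FFF and
  flattened beams share the family. `w` is calibrated numerically (Brent)
  so the continuous profile's FWHM equals the nominal width — the sampled
  tables reproduce the requested FWHMs to <0.002 mm.
* **PDD**: two-exponential build-up/attenuation
  `exp(−μd) − exp(−βd)`, normalised to 100 at dmax; β is solved from the
  requested dmax. Defaults: μ = 0.0075 mm⁻¹ (6xFFF), 0.0065 (10xFFF),
  0.0072 (6x) — chosen to give clinically plausible small-field depth doses
  (PDD(10 cm) ≈ 50–55 %).
* **Reference operating point**: output factors, off-axis FWHMs,
  calibration outputs (0.631/0.708/0.663 cGy/MU) and dmax values default to
  the measured reference dataset in `reference_data.py`. Per-cone dmax is
  only quoted there as endpoints (e.g. 8→12 mm across the 6xFFF cone set);
  intermediate cones are interpolated linearly in diameter — an assumption,
  recorded as such.
* **Film response**: fixed monotone quartics per channel (red steeper below
  ~2 Gy, green steeper above ~8 Gy, mirroring the sensitivity/dynamic-range
  trade-off), additive Gaussian counts noise per channel
  (default σ = 150 counts ⇒ ~1.5 % single-pixel dose noise at 7 Gy, the
  scale of observed film-to-plan scatter), a rigid film translation drawn
  per film (default σ = 0.3 mm per axis, a realistic setup error), and
  quantisation to 16 bits. The blue channel is filled with a constant: the
  48-bit format is honoured but blue is not used dosimetrically.
* **Scenario**: 2 energies × 6 cones × 3 depths × 2 replicate films
  (72 static scans; 7 Gy to the isocenter at 100 mm depth in a four-slab
  polystyrene stack) plus a 175°→185° CCW arc (~7.5 Gy) per energy/cone.
  All randomness flows from one seed; identical seeds give bit-identical
  data.

**What the recovery experiment shows — and what it does not.** Films are
simulated *from the exported plan planes* (bilinearly sampled at film
pitch). The noiseless study is therefore an exact inverse up to 16-bit
quantisation, and recovery error measures only what the film chain adds:
calibration fitting, inversion, quantisation, setup translation and
registration. That is the point of the design — it isolates the pipeline —
but it also means passing tests say nothing about detector physics the
generator does not contain: diode over-response at small fields, film energy
dependence, lateral scanner artefacts, or a planning system's source model.
Those are exactly the effects a real validation would probe; here they would
enter as systematic offsets the pipeline faithfully reports.

## 5. Problem sizes and determinism

Plan planes are 0.772 mm grids over ±16 mm (±12 mm for the sensitivity
check); films are 150 dpi over the plane minus a 2 mm margin; the recovery
study uses the full 72-film static design plus arcs, and the noisy rate is
accumulated over two seeds. The summary CSV is byte-identical across runs
with the same configuration and seed.

## 6. Known limitations

* No diode small-field correction factors, by design: the data model stores
  raw commissioning measurements.
* Only horizontal, axis-aligned dose planes; no 3-D grids, couch or
  collimator rotations, MLC/IMRT delivery, or CT-number calibration curves.
* RTDOSE import is restricted to single-frame axis-aligned planes.
* The slab radiological depth assumes the beam enters the top surface
  (adequate for the gantry-0 validation geometry); the cylinder is infinite
  along its axis.
* The printed reference validation tables carry one-decimal doses; summary
  statistics recomputed from them inherit that rounding (the worst static
  row evaluates to −3.9 % from printed values, where the unrounded data
  evidently gave −3.6 %).
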