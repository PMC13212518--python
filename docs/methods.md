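# Methods

This note documents the models, the synthetic-cohort design, the numerical
choices, and the limits of what the validation experiments demonstrate.

## Scale calibration

A top-view camera at fixed height images a ruler of known length at canopy
level; the ruler length over its pixel span gives `pixel_to_length`
(cm/px) per camera height, and areas convert with its square. The
pinhole relation between the two working heights (coefficients scaling as
the ratio of object distances, 2.2/1.5) is retained as a consistency check
between the two calibrations, but conversion always uses the empirically
calibrated coefficient — a linear object-distance factor applied directly
to a pixel *area* would be dimensionally inconsistent. Records without an
explicit camera height use the acquisition-day rule (≤ day 70 → 1.5 m,
afterwards 2.2 m); a record whose height has no calibration raises rather
than silently falling back, because a wrong coefficient corrupts every
downstream area quadratically.

Canopy width and curd diameter are reported as the mean of the two
converted bounding-box sides. The long side, short side and both raw
sides are exposed alongside; the mean was chosen because it is
rotation-robust for near-circular canopies and curds. Bounding boxes are
0-based, half-open `(x, y, w, h)`. Disjoint components of one class in a
mask are merged into a single instance — the acquisition design has one
plant per image, so fragments are segmentation artifacts, not plants.

## Growth models

All zoo members are functions of days after transplanting (day 1 = first
day after transplant). The sigmoids:

- logistic `a / (1 + b e^(−kt))`
- Gompertz `a exp(−b e^(−kt))`
- generalized Richards `a [1 + (d−1) e^(−k(t−tc))]^(1/(1−d))`, `d > 1`,
  which passes through the logistic at `d = 2` and tends to Gompertz as
  `d → 1`. The shape bound is `d ∈ (1.001, 10]` to avoid the Gompertz
  singularity; `tc` is the day of peak growth rate.

The curd model is a rising sine half-period `y0 + A sin(π(t−tc)/w)`,
monotone on `[tc − w/2, tc + w/2]` with peak *rate* `Aπ/w` at `tc`.
Closed-form first, second and third time derivatives are part of every
model spec and are self-tested against high-order finite differences.

**Fitting.** Bounded trust-region least squares with multi-start
initialization (default 8 starts: data-driven heuristics plus seeded 20%
jitter). Heuristics: asymptote `a ← 1.05·max(y)`; rate and midpoint from
log-linearization; Richards starts at the logistic-equivalent `d = 2`;
the sine proposes two structurally different starts — a rising
quarter-wave (trough at the first day) and a wide "parabola mimic" whose
extremum matches the least-squares quadratic's vertex and curvature —
because short pre-peak arcs have a second basin that a single start
misses. If no start converges, the fit is returned flagged
`converged=False`, never raised. Per-point standard errors `σᵢ` are
supported; when the noise of a series is known to be multiplicative with
coefficient of variation `cv`, the recovery experiments fit with
`σᵢ = cv·yᵢ`, the correct likelihood weighting (this roughly halves the
error of the weakly identified sine parameters).

**Goodness of fit.** R² is the standard coefficient of determination
`1 − SSres/SStot` (flagged undefined for zero-variance targets). RMSE
follows the single-regressor convention `sqrt(SSres/(n − k − 1))` with
`k = 1` — every zoo member has one independent variable, time — so model
ranking by RMSE is ranking by residual sum of squares, with ties broken
toward fewer parameters. Reduced χ² divides the σ-weighted SSres by
`n − p` with `p` the fitted parameter count. Both `k` and `p` appear in
the fit record for auditability.

## Kinetics

A sigmoid's growth-rate curve has one peak (root of the second
derivative) and two flanking inflection points (roots of the third
derivative); the interval between the latter is the **rapid growth
period**. Roots are located by scanning for sign changes on
`tc ± 5/k` and refining by bisection to 1e-8 days; landmarks falling
outside a 10×-extended observation window flag the fit as degenerate.
For the logistic the landmarks have the closed form
`(ln b ± ln(2+√3))/k`, used as the independent oracle; for Richards the
third-derivative roots reduce to a quadratic in the exponential variable,
used as a second cross-check.

**Curd classification.** From the sine fit: `rate(t) = (Aπ/w)
cos(π(t−tc)/w)`, peak `Aπ/w` at `tc`; the harvest-time-to-peak rate ratio
and the trend of the rate at harvest give the label — ratio ≥ 0.95 →
*peak burst*; else rising → *steady climbing*; else *mature and full*.
The 0.95 plateau threshold is a declared convention (configurable); no
quantitative definition of "remained stable" exists to estimate it from.
Harvest days outside the fitted half-period are clamped and flagged.
Growth duration is harvest − appearance day, identical to ECEP.

**Lead-time regression.** Ordinary least squares of the fitted second
inflection day on the observed curd-appearance day (this orientation makes
a negative intercept mean "inflection precedes appearance"); the mean lead
`mean(TCA − t_infl2)` is reported alongside.

## Series operations

Growth rates are difference quotients between consecutive acquisitions
(or the nearest pair spanning a requested window), stamped at interval
midpoints so they plot symmetrically against fitted rate curves.
Curd-appearance detection requires a run of ≥ 2 consecutive acquisitions
with a detection (debouncing single-frame false positives; configurable).
Developmental alignment maps the appearance day to day 1 and drops
pre-appearance points for curd traits. Cohort mean series omit days with
fewer than 2 contributing plants, which trims trajectory tails and
removes single-plant survivor bias. Gaps are never interpolated — all
fitting handles irregular time points directly. A plant's harvest day is
its last acquisition day.

## The 14 traits

LA, PCW, CA, FCD are final observed values; MLA GR, Tmax LA GR and
D-LA RGP come from the Richards rapid-growth analysis; MCA GR from the
sine rate; TGP = harvest day; TCA as detected; ECEP = TGP − TCA;
AER = (CA at harvest − CA at appearance)/ECEP by default (the
`CA/ECEP` variant is available — no canonical formula exists);
GR = TCA / Tmax LA GR; PCC = CA/LA. When no bounding-box series exists
(synthetic cohorts), PCW and FCD fall back to the equivalent-circle
diameter of the final areas — deterministic in LA and CA, which is why
synthetic trait tables show r(LA, PCW) ≈ 1 rather than the ~0.96 of real
measurements.

Replicates average into germplasm means (germplasm is the unit of
inference; 47 means avoid pseudoreplication). Correlations are plain
Pearson with per-pair two-sided p-values, no multiple-testing correction.
Clustering z-scores each trait (sample sd), then applies Ward's
minimum-variance linkage on Euclidean distances — the only Ward variant
consistent with Euclidean inputs — and cuts at k = 4. Incomplete
germplasms are excluded, not imputed.

## Synthetic cohort design

The generator emulates the acquisition protocol: imaging from day 1 every
3 days, daily once the first curd appears anywhere in the cohort, camera
height switching after day 70. Four archetypes with germplasm counts
14/12/11/10 (total 47) encode the qualitative group contrasts: a
mid-maturity compact type (smallest leaf asymptote ≈ 5600 cm², earliest,
shortest season), a large high-yield type (≈ 15400 cm², latest, largest
curds), a curd-dominant type (moderate vegetative scale, shortest and
most intense curd expansion), and a comprehensively coordinated middle
type. Parameters are drawn hierarchically — germplasm means from the
archetype distribution, replicate values with 25% of the archetype sd —
and per-plant RNG substreams are derived by stable hashing of the plant
id, so cohorts are reproducible under reordering.

Curd sine parameters are constructed from biological landmarks
(appearance day, expansion period, start/final areas, harvest phase)
rather than drawn independently, which guarantees the observed window
lies inside the monotone half-period by construction. The appearance day
itself is built as the leaf rate-curve's second inflection plus a lag of
5.71 ± 1.5 days, encoding the lead-time relation the kinetics stage is
later asked to recover. Measurement noise is multiplicative Gaussian with
cv = 2% (a fixture choice — no observation-error magnitude is documented
for the real system); multiplicative, because trait magnitudes span two
orders over a season and additive noise would distort the early points.

What the generator does **not** emulate: segmentation failure and
occlusion (curds under inner leaves), RGB appearance, weather gaps in the
calendar, genuinely correlated replicate environments, or bounding-box
measurements (PCW/FCD are area-derived). Passing recovery tests therefore
demonstrates the correctness of the downstream analysis, not robustness
to segmentation error.

## Known limitations and honest numbers

- **Sine parameter identifiability.** On a pre-peak arc at 2% noise the
  sine's (y0, A, w) trade off along a flat valley: zero-noise recovery is
  exact to ~1e-12, but at 2% noise the per-parameter median errors are
  ~12% even though fitted curves are visually and statistically excellent
  (median R² 0.999) and the fitted optimum always has lower cost than the
  generating parameters. Kinetic quantities (rates, phases) are much
  better determined than raw parameters.
- **Sine vs quadratic model selection** is a photo-finish on purely
  convex (steady-climbing) arcs: the sine family approaches a parabola
  only asymptotically, so whenever a noise realization slightly favors a
  parabola the quadratic wins by ~0.1–0.3% of RMSE. With ~70% of curds
  harvested pre-peak, the sine ranks first in roughly three quarters of
  plants, not nearly all of them.
- **Classification at 5% noise** is limited by the variance of the fitted
  harvest phase (sd ≈ 0.4 rad) relative to the ±0.32 rad plateau band
  implied by the 0.95 threshold: accuracy is ~78–85%, with at-peak curds
  the hardest. At zero noise it is exact.
- **Clustering recovery** of the four archetypes yields ARI ≈ 0.84–1.0
  across seeds; the comprehensively coordinated and curd-dominant
  archetypes are genuinely adjacent and occasionally trade 1–2 boundary
  germplasms.

## Problem sizes and determinism

The validation experiments use the full study geometry: 141 plants for
recovery, model selection and the lead-time regression; 300 plants for
noisy classification; 100 fixtures for the kinetics oracle and the mask
round trip. Everything is seeded: one integer fans out to per-plant
substreams, and reruns of the pipeline with the same config and seed
produce byte-identical CSVs.
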