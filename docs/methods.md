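# Methods

## Geometry model

The lesion (IPL) is a sphere of radius `r` (mm); the boost (SIB) dose
is idealized as constant inside the concentric sphere of radius
`r + m` and zero outside. Intrafraction motion displaces the prostate
— and with it the lesion — by a vector whose Euclidean length `d`
separates the two sphere centres. The overlap is the classical
two-sphere lens volume

    V_overlap(d) = π/(12d) · (2r + m − d)² · (d² + 2d(2r + m) − 3m²)

on the open window `m < d < 2r + m`; below it the lesion sphere is
entirely inside the boost sphere (`V_overlap = 4πr³/3`), above it the
spheres are disjoint (`V_overlap = 0`). The function is continuous at
both branch points (the formula reduces to the limits there), and both
boundary ties are assigned to the closed-form limits: `d = m` → full
enclosure, `d = 2r + m` → zero.

Two per-sample fractions are derived:

* `c_IPL(d) = V_overlap / (4πr³/3)` — non-increasing and continuous in
  `d`, in `[0, 1]`;
* `c_SIB(d) = r³/(r+m)³ · c_IPL(d)` exactly; its maximum over any
  trajectory is `r³/(r+m)³`, attained iff some sample has `d ≤ m`.

Numerics: the `1/d` prefactor is folded into the last factor
(`d + 2(2r+m) − 3m²/d`) so the `m = 0, d → 0⁺` corner stays finite,
and the result is clipped to `[0, 4πr³/3]` against rounding at the
window edges. The lens formula is never evaluated at `d = 0`.

Report tables round fractions to integer percent with half-up ties
(0.125 → 13 %); raw fractions are retained at full precision
internally and in the non-`_percent` CSVs.

## Motion model

Each axis (lateral, longitudinal, vertical) of the displacement from
the start-of-fraction position is an independent Gaussian random walk
with drift:

    Δx over Δt  ~  N( v·Δt ,  σ²·Δt·M_p² )

with `v` the drift rate (mm/min), `σ` the diffusion scale
(mm/√min), and `M_p` a per-patient motility multiplier, constant
within a patient, drawn log-normally with median 1 and log-sd `τ`
(`patient_motility_sd`). The walk starts at exactly (0, 0, 0) because
displacements are defined relative to the image-guided
start-of-fraction position. Displacement variance therefore grows
linearly in elapsed time — the defining empirical feature of
intrafraction prostate drift, and the reason a static Gaussian setup
kernel (as in conventional inter-fraction margin recipes) is not an
adequate substitute. No mean-reversion term is included; tracked
prostates show sustained drift within the few-minute fractions
modelled here, and the model deliberately stays minimal.

Seeding is hierarchical and documented so any subset regenerates in
isolation: with root seed `s`, the multiplier of patient `p` comes
from `SeedSequence([s, 1, p])` and the trajectory of fraction `f` of
patient `p` from `SeedSequence([s, 2, p, f])`. Identical parameters
and seed reproduce the cohort byte-for-byte after CSV serialization.

### Calibration of the defaults

The defaults in `src/iplboost/data/default_config.yaml` emulate a
28-patient 4D-ultrasound tracking cohort with 720 recorded fractions
totalling 53 h 33 m:

* `fraction_duration = 4.4625 min` (total time / 720 fractions) and
  `sample_interval = 5 s` → 54 samples per fraction;
  `fractions_per_patient = 26` → 728 fractions (720 is not divisible
  by 28) and 39,312 pooled samples.
* For a walk sampled at times `t_0 … t_K`, the pooled per-axis
  variance is `σ² · mean(t_k) · E[M²]` with `mean(t_k) = 2.2083 min`
  and `E[M²] = e^{2τ²}`. Inverting for pooled standard deviations of
  0.76 / 1.15 / 1.64 mm (lateral / longitudinal / vertical) gives
  `σ = 0.4358 / 0.6594 / 0.9404 mm/√min`. The ordering lateral <
  longitudinal < vertical reflects that the prostate drifts mostly
  posteriorly/inferiorly (bladder and rectum filling), barely
  laterally.
* Pooled per-axis means of −0.13 (longitudinal) and +0.11 mm
  (vertical) give drifts `v = mean / mean(t_k)` = −0.0589 and
  +0.0498 mm/min; lateral drift 0.
* `τ = 0.4`: the expected range of 28 standard-normal draws is ≈ 4.14,
  so per-patient motility multipliers span a factor ≈ e^{4.14·0.4} ≈ 5,
  matching the reported factor-five spread of per-patient mean radial
  displacement (0.50–2.53 mm).

These are cohort-level moment matches, not fits: a single simulated
cohort realization lands near, not on, the targets (e.g. the pooled
radial mean of the default seed is 1.82 mm against the 1.28 mm
reference — within the sampling spread induced by 28 lognormal
multipliers).

### What the generator does not emulate

Real trajectories contain transient excursions (peristalsis, gas),
occasional step changes, heavy-tailed increments and possible
within-fraction correlation structure beyond the diffusion term. Tests
passing on synthetic cohorts therefore validate the *pipeline
arithmetic* (statistics, coverage, DVH) and the *stated statistical
structure* (variance law, anchoring, motility spread), not the
faithfulness of any specific real cohort's tables; all
trajectory-dependent table entries are data-dependent by construction.
The two quantities that are geometry-forced — the best-case boost
occupancy `r³/(r+m)³` for each (r, m) — are exact regardless of
motion.

## Statistics

Ten statistics (mean, sample std with ddof = 1, min, 5/25/50/75/95 %
quantiles, max, rms) are computed per axis on the signed displacements
and on the radial distance, pooling every sample with equal weight
over all fractions and patients, or stratified per patient. Quantiles
use linear interpolation between order statistics (type 7, numpy's
default); no convention is scientifically forced, so one is fixed for
bit-for-bit reproducibility. The t = 0 anchor sample of each fraction
is a recorded position and is included by default
(`include_anchor=False` to drop it).

## Dose–volume histograms

`n` points (default 5000) are sampled uniformly in the lesion sphere
via isotropic direction (normalized Gaussian triple) × radius
`r·U^{1/3}` — chosen over rejection sampling so output is seed-stable
for a fixed draw count. Each point's dose fraction is the fraction of
displacement samples whose shifted boost sphere contains it
(inclusion test uses `≤`); the denominator is always the actual
number of displacement samples. The cumulative curve is built from
the exact per-point doses (no binning); the CSV writer additionally
grids doses at 1 % steps, as presentation only.

* `V_D` (volume at dose) is the exact fraction of points with dose
  ≥ D.
* `D_V` (dose at volume) is the `ceil(v·n)`-th largest point dose —
  the lower order statistic, conservative in the sense that "at least
  `v` of the volume receives ≥ D" holds exactly on the sampled points.

The mean per-point dose and the trajectory-mean of `c_IPL` are two
estimators of the same volume integral; their agreement within Monte
Carlo error is a standing cross-check in the test suite, as is the
dominance ordering of curves in the safety margin.

Per-patient DVHs reuse the same point set (per distinct radius,
derived from the root seed) across patients and margins so curves are
directly comparable.

## Pipeline

`run_pipeline` chains simulate (or load external CSV) → displacement
statistics → coverage tables (raw and percent, for both `c_IPL` and
`c_SIB`) → DVH CSVs per geometry (and per patient on request), and
writes a manifest (full config including all seeds, realized sample
counts, library versions) from which every output is exactly
reproducible. Defaults analyse the grid r ∈ {3, 5, 7} mm ×
m ∈ {0, 2, 5} mm. Degenerate geometries (margin exceeding the largest
recorded displacement, hence trivially full coverage) are logged as
warnings, not errors.

## Problem sizes in the test suite

Unit and property tests run on scaled-down cohorts (e.g. 10 patients
× 3 fractions) with the *motion scales untouched* — only counts are
reduced, so every statistical check still probes the calibrated
regime. The heavier statistical checks use 10,000 replicate fractions
(variance law), 1,000 random geometries × 200,000 Monte Carlo points
(lens-formula oracle), and 5,000-point DVHs (estimator consistency),
with fixed seeds throughout.

## Known limitations

* Sphere-only geometry: no organ-at-risk dosimetry, no non-spherical
  dose distributions or dose gradients.
* Centre-of-gland translation only: no rotation or deformation, no
  interplay with collimator/apparatus motion during delivery.
* No measurement noise model on top of the trajectories.
* The drift-diffusion generator is a statistical stand-in, not a fit
  to any patient's data (see above).
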