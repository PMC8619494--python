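# Methods

## The measurement model

A flow cytometer's side-scatter (SSC) signal reports intracellular
granularity. Metal nanoparticles associated with a cell — internalized or
membrane-bound; the method cannot distinguish the two — add scattering
centers, so a sample's mean SSC rises with its per-cell particle load.
Because raw SSC intensities drift with instrument settings and acquisition
batch, all inference is on the batch-normalized ratio

    nSSC = mean SSC of exposed sample / mean SSC of same-batch control.

Controls sit at nSSC = 1 by construction. The statistic is the *arithmetic
mean* over events (a median option exists but is never the default, since
the calibration is defined on means), computed after optional rectangular
gating; no gating is applied by default.

The calibration anchors every regression at the control point: an unexposed
sample has zero particles, so each per-size line is forced through
(nSSC, c-Ag) = (1, 0),

    c-Ag = m_d · (nSSC − 1),

with the closed-form forced-origin least-squares slope
m = Σ xᵢyᵢ / Σ xᵢ², x = nSSC − 1, y = c-Ag. Per-size slopes fall steeply
with core diameter — at a fixed mass dose, smaller particles are more
numerous and are taken up in larger numbers, while each contributes less
scatter — and are condensed into

    m(d) = a + b·e^(−k·d),

whose large-d asymptote a, amplitude b and decay rate k (1/nm) are fitted by
unweighted nonlinear least squares. The combined estimator
c-Ag = m(d)·(nSSC − 1) interpolates between calibrated sizes; where a
sample's diameter is exactly calibrated, the per-size line is preferred (it
is consistently the lower-RMSE estimator, in line with the published
ten-fold RMSE gap between the two modes).

The empirical exponential is *not* a scattering theory: Rayleigh (∝ d⁶) and
Mie predictions do not fit cell-associated particles, and no mechanistic
scattering model is attempted here.

## Reference counts from ICPMS

The regression's y-axis comes from element analysis: total silver mass of a
digested pellet divided by a hemocytometer cell count, divided by the mass
of one particle. The particle mass model is a solid sphere at the *nominal*
core diameter and bulk density (10.49 g/cm³ for silver; configurable for
other materials):

    m_particle = ρ·(π/6)·d³  →  5.4925 fg at d = 100 nm.

Hydrodynamic diameter is deliberately never used: corona and agglomeration
grow the scattering envelope, not the metal content. Masses are carried in
femtograms internally and nanograms at file boundaries. Two acknowledged
simplifications: no dissolved-ion correction (Ag⁺ released by dissolution is
counted as particles) and no digestion-recovery modelling.

## Fitting choices

* **Forced-intercept R².** No universal definition exists for a regression
  through a fixed point. We report the centered convention
  R² = 1 − SS_res/Σ(y − ȳ)², the most conservative: it can be negative when
  the forced line underperforms the mean, and is NaN (a sentinel, not an
  exception) when all y are equal.
* **Exponential fit.** The (b, k) objective is nearly flat along a ridge, so
  a single local fit is irreproducible. Levenberg–Marquardt is launched from
  a grid of 20 decay rates k ∈ [0.01, 0.2] nm⁻¹ crossed with a ∈ {0, min
  slope}, b solved from the smallest-diameter point at each start; the
  lowest-RSS converged solution is returned and is verified to beat every
  start. The fit is unweighted — each per-size slope counts equally — since
  no weighting scheme is implied by the data. At least three distinct
  diameters are required for identifiability.
* **Negative estimates.** nSSC < 1 yields a negative c-Ag estimate. It is
  returned as-is and flagged `sub_control`, never silently clamped (clamping
  biases downstream averages); a `clamp` option floors at zero for
  reporting. Estimates beyond the calibrated range (nSSC > 23 by default,
  the upper end of the validated working range) are flagged `out_of_domain`.
* **Pooling.** Per-size fits pool both plate configurations and all media
  heights into one line per diameter; the response is treated as a function
  of particle load only, with exposure conditions acting through the load.
  Per-condition fitting is available by filtering points before the fit.

## Validation workflow

Points are split into training and validation sets by a seeded random split
stratified by diameter (both sides of every stratum non-empty); the scheme
and seed are recorded in the report. Validation estimates each held-out
point from its nSSC and condenses deviation from the ICPMS-measured value
into RMSE (particles/cell). Exclusion of an anomalous size is explicit and
auditable: a diameter is flagged when its group RMSE exceeds 3× (tunable)
the median group RMSE, and reports always carry the inclusive RMSE next to
the exclusive one, so exclusion never hides data.

## The synthetic study generator

`sscquant.synthetic` emulates the paired experiment the calibration assumes:
2 configurations × 3 media heights × 5 core sizes × 3 replicates, with one
unexposed control per (configuration, height, replicate) batch. The effect
model is deterministic per condition:

    c(d, config, h) = base · (d_ref/d)^1.5 · (h/⟨h⟩) · f_config · anomaly

with f_upright = 1, f_inverted = 0.4 (diffusion-only delivery), a 4× uptake
boost at the anomalous diameter (40 nm by default, mimicking the unusually
high association of heavily agglomerating small particles), and
base = 11,000 NPs/cell — chosen so the design maximum (66,000 NPs/cell) and
maximum nSSC (≈ 21.5) sit inside the validated working range (~80,000
NPs/cell, ~23 nSSC). These encode the qualitative orderings of the real
experiment (upright > inverted, increasing with height, decreasing with
size except the 40 nm anomaly); no per-condition numeric table exists to
match magnitudes against, and none is attempted.

Noise enters at three places, each a config parameter: event-level SSC
spread (log-normal, CV 0.35 — right-skewed and strictly positive, the
standard shape for cytometry intensities; only the mean matters downstream),
sample-level mean perturbation (Gaussian, CV 0.05, replicate biology and
drift), and ICPMS mass error (Gaussian, CV 0.10, truncated at zero). The
cytometry read-out inverts the estimator exactly — sample mean SSC =
control mean × (1 + c/m(d)) — so a zero-noise study round-trips to the
generating slopes identically; this identity is the package's core test
oracle. Output is fully deterministic for a fixed seed, including CSV bytes.

What the generator does *not* emulate — hence what passing tests cannot
show about real data: particokinetic transport (sedimentation/diffusion
ODEs), agglomeration kinetics, single-particle optics, cytometer
electronics (pulse shapes, compensation, doublets), dose–response
saturation, and any deviation of real uptake from the assumed linear
SSC–load relation.

## Problem sizes and numerics

Simulation-backed checks run at sizes chosen to make Monte-Carlo error
negligible relative to the tolerances they assert: slope-recovery
experiments use 200 replicates of 30 points at 10% CV (the forced-origin
estimator is unbiased under multiplicative noise, so means converge at
~0.7% standard error); ordering properties (per-size vs combined RMSE,
exclusion benefit) are asserted as majorities over 50 seeded studies at
2,000 events/sample. Law-of-large-number checks use 50,000 events and 3-σ
bands. All randomness flows through `numpy.random.default_rng` seeds.

## Known limitations

* The calibration constants are specific to bPEI-coated Ag particles on
  A549 cells with a 488 nm instrument; transfer to other particles, cells
  or cytometers requires re-calibration.
* nSSC cannot separate internalized from membrane-bound particles, and the
  linear model says nothing below nSSC = 1 or above the calibrated range.
* The ICPMS reference counts inherit the sphere-at-nominal-diameter
  convention; polydisperse or hollow particles would bias c-Ag accordingly.
* The FCS reader covers single-dataset list-mode files (float32/float64/
  integer, either byte order); spectral, multi-dataset or ASCII-encoded
  files are rejected with a format error.
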