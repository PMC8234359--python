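# Methods

This note documents the models, conventions, and numerical choices behind
`zfpk`, and what the synthetic-data tests do and do not demonstrate.

## Measurement model

The observational unit is an integrated fluorescence intensity (RFU):
the sum over a delineated region of interest of the background-corrected
pixel values, `Σ max(0, pixel − background)`. Background is a single
scalar offset per image; no flat-field or registration correction is
applied, and masks are supplied rather than segmented (the workflow this
replaces used manual delineation, so automated segmentation is
deliberately out of scope). Whole-body (WB) and yolk regions are
quantified directly; rest-of-body (RoB) is their pointwise difference.
Because noise can drive WB − Yolk below zero while the underlying
quantity is non-negative, negative differences are clamped to zero and
every clamp is logged. Yolk contours are only meaningful up to 72 h
(afterwards the yolk is no longer discernible), so yolk and RoB series
stop there.

Times are hours post exposure start. Exposure begins at the two-cell
stage, so hours post fertilization and hours post exposure coincide to
within minutes; the package treats post-exposure time as authoritative.

## AUC and censoring

Exposure is summarized by the linear-trapezoidal AUC over a configurable
window, default 0.25–72 h — the interval over which both routes have
comparable data (the bath is washed out at 72 h; the alternative 0–120 h
reading of the exposure-ratio definition is inconsistent with the
tabulated window and was resolved in favor of the table). Censored points
are removed before integration; the integral runs from the first retained
observation to the last retained observation inside the window, with no
back-extrapolation — integrating into a region where the signal is known
to be corrupted would manufacture area from an artifact. A series with a
single retained point yields AUC = 0 with a degenerate-window warning;
zero retained points is an error.

Censor flags normally arrive with the data (`censored` column). For the
early post-injection quenching artifact — the injected dye transiently
aggregates at the depot and under-reports fluorescence — a heuristic
policy (`iy_leading_quench`) is provided: on injection-route series of
the depot-bearing compartments (WB and yolk), the leading run of points
that precede the time of the series maximum and fall below θ × maximum
(default θ = 0.8) is censored. Two deliberate restrictions:

* The rule is **not** applied to RoB series. RoB rises monotonically by
  redistribution, so its maximum is the last point and the leading-run
  rule would censor essentially the whole series.
* Explicit flags always take precedence; the policy only adds flags.

Known limitation: under substantial measurement noise (CV ≳ 0.1) the
θ-cutoff is computed against a noise-inflated maximum, and the rule can
censor extra plateau points, deflating AUC and biasing RD upward by
roughly +0.02–0.03 in simulation. The heuristic is intended for averaged,
low-noise curves of the kind produced by cohort imaging; with noisy
single-replicate data, prefer explicit flags (the default policy). The
quench artifact itself, left uncensored, perturbs RD by < 0.01 because it
recovers within a few hours of a 72-h window.

## Exposure statistics

Relative Exposure, RE = AUC_imm / AUC_inj per compartment, and Relative
Distribution, RD = AUC_RoB / AUC_WB after injection, are unitless and
invariant under rescaling of the fluorescence axis — the property that
makes them comparable across compounds with different quantum yields.
Conventions:

* RE with a zero immersion AUC is exactly 0 ("no detectable uptake"); a
  zero injection AUC makes the ratio undefined and is an error — the two
  cases are deliberately distinct.
* RD lies in [0, 1] for exact inputs because WB = Yolk + RoB. Published
  (rounded) inputs can violate the decomposition slightly; the ratio then
  warns rather than fails, and RD is capped at 1 in summaries.
* All internal arithmetic is full precision; rounding (2 decimals for
  ratios, 3 for model statistics) happens only in reports.

Reproduction caveat: recomputing the published exposure table from the
published AUC table agrees to ±0.02 in 27 of 28 cells. The exception is
the FAMA injection row, whose printed WB value (27.8) is inconsistent
with its own Yolk + RoB decomposition (21.83) — the derived RD (0.25 vs
printed 0.32) inherits the inconsistency. The packaged fixture keeps the
printed value; tests document the exception rather than patch it.

## QSPkR regression

Ordinary least squares on small polynomial designs. Quadratic and
interaction terms are centered — `(x − x̄)²`, `(a − ā)(b − b̄)` — which
changes coefficients but not the fitted surface (an invariance the tests
enforce). Centering defaults to sample means recomputed from the input;
a fixed-constants mode reproduces externally printed equations exactly.
The sample means of the reference panel (Log D: −0.177, MR: 166.591)
match the printed centering constants to three decimals, which is how the
convention was identified.

Reported statistics: R² = 1 − SSE/SST, adjusted R², RMSE = √(SSE/(n−p))
(residual standard error), and the overall-regression F-test p-value.
For the reference panel the printed "R² adj" column is internally
inconsistent: the RoB model's printed 0.82 matches adjusted R², while the
WB model's printed 0.81 matches plain R² (adjusted ≈ 0.71). Both are
always reported. The yolk model spends 5 parameters on 7 observations
(2 residual degrees of freedom) and is flagged as near-saturated.

No variable selection is implemented: the three model forms are taken as
given. Fitting uses statsmodels OLS; tests cross-check the coefficients
against a direct Nelder–Mead minimization of the SSE and verify residual
orthogonality from the normal equations.

## Synthetic-data generator

The generator produces the phenomenology the pipeline must handle, with
exact ground truth — it makes no mechanistic claim. Kinetics are
two-compartment first-order with closed-form piecewise solutions (no ODE
solver): WB = Yolk + RoB identically at all times.

* **Immersion**: uptake into the embryo at rate `k_up · permeability ·
  c_imm` while the bath is present (t ≤ 72 h), split 70/30 between yolk
  and RoB (the lipid-rich yolk retains small molecules; the 0.7 fraction
  matches the observed immersion yolk/WB AUC ratio of the most lipophilic
  reference dye), yolk→RoB redistribution at `k_redist`, washout after
  72 h, RoB elimination (`k_elim` = 0.05 h⁻¹) only after 96 h — late
  enough not to touch the default AUC window.
* **Permeability** is logistic in Log D, midpoint 1.4 and slope 4, so the
  Log D 1.73 compound absorbs readily (≈ 0.79) while compounds below
  Log D ≈ 0.5 are essentially excluded — reproducing the observed
  pattern in which only the most lipophilic dye reaches RE > 1.
* **Injection**: the full dose starts as a yolk depot and redistributes
  at `k_redist` = 0.008 h⁻¹, chosen so the true 72-h redistributed
  fraction (RD = 0.24) sits inside the realistic 0.17–0.32 band. An
  optional per-compound spread (`redist_range`) draws rates whose RD span
  covers that band, at the cost of larger trapezoid discretization error
  for the fastest-redistributing compounds (up to ≈ 2.2 % on RE_RoB,
  versus ≤ 1.9 % with the shared default rate).
* **Quenching** is an observation artifact, not a mass change: the
  observed yolk signal after injection is multiplied by
  `1 − exp(−t/1.5 h)`, suppressing the 15-min observation by ~85 % and
  recovering almost fully by 6 h.
* **Noise** is multiplicative lognormal with mean 1 and specified CV
  (default 0.1), drawn independently for yolk and RoB; the observed WB is
  their sum, so synthetic tables satisfy WB = Yolk + RoB exactly — the
  same additivity a subtraction-based quantification produces.
* **Doses** (`dose_iy` = 1000, `c_imm` = 10) are arbitrary
  fluorescence-equivalent units: every downstream statistic is
  scale-free, so absolute levels are irrelevant by construction.

The image renderer deposits each compartment's amount as a smoothed
random texture truncated at the compartment boundary and renormalized, so
integrated intensity over the ground-truth mask equals the requested
amount exactly (16-bit quantization on disk perturbs each pixel by at
most 0.5). Geometry is a stylized lateral view: elliptical body,
circular yolk.

What passing synthetic tests show: the pipeline inverts the generator's
observation model — quadrature error only, no systematic bias from the
noise or artifact handling at the study's sampling design. What they do
not show: robustness to real-image confounds (uneven illumination,
embryo-to-embryo geometry variation, segmentation error, autofluorescence,
signal bleed across the yolk boundary), none of which the generator
emulates.

## Problem sizes and determinism

All analyses are small (7 compounds × 2 routes × ≤ 3 compartments × 9
timepoints); the test suite and the acceptance script each run in
seconds. Monte-Carlo checks use 200 study replicates (RD bias) and 500
regression refits (coefficient recovery) — large enough that the
standard error of the estimated bias is well below the 0.02 decision
threshold. Every stochastic component is seeded through
`numpy.random.default_rng`; identical seeds give bit-identical series,
images, and output files. Ground-truth AUCs use dense-grid trapezoid
quadrature at Δt = 0.02 h, two orders of magnitude below the visible
discretization error of the 9-point study grid.
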