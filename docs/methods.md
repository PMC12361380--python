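# Methods

This note documents the models, conventions, defaults and numerical choices
behind `ooquant`, and what the synthetic-data experiments do and do not
demonstrate.

## Imaging model and conventions

An `ImageStack` is a calibrated `(z, y, x, channel)` volume of non-negative
intensities in arbitrary units, with lateral pixel size and z-step in µm.
Voxel indices are 0-based; physical distances are in µm; masks follow the
half-open array convention. OME-TIFF round trips preserve calibration and
channel names; files without resolvable calibration require an explicit
pixel-size override, and the value used is recorded in the stack metadata.

Before profiling, stacks can be resampled laterally to a common pixel size
(linear interpolation; the original calibration is kept under
`metadata["rescaled_from"]`). No canonical target pixel size exists for this
kind of data, so the target is a required argument rather than a constant.

## Segmentation

Oocyte and cumulus cells are separated purely by size: connected components
above an intensity threshold whose equatorial equivalent diameter reaches
50 µm (default, configurable) are oocytes; smaller components are cumulus
cells. Human oocytes (~110–120 µm) and cumulus cells (~10 µm) leave a wide
unambiguous gap, so the cut value is uncritical.

Numerical choices:

- The default threshold is Otsu computed on log-intensities. On a linear
  histogram a bright organelle cluster can dominate and Otsu then splits
  "cluster vs rest of cell"; on the log scale the dominant separation is
  cell vs dark medium, which is the intended split. An absolute threshold
  can be supplied instead.
- Each component's boundary is then tightened to half its median internal
  intensity (iterated to a fixed point). This is the standard half-maximum
  edge criterion for blurred objects; without it, small bright cells absorb
  a rim of dim surroundings and their mean intensities are diluted several-
  fold, which would bias every oocyte-vs-cumulus comparison.
- The equatorial plane is defined operationally as the z-slice of maximal
  cross-section area; the equatorial ellipse is the second-moment best fit
  at that plane, and the diameter readout is its major axis.
- Cumulus viability: cells whose mean mitochondrial-potential (TMRE) signal
  falls below 2× the median background outside all cells are treated as
  dead and excluded. The factor is configurable; positivity has no
  published operational definition for these data.

## Radial profiling

From the equatorial ellipse centre, rays are cast at 1° increments (360
rays by default) and sampled by bilinear interpolation at one-pixel radial
steps, for every z-slice; the rays are averaged over angle into a
radius × z image. The equatorial band (equator ± 2 slices by default) is
averaged into a single mean-intensity-versus-distance curve. Angle-first or
z-first averaging are mathematically identical for means; angles-first is
implemented and the band average is verified against brute-force voxel
means in the tests.

Per-oocyte curves end at the mean ellipse radius so that zona and exterior
signal never enter the curve, and are min–max normalized (min → 0,
max → 1; a constant curve is an error). Cohort curves are built by linear
interpolation of each normalized curve onto a common grid spanning 0 to the
smallest oocyte radius in the cohort; each distance records the mean,
sample SD (n − 1; zero where a single curve contributes) and the number of
contributing curves. Profiles never extrapolate beyond their own support.

## Breakpoint (two-segment) regression

The radial distribution of a channel is summarised by the breakpoint ψ of a
continuous two-segment linear model fitted to the cohort mean curve
(unweighted — the per-distance SD is reported but not used as weights).
The estimator is the classical iterative linearisation for segmented
regression: at working breakpoint ψ₀, regress y on
{1, x, (x − ψ₀)₊, −1[x > ψ₀]} and update ψ ← ψ₀ + γ̂/β̂, where β̂ and γ̂ are
the hinge and indicator coefficients. Numerical details:

- Initialisation: best candidate on a coarse grid (range/50) when no
  explicit ψ₀ is given; explicit ψ₀ must lie strictly inside the data
  range. Convergence tolerance 10⁻⁴ µm, at most 50 iterations, restarts
  from 25/50/75% of the range if the update leaves the data range.
- On noisy data the linearisation oscillates within a small neighbourhood
  of the optimum, and the exact RSS profile has micro-minima between
  neighbouring x values. After the iteration, a fine local scan (0.01 µm
  steps within ±2 µm) plus a bounded Brent polish settles ψ on the exact
  local RSS minimiser. With the coarse-grid initialisation this matches an
  exhaustive 0.01 µm grid search (implemented independently as
  `grid_search_oracle`) on every tested instance.
- The standard error of ψ̂ comes from the delta method on γ̂/β̂ using the
  OLS covariance of the final working model; the 95% CI is
  ψ̂ ± 1.959964·SE, clipped to the data range with a warning. When no slope
  change is detectable (β̂ ≈ 0) the breakpoint is unidentified and the SE
  is reported as infinite.
- Reported slopes and RSS come from the continuous three-parameter model
  refitted at ψ̂; `slope_right − slope_left` equals the hinge coefficient
  by construction.

In simulation (n = 300 grid points, noise SD 0.05, strong slope contrast)
the empirical coverage of the 95% interval is ≈ 93–95%: the Wald/delta
interval is known to be mildly anticonservative for breakpoints, and large
replicate counts can resolve that 1–2 point deficit. Exactly one breakpoint
is modelled; model selection (e.g. Davies' test) and multi-breakpoint fits
are out of scope.

Two conditions are compared by 95% CI overlap; the comparison reports the
signed gap between the nearest interval endpoints (positive = disjoint).

## Intensity statistics

- Whole-oocyte activity readout: mean over the projected oocyte mask of
  the maximal-Z projection.
- Per-donor normalization divides each donor's readouts by that donor's
  median of a reference group — GV oocytes for stage comparisons, cumulus
  cells for oocyte-vs-somatic comparisons (configurable; the reference
  median is exactly 1 per donor afterwards). Donors lacking a reference
  record are excluded with a warning, so only donors contributing both
  groups enter a comparison.
- Oocyte-vs-cumulus comparisons use per-slice 2D-mask means restricted to
  z-slices containing both compartments, averaged across qualifying
  slices.
- Paired treatment effects (e.g. probe retention after the efflux blocker
  verapamil) are after/before ratios matched by cell id; unmatched cells
  are dropped with a warning.
- Group comparisons use unpaired two-sided t tests with Welch's correction
  (scipy's implementation; the test suite checks it against the closed-form
  Welch/Satterthwaite formulas to 10⁻¹⁰ and its null type-I error by
  simulation). No multiple-testing correction is applied — comparisons are
  reported independently — and donor-level averages are provided for
  donor-paired displays.

## Membrane peak and refractile bodies

The plasma-membrane readout is the maximum of the raw radial profile within
±3 µm of the cell boundary; the interior of the curve provides a background
median and SD, and the maximum is flagged as a genuine peak only above
background + 2 SD. The intracellular counterpart takes a maximal projection
over the equatorial band and averages over the equatorial mask eroded by
3 µm (default), the largest cytoplasmic area that safely excludes the
membrane rim.

Refractile bodies are detected inside the oocyte as connected components of
the detection channel above `rel_threshold` (default 3) times the median
intra-oocyte intensity, filtered by volume-equivalent diameter ≥ 2 µm
(default). Marker positivity per channel requires the body mean to reach 2×
the local background (median inside the oocyte with bodies excluded); the
per-oocyte count includes bodies positive in all required channels. All
thresholds are relative, so counts are invariant to global intensity
scaling. Manual counting was the only precedent for this readout; the
automated surrogate's defaults are validated against planted bodies in the
simulator and exposed in the API.

## Synthetic cumulus–oocyte complexes

The generator renders what the pipeline needs to be testable, not optical
realism:

- Geometry: a spherical oocyte of diameter 115 µm; a nucleus (default
  radius 12 µm, GV presets) that excludes organelle puncta — MII presets
  use a token 1 µm nucleus since the germinal vesicle has broken down; ~10
  cumulus cells of radius 5 µm on an equatorial ring outside a 10 µm zona
  gap. Default voxels 0.4 µm laterally and 2 µm axially, matching typical
  confocal acquisition of whole oocytes; tests and the validation
  experiments use 1.0–1.5 µm lateral voxels to keep run times in seconds
  (the planted truths are voxel-size independent).
- Radial organelle densities are mixtures of a uniform component, a
  central uniform ball ("cluster", radius 30 µm in GV-like presets with
  95% weight; 50 µm for dispersed MII mitochondria, 20 µm for centrally
  clustered MII lysosomes) and a Gaussian shell. The shell is defined as a
  Gaussian ridge in volume (intensity) density — the per-radius sampling
  density carries the r² geometric factor — so a shell planted at 40 µm
  peaks at 40 µm in the measured profile.
- Each punctum is rendered as a 3D Gaussian (PSF σ 0.3 µm laterally, 3×
  wider axially, both configurable) at its sub-voxel position. Noise is
  Poisson on the expected intensity plus Gaussian read noise (SD 3);
  the cytoplasmic baseline (default 500) keeps the maximal-Z projection's
  noise-extreme bias small relative to multiplicative signal changes.
- Donor effects are a single lognormal multiplier per donor applied to the
  whole scene; per-donor normalization cancels them exactly, which is the
  point of that procedure. Stage and treatment effects are multiplicative
  gains on oocyte and cumulus signal; re-imaging the same scene with new
  gains reuses the scene seed (same organelle positions) with a fresh
  noise seed.
- The planted oocyte:cumulus intensity ratio is defined on the z-slices
  both compartments occupy: the cumulus level is derived from the expected
  oocyte mean over those slices, so the per-slice comparison estimates it
  without geometric bias.
- Cohort datasets pair every donor with both stages. By default both
  stages share the GV spatial pattern so the planted stage ratio is a pure
  intensity effect — projection readouts would otherwise confound
  intensity with redistribution; the stage-dependent spatial contrast is
  exercised separately through the per-stage presets.

Everything is deterministic given the truth object: one seeded generator
drives geometry and sampling, a second (derived) one drives noise, and
identical seeds give bit-identical stacks at every level.

What passing on synthetic data does not show: robustness to real-world
zona autofluorescence, depth-dependent attenuation, spherical aberration,
polar bodies, touching or irregular cumulus clumps, or stage classification
errors — none of which are modelled.

## Validation experiments

`ooquant.validation` (driven by `scripts/acceptance.py` and the acceptance
tests) recovers planted truths end to end at desk scale: exact noiseless
breakpoint recovery; agreement of the iterative fit with the exhaustive
grid oracle on 50 noisy instances; 95% CI coverage over 500 replicates;
flat-disc, planted-shell and rotation checks of the profiling chain;
ordered non-overlapping breakpoint CIs for GV-like vs MII-like cohorts of
8 oocytes each; recovery of planted 0.5 oocyte:cumulus and 0.6 GV:MII
ratios through segmentation → readout → per-donor normalization; Welch
type-I calibration over 1000 null replicates; and exact counting of 5
planted refractile bodies with a sub-threshold body excluded.
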