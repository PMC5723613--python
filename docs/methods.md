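# Methods

`divebout` reconstructs, as a tested pipeline, the inference chain used in
multi-sensor seabird foraging studies: 1 Hz depth and 25 Hz tri-axial
acceleration to dives and dive bouts, unsupervised behavioral partitioning
to pursuit-and-catching events (PCE) and pursuit-and-catching time (PCT),
benthic/pelagic classification against bathymetry, and penalized-spline
GAMs linking capture effort to dive covariates and bout residence time.
This note records the models, the parameter choices that matter, and the
places where the design was genuinely open.

## Segmentation definitions

A **dive** is a maximal submerged run — consecutive samples with corrected
depth above the wet threshold (default 0.5 m) — whose maximum depth reaches
at least 1 m. The run is half-open `[start, end)`: `start` is the first wet
sample, `end` the first dry one. The 1 m criterion is the standard auk dive
definition; the wet threshold is our own convention for the start/end
instants (the 1 m rule alone does not define them) and is set to the scale
of the pressure sensor's surface noise. Both thresholds are inclusive
(`>= 1 m`) and exposed as CLI flags.

A **dive bout** is a maximal group of consecutive dives whose inter-dive
surface gaps (end of one dive to start of the next) are at most 300 s,
inclusive; an isolated dive is a bout of one. Bout time underwater is the
sum of member dive durations, exactly.

Depth is obtained from pressure as `(p - p_surface) / 100 mbar per metre`
(no latitude or density correction — a documented approximation), with
small negative values retained down to -0.5 m. The surface pressure is
tracked by a running minimum over a 10-minute window, lightly smoothed;
this assumes the bird surfaces at least once per window, which holds for
auk-like divers whose dives last a few minutes at most.

## Behavioral partitioning and PCE

Per deployment, the 25 Hz trace is summarized in non-overlapping 1 s
windows: static acceleration (2 s centered running mean, the
gravity/posture component) per axis, mean absolute dynamic acceleration per
axis, mean VeDBA and ODBA, per-axis variance, and pitch from the static
vector. A K-component full-covariance Gaussian mixture is fitted to the
window features by EM (best of 5 seeded restarts, covariance ridge 1e-6
relative to the pooled variance, log-likelihood monotonicity asserted in
tests). K defaults to 4 — roughly flight, surface rest, underwater
swimming, and pursuit — and is configurable; no published value fixes it.

The pursuit/catching component is the one whose assigned within-dive
windows have the highest mean VeDBA, a direct operationalization of "fast
and sharp" underwater movement; ties break toward higher VeDBA variance.
Maximal runs of that label, merged across sub-window gaps, clipped to dive
boundaries and filtered at 0.2 s (5 samples), become PCE. The per-dive
count and the per-bout total event time (PCT) are the two model responses;
bout PCT equals the sum of its dives' event time by construction, and the
tests assert this conservation exactly.

## Habitat classification

Each dive is located at the regularized GPS fix (100 s lattice, linear
interpolation, earlier-fix tie-breaking) nearest its start, matched to the
nearest bathymetry cell (no bilinear interpolation — smoothing across shelf
breaks would blur exactly the benthic/pelagic contrast), and classed
benthic when its maximum depth comes within 10 m of the charted seafloor.
A dive deeper than the chart is classed benthic with a logged warning: the
bird demonstrably reached bottom, so the chart is wrong. No-data cells
leave the class unknown, excluded from class-specific models.

## GAM engine

The engine is written in-house around three penalized term types:

* **Cubic regression splines** in the knot-value parameterization: the
  coefficients are the spline's values at k knots placed at quantiles of
  the covariate, and the penalty is the exact integrated squared second
  derivative (null space: straight lines). Evaluation at the knots
  reproduces the interpolating natural cubic spline (asserted against
  `scipy.interpolate.CubicSpline`), and evaluation beyond the boundary
  knots extends linearly.
* **Anisotropic tensor smooths**: row-wise Kronecker products of marginal
  bases with one marginal roughness penalty — and one smoothing parameter —
  per covariate, appropriate when the margins are on different scales
  (seconds and metres).
* **Random effects as penalized terms**: indicator columns with an identity
  (ridge) penalty; the smoothing parameter is the inverse variance
  component times the dispersion. Unseen levels predict at zero effect.

Every smooth absorbs a sum-to-zero constraint over the training rows;
`by`-factor smooths replicate the constrained basis per level
(individual- or class-specific smooths) with smoothing parameters shared
across levels — a deliberate simplification that keeps the outer
optimization low-dimensional.

**Fitting.** For fixed smoothing parameters, coefficients minimize the
penalized deviance by iteratively reweighted least squares with step
halving (the penalized deviance is non-increasing; asserted). Smoothing
parameters maximize a Laplace approximation to the marginal likelihood in
which penalties act as improper Gaussian priors ("ML" selection). The
outer optimizer is Nelder-Mead on log smoothing parameters from a unit
start with an explicit wide initial simplex; penalties are rescaled to the
magnitude of their design block so the search box covers both the
unpenalized and the fully smoothed limits. The dispersion is profiled:
closed form for Gaussian, a bounded 1-D profile for Tweedie, fixed at 1
for Poisson.

**Families.** Poisson (log) for per-dive PCE counts; Tweedie with power
p = 1.05 (log link) for PCT — the compound Poisson-gamma with positive
mass at zero, the reason the family fits a non-negative duration response —
with the log-density evaluated exactly by the series expansion over the
latent Poisson count (checked against the closed-form zero mass, unit
total mass by quadrature, and the scaled-Poisson limit as p -> 1 measured
as binned probability mass, since the limiting distribution concentrates
on atoms where pointwise densities diverge); and Gaussian (identity) for
the log-log bout model.

**Reported statistics.** Effective degrees of freedom are the trace of
the influence matrix; AIC is `-2 loglik + 2 (edf + #dispersion
parameters)`, with the Gaussian log-likelihood reported at the ML
dispersion so the unpenalized linear model reproduces the classical AIC
exactly. Adjusted R-squared uses response-scale residuals with edf in the
denominator. Numeric agreement with any particular GAM package's AIC is
not claimed, but fitted curves and surfaces were cross-checked against R
`mgcv` (method = "ML", same bases) and agree to a fraction of a percent;
one such cross-check runs in the test suite. Prediction intervals are
symmetric on the link scale (±1.96 SE from the coefficient covariance),
transformed to the response scale; covariates outside the training hull
are flagged as extrapolated.

## The model suite

Dive level (Poisson, animal ID fixed, bout ID random): for a pelagic-only
species, six candidate structures — individual-specific or species-level
smooths of dive duration and maximum depth entering additively, as a
tensor interaction, or both, basis dimension 5. For a benthic/pelagic
species, three class-specific structures with a class-specific linear
bathymetry slope, basis dimension 3 for isotropic smooths and 5 for the
tensor. Candidates are ranked by AIC; structures within 2 AIC units of
the best are treated as equally supported and the one with fewest
effective degrees of freedom is selected (the "simpler structure on
near-ties" rule, generalized from the narrative selection the study
applies).

Bout level: PCT against time underwater as a Tweedie (p = 1.05) GAM with
individual-specific k = 3 smooths (zeros allowed — the family's point mass
at zero is why it is used), or a Gaussian model of log PCT on a smooth of
log time (zeros excluded with a logged count). Individuals with fewer
than 5 bouts are dropped with a warning. Each individual gets a
prediction curve with a 95% interval and a plateau summary: the curve
maximum, the residence time at which it is reached, and whether the curve
rises monotonically up to it.

Species comparison: ordinary least squares of log PCT on log time
underwater plus a species indicator (via statsmodels); the species
coefficient is the log ratio of capture time per unit residence time.

## Synthetic data: what it emulates and what it does not

The generator produces bout-structured trips with a shared clock: 1 Hz
trapezoidal dive profiles (constant 1.5 m/s descent/ascent, flat bottom;
dive starts and ends on integer seconds with every in-dive sample above
the wet threshold, so segmentation recovers the true structure exactly —
a constructive guarantee, not an approximation), 25 Hz acceleration with
four movement regimes (flight flapping 8 Hz/0.4 g between bouts, surface
rest 0.05 g within-bout, swim strokes 3 Hz/0.25 g in dives, and broadband
PCE bursts at a configurable amplitude ratio, default 4, over 0.1 g
noise), GPS fixes on the 100 s lattice, and a smooth synthetic bathymetry
field at 1/8 arc-minute resolution (~230 m) supporting both dive classes.

Per-dive PCE counts are Poisson with log-mean `eta(duration, depth) -
depletion_rate * cumulative bout underwater time`. The default rate
surface is peaked — a Gaussian product ridge centered at 30 s dives in the
top 10 m over a weak additive trend, mirroring the reported shallow
short-dive capture peak for the pelagic species — giving ~2.5 expected
events at the peak and ~0.6 away from it. Event intervals are placed without
overlap inside the dive (edge margin 1.5 s, minimum separation 2 s), so a
very short dive physically caps how many multi-second captures fit; the
Poisson count property therefore holds exactly where dive duration leaves
placement unconstrained. The within-bout depletion term
(default 0.0015 s^-1 for the shallow-pelagic profile, 0 for the mixed
profile) makes expected bout gain saturate mechanistically, keeping
dive-level and bout-level truths mutually consistent rather than sampling
PCT directly. The nominal saturating gain `a*t/(b+t)` (defaults a = 300 s,
b = 500 s) is also available directly through the bout-level generators
used in the recovery studies, with Gamma noise (shape 10, CV ~0.32) and
residence times spanning 100-4500 s as in the field data's bout range.

Deliberately not emulated: realistic flight dynamics or biomechanics
(only regime separability matters for testing the EM step), temperature,
tides or currents, GPS error, sensor drift (available separately in the
drift-correction tests), and posture changes during dives. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
statistical form; they do not validate behavior on tag artifacts absent
from the generator (e.g. burst amplitude overlap between swimming styles).
The distribution of dives per bout and bouts per trip is not published;
both are exposed parameters (defaults 20 and 10) without any claim of
fidelity.

## Simulation scales and evaluation choices

Recovery studies run at desk scale: surface recovery at n = 2000 dives
with the estimated log-rate compared to truth on a 20x20 grid spanning
the 1st-99th percentile covariate box (the min-max box includes empty
corners no method can recover; R mgcv scores identically there);
structure selection at n = 1500 over 100 replicates, counting a win
whenever an interaction-containing structure outranks the pure-additive
one; gain recovery at 150 bouts; species-contrast calibration over 200
null replicates at 100 bouts per species. The bout-curve plateau is the
maximum of the fitted curve over the observed residence-time range: with
a k = 3 natural-cubic smooth the fitted curve systematically dips just
past its plateau (mgcv produces the identical curve), so "saturating" is
asserted as a monotone rise to an interior plateau within 15% of the true
asymptote, and "no plateau" as a curve still rising at the end of the
observed range.

## Known limitations

* Smoothing parameters are shared across `by`-levels; fully
  level-specific smoothing would need one parameter per level.
* Smooth-term p-values are not reported; the engine exposes AIC, edf,
  adjusted R-squared and intervals instead (approximate Wald tests on
  penalized coefficients are possible but were deliberately left out).
* No REML, GCV, or autocorrelation structures; bouts are treated as
  serially independent.
* The Tweedie power p is fixed (default 1.05), not estimated.
* Bathymetry IO covers ESRI ASCII grids and minimally geo-referenced
  GeoTIFFs (square pixels, single band); no datum transformations.
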