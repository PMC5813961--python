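# Methods

This note documents the models and procedures flywaykit implements, the
choices made where the design was genuinely open, and what the synthetic
fixtures can and cannot demonstrate about real data.

## Coordinate system and analysis windows

All geometry is done in the North America Equidistant Conic projection on
the NAD83 datum (GRS80 ellipsoid).  The projection parameters are the
common continental parameterization — standard parallels 20°N/60°N,
central meridian 96°W, latitude of origin 40°N — and are configurable via
a proj-style string (`+proj=eqdc ...`).  The equidistant conic is used
because it preserves true distance along every meridian, so "window height
in kilometers" along the south–north axis is exact; the forward/inverse
maps are the classical ellipsoidal series (meridian-arc expansion, inverse
by rectifying latitude plus two Newton steps; round-trip error is below
10⁻⁶ degrees).  Corridor results are mildly sensitive to the parallels
chosen; the defaults are the published continental ones.

Analysis windows are `W` contiguous half-open slabs of equal height,
lower-inclusive, window 1 southernmost, anchored flush at the minimum
northing of the combined data with `W = ceil(span/height)`.  The single
point sitting exactly on the grid's outermost top boundary is assigned to
the last window (otherwise the very datum that defines the grid span would
be flagged out-of-grid); every other out-of-grid point is flagged, never
silently dropped.

## Screening and track quality control

Sighting screening retains confirmed records only and removes Canadian
records dated 25 May–20 August inclusive (sedentary season; "between" was
read as inclusive of both endpoints).  All inequalities in the telemetry
filters are strict in the direction stated for them: flight is velocity
> 2.6 m/s (2.6 exactly is ground; a missing velocity classifies as ground,
because a misclassified ground fix joins a stopover cluster rather than
being discarded); the displacement filter rejects > 100 km/h; the spike
filter rejects turn angles < 5° when both legs exceed 50 km.

The three telemetry rules run as one forward pass per bird against the
last *retained* fix: out-of-order timestamps drop the later fix, the speed
rule drops the later fix of the offending pair and re-evaluates from the
last retained fix, and after each acceptance the trailing retained triple
is checked for an angular spike repeatedly until stable.  Because the
speed rule is enforced against retained fixes, removing a spike can never
create a new speed violation (triangle inequality), and the whole pass is
idempotent — re-running QC on its own output changes nothing.  Every
rejected fix appears exactly once in the rejection log with a
machine-readable reason.

Stopover clustering is sequential chaining: a new site starts when the
move between consecutive ground fixes exceeds 15 km.  Whether the 15-km
rule should bound consecutive moves or cluster diameter was ambiguous; the
chaining reading was adopted, and the test suite pins the observable
consequence (five fixes 10 km apart spanning 40 km form one site).
Interactive inspection steps in the original field protocol are replaced
by this deterministic pass; migration-period delineation is expected to be
done upstream (explicit date ranges), not inferred.

## Corridor estimation

Within each window the west/east corridor edges at core level L are the
(100−L)/2 and 100−(100−L)/2 percentiles of the eastings, computed with
linear interpolation between closest order statistics (numpy's default
definition; configurable, since edge positions shift by O(1/n) between
percentile definitions).  Dataset-specific edges are combined as averages
weighted by per-window sample sizes; a window empty in one dataset defers
to the other; a window empty in both is flagged missing — interior missing
windows are linearly interpolated from their neighbours, terminal missing
windows truncate the corridor.

Polygon vertices sit at window vertical midpoints, with the terminal
windows squared off to the grid's outer boundaries.  A zero-width window
(degenerate single-x data) is opened by one millimetre so the ring stays
simple.  Confidence bands bootstrap both datasets independently at their
original sizes (1,000 resamples by default), recompute combined edges per
replicate, and take the 2.5th/97.5th percentiles per edge; resampling is
of individual locations, which understates uncertainty for autocorrelated
telemetry (see limitations).

Window-height selection evaluates candidate heights (50–700 km by 50) on
two axes: data fit, the mean over bootstrap replicates of the fraction of
all original locations inside the replicate corridor, required to reach
0.95; and shape complexity, the patch fractal dimension
`2·ln(0.25 P)/ln(A)` (P, A in meters) of the point-estimate polygon, which
is exactly 1 for squares and grows with boundary crenellation.  Among
passing candidates the minimum-index height wins; ties go to the smaller
height.  The containment rule during fitting ("averaged over replicates")
was one of several defensible readings of an ambiguous criterion and is
recorded as such.

## Trend models

The positional model is a cell-means Gaussian linear model: per-window
intercept and per-window year slope (2W coefficients), one shared error
variance.  Slopes are reported in km/year; year offsets are anchored at
1942.  Internally the year covariate is centered at the mean stage-1
observation year.  This matters: the two-stage scheme transfers only the
*marginal* posterior mean and variance of each coefficient as an
independent normal prior, and in an uncentered parameterization the
intercept and slope posteriors are correlated at about −0.95, so marginal
transfer lets the narrow-span telemetry data (2010–2016) falsely sharpen
the slope posterior — a stationary scenario then yields ~18% false slope
detections instead of ~5%.  Centering makes the transferred marginals an
essentially faithful summary of the stage-1 posterior while leaving
slopes, fitted values and year predictions mathematically unchanged; only
the intercept's reference time moves.

Gibbs sampling uses the conjugate updates: coefficients given the variance
are multivariate normal (with flat priors the conditional mean is the
least-squares estimate, so the sampler is exact around OLS), and the
variance given coefficients is inverse-gamma with the vague (0.001, 0.001)
prior in both stages.  Only coefficient priors transfer between stages — a
normal prior cannot describe a variance, so each stage gets its own vague
variance prior.  Defaults are 2,000 burn-in and 10,000 kept draws; chains
are never auto-extended (reproducibility over adaptivity), and a
split-chain scale-reduction diagnostic is available on the results object.
Windows need at least two distinct observation years per stage to
contribute; a window present only in stage 2 falls back to a flat prior
with a warning.

Corridor-width change is measured against the per-window median of the
combined datasets over all years (the long-term centerline).  Offsets are
east-positive; an offset of exactly zero is assigned to the east side.
Three responses are modelled with the same two-stage machinery: |offset|
for all locations (negative slope = narrowing), and the signed offset
separately for west-side and east-side locations (positive west slope =
movement toward the median).  Because side labels come from the empirical
centerline, subset slopes carry a small selection-effect bias (measured
below 0.05 km/yr at the default conditions).  Predictions for 1980 and
2014 are posterior-mean point estimates `α_w + β_w (t − t_ref)`; years
outside 1942–2016 warn as extrapolation.

## Synthetic flyway generator

The generator emulates the statistical structure the analyses assume: a
3,900-km flyway split into 13 windows of 300 km; a gently west-bending
centerline; locations falling west or east of it with probability ½ at a
half-normal distance whose *mean* s varies by window and declines linearly
in time at a side-specific contraction rate.  Parameterizing the
half-normal by its mean (σ = s·√(π/2)) makes the contraction rate exactly
the year-slope of the mean signed offset on that side, so all ground-truth
slopes are closed-form: positional slope = drift + (c_west − c_east)/2,
west-side offset slope = +c_west, east-side = −c_east, |offset| slope =
−(c_west + c_east)/2.

Defaults mirror the study system: 5,000 sightings uniform over 1942–2016,
58 telemetered birds over 2010–2016 at 4–5 fixes/day, eastward drift
1.2 km/yr, west-flank contraction 0.9 km/yr with a stable east flank.
Baseline west spreads run 70→125 km south→north — the smallest values for
which a constant 0.9 km/yr contraction keeps every window's spread
positive through 2016; a constant contraction over 74 years cannot match
both 1942 and 2016 corridor widths at once, so realistic widths hold near
the middle of the record.  Telemetry tracks plant stopover centers every
100–400 km with era-appropriate lateral offsets, jitter ground fixes
within 3.5 km of each center, interpolate in-flight fixes between
consecutive stopovers, and use velocity ranges disjoint around 2.6 m/s so
flight classification is exact by construction.  `inject_artifacts` plants
violations of exactly one QC rule each (speed, angular spike, timestamp
swap) with truth labels.  Identical scenario and seed give byte-identical
fixture files.

## Calibration findings and limitations

The verification suite measures, rather than assumes, the calibration of
the two-stage inference under the generator's conditions:

- With independent stage-2 data and a stationary scenario, 95% credible
  intervals cover truth at 0.955 and the null false-detection rate is
  0.045 — the sampler and prior transfer are calibrated.
- With the generator's telemetry tracks, coverage drops to ~0.89 and the
  null detection rate roughly doubles (~0.10).  The cause is dependence
  the Gaussian iid likelihood ignores: all of a bird's stopovers share one
  migration year, and in-flight fixes interpolate between adjacent
  stopovers, so the telemetry stage overstates its information content.
  The effect is scale-invariant (unchanged from 10 to 58 birds) because it
  is set by the within-track dependence structure, not the number of
  tracks.
- The default scenario's constant contraction makes residual variance
  fall over time; this heteroscedasticity costs a further ~2 percentage
  points of coverage in the positional model.

These are properties of the method applied to data with this structure —
the same caveats apply to real telemetry, where locations within a bird
are autocorrelated and the bootstrap and likelihood both treat them as
independent.  The synthetic fixtures share the real data's corridor
geometry, sampling cadence and filter-relevant failure modes, but not
observation biases of opportunistic sighting effort (population density,
roads, towns), measurement error in reported positions, or
behaviorally-driven stopover site fidelity; passing tests demonstrate
correctness of the computations and calibration under the stated
generative assumptions, not unbiasedness on real-world sampling.

Problem sizes used in the automated suite (chosen to exercise each
property at sufficient precision): geometry and quantile oracles at up to
10⁶ Monte-Carlo points and 1,000 random vectors; Gibbs-vs-OLS on 50 random
designs; 200 end-to-end replicates (1,500 sightings, 10 birds, 500/2,000
chains) for coverage; 500 replicates at n = 500 per window and dataset
with 1,000 bootstrap resamples for band calibration; 80 stationary
replicates for the null detection rate.
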