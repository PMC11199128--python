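# Methods

This note records the models, numerical choices and assumptions behind
`gullcast`, and what the synthetic experiments do and do not demonstrate.

## Gridded fields and interpolation

All meteorological inputs are regular lat–lon rasters (`GridField`):
latitudes ascending in degrees north, longitudes in [0, 360) degrees east,
cell-center registration, UTC times. Sea-level pressure is validated
against physical bounds (870–1090 hPa) and ice fraction against [0, 1].
Point queries use bilinear interpolation in space followed by linear
interpolation in time; the scheme is exact for any field affine in
latitude, longitude and time, which the tests verify at machine precision.
There is deliberately **no extrapolation**: queries outside the grid hull
or the time range raise, so a trajectory that leaves the wind domain is
detected rather than silently clamped.

"Daily" SLP patterns are the arithmetic mean of all sub-daily snapshots in
the UTC calendar day. Reanalyses distribute sub-daily fields and do not
define a canonical daily pattern; the mean is the standard convention and
is isolated in one function (`daily_mean`) so a fixed-hour-snapshot
convention can be substituted.

NetCDF I/O goes through xarray's scipy backend (classic NetCDF format),
with CF-style coordinate names auto-detected, descending latitude axes
reordered and longitudes normalized on read.

## Method A: SOM pattern classification

The classifier is a 4×4 Kohonen lattice (16 nodes, numbered row-major
#001–#016) over flattened daily SLP rasters in raw hPa — no anomaly
removal, no standardization, no area weighting of grid cells (each is
available behind the API but off by default, since the plain-pattern
Euclidean distance is the convention being reproduced).

Training is the **batch** algorithm: per epoch every input is assigned to
its best-matching unit (BMU, minimum Euclidean distance; ties to the lowest
node id), and every codebook vector is recomputed as the Gaussian-
neighborhood-weighted mean of all inputs, with the lattice neighborhood
radius shrinking linearly from `max(rows, cols)/2` to 0.5 over the
configured epochs (default 100, early stop when the mean quantization error
changes by <1e-6). The codebook is initialized on the plane of the first
two principal components, with component signs fixed deterministically, so
retraining the same inputs reproduces the same model bit-for-bit — a
property an operational forecast product needs and that online/random-init
SOMs lack.

Node sighting probabilities are plain empirical fractions
`n_sighted / n_days` over effort-filtered observation days. Two counting
identities hold exactly and are enforced in tests: node denominators sum to
the number of classified days, and the denominator-weighted mean node
probability equals the overall sighting rate. A node with zero observation
days is *missing*, never 0%: 0/0 carries no evidence, and a forecast
landing there reports missing with the node id.

## Method B: backward trajectory and occurrence GLM

The trajectory integrator is first-order backward Euler with 1-hour steps:
`p(t−Δt) = p(t) − V(p(t), t)·Δt`, wind interpolated linearly in space and
time, no vertical motion (the species flies near the surface). Meter
displacements convert to degrees with `Δlat = d/(R·π/180)` and
`Δlon = d/(R·π/180·cos φ)`, R = 6371 km. Under constant wind the scheme is
exact and matches the closed-form displacement (10 m/s meridional wind over
24 h moves the parcel 7.770°, i.e. Lat24 = 52.77°N for northerly flow from
45°N); under smooth rotational flow the endpoint error halves when the step
halves (first-order), and a 24-h backtrack in solid-body rotation conserves
the radius to ≈0.3%. No Petterssen-style corrector is used — the hourly
step matches the method being reproduced and the convergence test bounds
the cost of that choice. A parcel that exits the wind grid is frozen at the
boundary and flagged (`left_domain`), so rare fast-flow days still yield
covariates with an audit trail, rather than erroring.

Bearings of the lagged parcel position are planar with cos-latitude scaling
(`atan2(Δx, Δy)`, degrees clockwise from north in [0, 360)), taken from the
arrival point toward the parcel; at a few hundred kilometers the difference
from great-circle initial bearing is negligible. The opposite convention is
a parameter away. The arrival instant for historical covariates is 00 UTC
of the observation date.

The occurrence model is a binomial GLM fitted by IRLS (statsmodels) on
z-scored covariates, convergence tolerance 1e-10; `k` counts coefficients
including the intercept and `AIC = −2·logLik + 2k` holds as an exact
identity on every fitted model. Scaling constants come from the training
set only and are frozen into the model artifact; forecast inputs (including
the fixed 60-minute duration) are standardized with those constants.
Perfect separation yields a flagged non-converged model; a singular design
raises naming the collinear terms. An independent Nelder–Mead likelihood
maximization reproduces the IRLS coefficients to 1e-4 in the tests.

Model building is two-stage: (1) within each three-member family — ice
extents {whole, north, south of 51°N}, parcel latitudes {24, 48, 72 h},
parcel bearings {24, 48, 72 h} — fit member + duration and keep the
lowest-AIC member (ties to family order); (2) enumerate all 32 subsets of
{ordinal date, ice winner, latitude winner, bearing winner, duration}, rank
by AIC, and report Δ-AIC from the best. The ordinal date counts from
November 1 = 1 continuously through the winter. Duration is a free
candidate, not forced into every model.

## Sighting records and de-duplication

A wandering individual can linger, so presence days at one site are chained
into periods whenever successive presence days are ≤2 calendar days apart
(consecutive days or a one-day gap); each period keeps only the earliest
day attaining its maximum count. Absence days within ±2 days (two-sided) of
*any original* presence day at the same site are dropped — the conservative
reading, since a nearby sighting means the bird may still have been
present — and the surviving absences, chained at ≤2-day spacing, keep only
the first day of each chain. Sites are processed independently. The
pipeline is idempotent, and on random fixtures it agrees exactly with an
independent pairwise-transitive-closure reimplementation. The effort filter
keeps days watched ≥45 minutes (a 45-minute day is kept). Both gap
thresholds and the window months (November–February) are parameters.

## Sea-ice covariates

"Extent" is the cos-latitude-area-weighted mean ice fraction over a basin
mask, reported for the whole mask and its halves north/south of 51°N (a
cell centered exactly on the split counts as north). The default mask is a
rectangular Sea-of-Okhotsk proxy (44–62°N, 135–157°E) intersected with the
ice product's ocean cells; a user-supplied mask should replace it when
geographic fidelity matters. A thresholded convention (area fraction with
concentration ≥15%) is available since "proportion of ice surface" admits
both readings; the mean-fraction default is documented as such.

## Synthetic data: what it emulates, and what it does not

The generator produces a dynamically coherent winter: a Poisson storm track
of Gaussian lows born west/southwest of the domain (amplitude −18 to −45
hPa, σ 500–900 km, lifetime 3–6 days with a sinusoidal deepen/fill
envelope, drifting east-northeast at 500–1100 km/day), superposed on a
1013 hPa background with spatially smooth AR(1) pressure noise (day-to-day
persistence 0.7, sd 1.5 hPa). Stacked anomalies pass through a soft tanh
saturation (110 hPa scale) so random coincidences of deep lows stay within
physical pressure bounds. Winds follow geostrophic balance
`u = −(1/ρf)∂p/∂y, v = (1/ρf)∂p/∂x` (f = 2Ω sin φ, centered differences,
speeds capped at 40 m/s as a crude surface-drag stand-in); this gives the
pattern–wind covariance the forecast systems rely on, not forecast-grade
physics. The ice edge combines a weak seasonal ramp (≈62°N early season to
≈52°N late) with a persistent AR(1) wander of ~2°, so ice extent correlates
with, but is not a deterministic function of, the calendar — keeping the
ice and date covariates statistically separable. Sighting records draw
presence from a logistic truth on z-scored Lat24, ordinal date and duration
with default coefficients (−2.38, 1.74, 0.48, 0.59) matching the fitted
real-data model's effect sizes; presence-day counts follow a zero-truncated
negative binomial whose *truncated* moments are mean 35 / sd 64 (solved
size 0.0947, mean 13.065 — naive parameterization overshoots by ~30%).
Durations are normal (mean 77.5, sd 65.8 minutes) floored at 15.

Not emulated: realistic storm-track climatology, ageostrophic/boundary-
layer winds, ice dynamics, observer heterogeneity, inter-annual abundance
variation. Passing synthetic tests therefore demonstrates that the
*pipeline* recovers known structure under the stated signal strengths; it
says nothing about real-data forecast skill.

## Synthetic experiment scales

Chosen once as scaled-down analogues of the real training record (5748
pattern days, 104 observation days, but with the signal strengths above):

* coefficient recovery: 2000 observation days, one fixed seed, each
  coefficient within ±0.15 of truth (Fisher-information scale ≈ 2×SE);
* AIC term selection: 20 sighting redraws over one fixed 2000-day season;
  the AIC-best model contains every true term in ≥90% of redraws. The
  *exact* term set is recovered less often by construction — AIC admits a
  spurious extra term with probability ≈ P(χ²₁ > 2) ≈ 0.16 per noise
  family — and that rate is reported, not asserted;
* end-to-end concordance: both systems trained on a 1502-day season with
  1000 observation days (≈60 days per node, keeping node probabilities
  signal- rather than sampling-noise-dominated); 50 paired scenarios
  compare a developed low in the Kuril/Kamchatka sector east of the site
  (center 45–51°N, 155–162°E, −30 to −50 hPa, σ 600–800 km, placed so the
  site sits in the low's northerly western flank) against a calm day with
  identical noise; both methods must rank the low day higher in ≥90% of
  pairs.

A complementary regression scenario reproduces the known failure mode of
pattern classification: a shallow small-scale low (−15 hPa, σ 300 km) near
the site leaves the basin-scale pattern — and hence Method A's node —
unchanged while reversing the local flow that drives Lat24, decoupling the
two methods. This is why the report keeps them side by side.

## Numerical conventions and edge cases

* BMU ties break to the lowest node id; family-screening AIC ties keep the
  earlier family member; subset-selection ties rank the smaller model first.
* Flattening of a pattern raster is row-major (latitude varies slowest) and
  has an exact inverse.
* Coincident points in the bearing computation return 0.0 with a degenerate
  flag.
* Counts and probabilities are reported missing (None/NaN), never silently
  zero, whenever the defining denominator is empty or input coverage is
  absent; every such decision is logged.
* All generators accept a seed and are bit-reproducible under it; seeds are
  combined through `numpy.random.SeedSequence`.

## Known limitations

* The SOM hyperparameters (epochs, neighborhood schedule) are reasonable
  defaults, not a replication of any particular trained lattice; node
  identities on real data will differ between trainings of different
  records.
* Geostrophic synthetic winds over-rotate around shallow lows at low
  latitudes and ignore friction-induced cross-isobar flow; trajectory
  covariates on real winds will differ quantitatively.
* The rectangular ice mask is a proxy; basin-accurate extents need a
  user-supplied mask.
* Backward Euler is first-order; sub-hourly steps or a corrector would
  reduce trajectory error under strongly curved flow.
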