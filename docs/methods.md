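# Methods

This note documents the models, parameter choices and numerical decisions
behind each module, what the synthetic generator does and does not
emulate, and the known limitations.

## Solar model

Declination and the equation of time use the NOAA truncated Fourier
series in the fractional year; elevation comes from the standard
hour-angle formula without atmospheric refraction. Accuracy (a few
hundredths of a degree in declination, < 0.5 min in the equation of time)
is two orders of magnitude below threshold-geolocation error, and the same
formulas serve the forward simulator and the estimator, so shared
systematic terms cancel in round trips. Tests check the formulas against
dense-grid evaluation and almanac values rather than against the
estimator. Equinox dates are found as declination zero-crossings, not
hard-coded.

## Synthetic data generator

The generator is first-class, tested code: it defines the study
conditions under which everything downstream is validated.

**Annual cycle.** One bird-year per schedule: colony attendance from
January, population-specific laying (day-of-year means 60/77/84 ± 5 d for
the Mallorca, Menorca and Yelkouan-system colonies — the western colony
breeding a couple of weeks earlier, as observed in this system), 50 d
incubation in alternating 2–4 d pair shifts (male first), chick rearing
with nocturnal provisioning every 1–3 nights, migration departure ≈ 55 d
after hatching, return around day-of-year 268–283. Females take a 12-d
pre-laying exodus ending the night the egg is laid; both sexes make
isolated single-day prospecting cave visits in the three weeks before
laying (never two consecutive days, so they cannot mimic an incubation
shift). Ground truth records the exact colony-night and cave-day sets
plus the five annual-cycle dates the pipeline must recover.

**Regions.** Non-breeding destinations are drawn from an Atlantic box
(38–47°N, 12–2°W) or a Mediterranean box (36–43°N, 0–10°E); Yelkouan
birds may instead use a far-eastern Mediterranean-system box (no strait
routing is modelled). Default mixtures: Mallorca P(Atlantic) = 0.85,
Menorca P(Mediterranean) = 0.80, Yelkouan P(Mediterranean) = 1. Transit
legs cap daily displacement at 500 km (< the 600 km/day continuity
invariant); residency is an AR(1) wander around the drawn centroid.

**Light.** Light is a clipped piecewise-linear map of solar elevation,
anchored so that light = threshold (10 of 64) at exactly the device's true
sun elevation angle, reaching 0 at EA−2° and 64 at EA+2°. Anchoring the
threshold at EA is what makes EA a meaningful calibration constant; a ramp
not passing through (EA, threshold) would bias every twilight by a fixed
elevation offset that calibration would then absorb. Twilight noise is a
Gaussian time jitter per twilight (default SD 2 min); shading events
(default 0.2/day, 20–40 min) force daytime light to zero; cave days are
fully dark. The default cadence is 2 min — finer than the 10-min archival
cadence of the classic loggers but matching their internal 1-min sampling —
chosen so that linear-interpolation error at the twilight crossings
(< ~1 min) stays subordinate to geolocation error. Light values are kept
continuous (un-quantised) "arbitrary units".

**Immersion.** Wet counts per 10-min block of 200 samples: 0 in colony
states, ≥ 0.8·max when rafting, Binomial with p ∈ (0.25, 0.7) (floored at
1) when foraging, and mostly-dry transit with a forced water rest at least
every 4th block so a transit night can never contain a 2-h dry run and
masquerade as a colony visit. Colony "night" uses sun elevation −6° at
the colony — the same convention the detector uses, which is what makes
exact-recovery tests meaningful.

**Isotopes.** Per-(population, feather, year) cells reproduce the
published colony means/SDs exactly. Cohorts that mix non-breeding regions
draw instead from region-conditional cells: Atlantic = the Mallorca P6
cell (that colony is essentially all-Atlantic), Mediterranean P1 = the
French (pure-Mediterranean) cell, and Mediterranean P6 = (11.1 ± 0.9‰,
−17.4 ± 0.4‰), a mixture deconvolution of the Menorca colony cell chosen
so the implied two-group separation reproduces the published training
Wilks' Λ ≈ 0.22 (a colony cell cannot be used directly for a
region-conditional draw, because the Menorca colony is itself an ~80/20
regional mixture). δ¹⁵N–δ¹³C correlation defaults to 0 and is
configurable.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: oceanographic habitat structure, weather-driven
shading statistics, sensor drift and clock error, logger failure modes,
breeding failure (every simulated pair completes incubation), and
behavioural state budgets at sea (dwell times are free parameters, not
estimates of real birds).

## Geolocation

Twilight crossings are linearly interpolated between samples. Dark
periods < 4 h and light periods < 1 h are flagged (`short_dark`,
`interference`) and removed from pairing; each remaining day yields a noon
pair (sunrise→sunset) and a midnight pair (sunset→next sunrise), i.e. two
fixes per day, dated by the pair midpoint's civil date. Longitude uses
the NOAA sign convention (solar noon in UTC minutes = 720 − 4·lon − EoT).
The latitude equation is solved in closed form (a·sin φ + b·cos φ = c);
when both quadrant solutions are admissible the hemisphere is chosen by
comparing the observed day length with the equatorial day length for that
EA and declination, then the smaller |φ|.

Latitude is reported missing, with a flag, when the equation has no
solution (polar day/night at that EA) or when |declination| < 0.5°. The
declination criterion is the operative equinox-degeneracy test: with a
negative EA the day length at the equinox is > 12 h at every latitude, so
a "day length ≈ 12 h" test would never fire on the equinox itself, while
|δ| → 0 is exactly the regime where ∂(day length)/∂φ → 0.

Calibration scores each candidate EA by the median great-circle distance
of usable window fixes to the colony; ties break by fewer on-land fixes
(against an optional shapely polygon) and then by proximity to −3.5°, the
centre of the plausible range for these loggers. The speed filter is a
single forward pass against the last retained fix (an iterative
back-and-forth filter was deliberately not used: flagging is then
order-independent and idempotent). Equinox windows take the "winter side"
as the side toward the winter solstice — before the March equinox, after
the September one — where latitude error grows fastest. Filters
accumulate in a provenance set per fix; `manual` flags survive
refiltering.

## Phenology

Detection thresholds are expressed in time, not blocks: the ≥ 2-h dryness
run is rescaled to the trace's actual block length, making detection
invariant to block refinement. The non-breeding period is delimited by
the longest gap between night visits, guarded by `min_migration_days = 30`
so a mid-season absence cannot qualify; an exact tie between two maximal
gaps is an error rather than an arbitrary choice. For the female laying
rule, "colony visit" accepts night or day visits, and the exodus is
searched up to the first multi-day day-visit run so neither isolated
prospecting visits nor the migration gap can be mistaken for the exodus;
with ties, the latest maximal gap wins (the exodus immediately precedes
laying). The pair rule looks for the first pair of abutting, non-
overlapping multi-day day-visit runs, one per partner, and falls back to
the sex rules. Return-date imputation uses the cohort median over
day-of-year with the earlier central value at even n, for determinism.
The hatching proxy is simply the last day visit; no correction for
post-hatch brooding is attempted.

## Space use

The projection is the spherical Lambert conformal conic (standard
parallels 33°N/45°N, central meridian 5°E, origin 39°N; Earth radius
6371.0088 km), implemented directly from the standard forward/inverse
formulas and verified by metre-level round trips and a geodesic oracle.

The bandwidth selector is the 2-stage unconstrained multivariate plug-in:
pre-sphere with the sample covariance; take the 6th-order integrated
density-derivative functionals from the normal reference; use them in the
asymptotic-MSE pilot formula for kernel estimation of the five 4th-order
functionals (the odd multi-indices (3,1)/(1,3), whose AMSE constant
vanishes, reuse the (2,2) pilot); minimise the resulting AMISE criterion
over symmetric positive-definite matrices via a log-Cholesky
parametrisation (Nelder–Mead, started at the normal-reference matrix
n^(−1/3)·I); back-transform. Pairwise functional sums are O(n²) and use a
deterministic stride subsample above n = 4000. Degenerate scatter or a
failed optimisation falls back to the normal-reference matrix with a
warning. The selector is validated against the Gaussian reference (it
lands within a few % of n^(−1/3)·Σ on Gaussian data), by covariance
equivariance, and by n-monotonicity.

Densities are computed by linear binning to cell centres plus FFT
convolution with the kernel sampled out to 5 SDs; the grid pads the data
bounding box by 4 marginal kernel SDs (3 would lose ≈ 0.5% of an
edge-point's kernel mass and break the Σ = 1 ± 10⁻³ normalization
invariant). No renormalisation is applied — the reported mass is the
honest discrete integral. The level-p contour is the smallest set of
cells by descending density whose mass reaches p/100 (deterministic
flat-index tie-break), which makes nesting structural; polygons are traced
at the resulting density threshold. Pooled (population) densities weight
birds equally by default; per-fix weighting is available via the
`weights` argument. Grids write as ESRI ASCII, contours as GeoJSON
(optionally unprojected to lon/lat).

## Isotopes

Lipid normalization applies only at C:N strictly above 3.15, through a
registry (`post2007`, the linear aquatic-tissue equation, is the default;
`kiljunen2006` is the non-linear fish-muscle alternative) whose equation
id should be recorded with outputs. Trophic discrimination defaults to
+3.7‰ δ¹⁵N and +1.9‰ δ¹³C, diet → feather.

The discriminant is fitted from first principles (group means, pooled
within-group covariance S_W): Fisher functions S_W⁻¹μ_g with constant
−½μ_g'S_W⁻¹μ_g + log prior; the canonical function is scaled to unit
pooled within-group variance and centred on the midpoint of the group
means, so with the default equal priors its sign rule coincides with the
Fisher argmax (verified as a test invariant). Priors default to equal
because training groups in this problem are typically very unbalanced and
the assignment question is about the bird, not the sampling design;
proportional priors can be passed explicitly. Wilks' Λ = 1/(1+λ₁) is
emitted with both Rao's F ((1−Λ)/Λ·(n−3)/2 on (2, n−3) df) and Bartlett's
χ² (−(n−3)·ln Λ on 2 df) approximations, since reports in this field mix
the two conventions. Exact Fisher-score ties are returned unassigned with
a flag rather than broken arbitrarily. The published P1/P6 coefficient
sets are evaluated exactly as typeset (their training data are not
public); no re-derivation is attempted. scikit-learn's LDA and
statsmodels' MANOVA serve as independent cross-checks in the test suite
only. Ward clustering delegates to scipy's linkage; the test oracle is an
explicit centroid-formula agglomeration. Chick-down reference samples are
context only and are never used for training.

## Pipeline and problem sizes

The pipeline derives one sub-seed per stage from the run seed
(`SeedSequence`), writes plain CSV/JSON between stages, and records
per-stage record counts and SHA-256 hashes in a manifest; identical
configs and seeds reproduce byte-identical outputs. Default problem
sizes were chosen as the smallest that exercise each property cleanly:
the demo pipeline runs 2 birds per colony at a 10-km KDE cell; the
acceptance script uses 50 stationary bird-days, a 30-day calibration
window, 100 bird-years for phenology recovery, 10⁴ points for KDE
calibration, and a 500-bird cohort against 50 training birds per region
for mixture recovery.

## Known limitations

- Latitude near the equinoxes is structurally unidentifiable; the package
  flags rather than repairs it (no template-fit or state-space smoothing).
- The threshold method ignores shading-induced twilight bias in real
  data; calibration absorbs its mean but not its variance.
- Fitted discriminants assume shared within-group covariance; strongly
  unequal group covariances shift the optimal boundary away from the LDA
  boundary (the mixture-recovery margin quantifies the practical effect).
- The spherical projection differs from an ellipsoidal Lambert by ~0.3%
  in scale; irrelevant at geolocation error scales but not for precision
  cartography.
- Immersion-based visit detection assumes a dry burrow; species that
  raft motionless for whole nights would need the dryness threshold
  revisited.
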