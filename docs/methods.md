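# Methods

## Statistics

The package quantifies two features of the synsacral vertebral canal from an
ordered anterior→posterior cross-sectional-area series *A*₁…*A*ₙ (mm²).

**Running mean.** movmean₃ averages each section with its two neighbours;
at the series ends, where the window would leave the series, it averages the
two available sections. This truncated-window rule means every section —
including the endpoints, where the three-point ratio formula is undefined —
yields a dimensionless ratio *R*ₙ = *A*ₙ/movmean₃(*A*)ₙ, algebraically equal
to 3*A*ₙ/(*A*ₙ₋₁+*A*ₙ+*A*ₙ₊₁) on interior sections.

**LSTC prominence** is the sample standard deviation (n−1 denominator,
matching the default of the common statistical environments deposited
analysis code is written in) of the *R*ₙ. **Expansion ratio** is
max movmean₃(*A*) over the mean of the raw first and last areas; we read
"the most anterior cross-sectional area and the most posterior" literally
as raw areas, not running-mean values. Both statistics are invariant under
uniform rescaling of the areas and are therefore body-size-free.

**Analysis window.** The canonical profile is 11 sections: the
maximum-area section plus five on each side. Ties for the maximum are
broken toward the profile midpoint (the expansion peaks near the middle of
the lumbosacral region), then anteriorly; the choice is deterministic and
checked by enumeration in the tests. Profiles whose maximum sits within
five sections of an end cannot host the window and raise an error stating
the deficit. Shorter series (≥ 3 sections) are accepted with a recorded
`short-series` warning so partial specimens remain usable without silently
redefining the protocol.

## Section-area measurement on voxel volumes

For synthetic lumen volumes (binary, isotropic pitch in mm, longitudinal
axis = third index) the per-plane measurement emulates the manual
fill-and-count procedure applied to µ-CT section images: morphological
closing with a disk (default radius 3 voxels) bridges the small boundary
gaps that nerve-root foramina leave, then the connected lumen component
containing a deterministic interior seed (centroid, falling back to the
deepest distance-transform pixel for crescent sections) is flood-filled,
holes included, and its pixel count converted by pitch². A lumen touching
the image border means the fill would escape an open contour and raises an
error naming the plane. Sections are taken orthogonal to the grid axis; the
manual protocol's oblique per-canal alignment has no quantitative
definition, and the phantoms place their recesses orthogonally, so the
simplification loses no information on synthetic data (it would on real
scans — a known limitation).

The closing radius must exceed the notch half-width (phantom notches are 2
voxels wide) without bridging adjacent anatomy; 3 voxels satisfies both at
the default geometry and is configurable.

## Phantom geometry

Ground truth is defined on areas, not radii: the analytic profile is

A(t) = A₀ · (1 + g·exp(−(t−z_c)²/2σ²)) · (1 + d·[canal section]),

with t the fractional position, g the expansion gain, σ the expansion
width, d the recess depth, and canal sections at odd 1-based positions.
g = d = 0 gives a constant profile (prominence 0, expansion ratio 1);
d = 1, g = 0 on unit base area gives the hand-checkable alternating profile
[2,1,2,…,2] with prominence 0.4452.

The voxel builder solves the tube radius from the smooth term,
r(z) = √(A_exp(z)/π), so the circular section matches the analytic area
exactly up to rasterisation. Each canal plane carries a dorsal rectangular
recess slot of width r(z)/2 and height d·A_exp(z)/(r/2) — exact extra area
d·A_exp — prismatic over an axial extent d·canal_spacing centred on the
plane. The narrow slot keeps its junction with the circle under about one
voxel of re-entrant gap, so gap closing cannot measurably inflate the
area. Recess slots reaching the intercanal planes (d approaching 1 at the
given spacing) are rejected as an invalid specification. Optional notches
cut a 2-voxel-deep dorsal bite at intercanal planes to exercise the
gap-closing step; they are measurement artifacts and do not enter the
analytic ground truth.

Defaults (r₀ = 2 mm, pitch 0.1 mm = r₀/20, 5 canals, spacing 1.5 mm) build
and extract in well under a second; at that pitch, per-section extraction
error is ≤ 1.5%, recovered prominence is within 0.01 and expansion ratio
within 2% of the analytic values, and errors shrink monotonically as the
pitch is refined.

**Expansion/prominence coupling.** The running mean only partially shields
the expansion ratio from recess depth: with canal sections at the window
ends, the maximal 3-point mean carries a (1+2d/3) recess factor while the
raw-end denominator carries (1+d), so the expansion ratio falls by exactly
(1+2d/3)/(1+d) − 1 (about −15% from d = 0 to d = 0.8; visible already in
the toy profile, whose expansion ratio is (5/3)/2 = 0.833, not 1). The
shielding is real but relative — a raw-maximum numerator would move
(1+d)-fold — and the residual drift is an intrinsic property of the
statistic on profiles whose recesses persist to the window ends, not a
numerical artifact. The test suite characterises this law rather than
asserting perfect decoupling.

## Synthetic cohorts

`generate_cohort` draws per-species metrics log-normally — metrics are
positive and right-skewed — with defaults
(location −1.915, log-SD 0.337 for prominence; 1.389, 0.283 for expansion)
chosen by moment-matching the published 44-species sample
(prominence 0.156 ± 0.054, expansion 4.17 ± 1.20). The locomotor-group
signal is an additive shift of the prominence log-location for a
`group_fraction` subset (default half of 44 species); expansion carries no
shift, mirroring the published pattern of a prominence trend without an
expansion trend. Specimens within a species scatter with log-SD
`within_log_sd_scale` (default 0.25) times the between-species log-SD, so
conforming cohorts have within-species variance below between-species
variance. Non-group lifestyle flags are independent coin flips. All
randomness sits behind one integer seed.

`cohort_area_tables` converts drawn metrics into actual 11-section analytic
profiles by alternating one-dimensional bisections for (g, d); the match is
exact to ~0.1% except where the smooth bump alone exceeds a small
prominence target, in which case depth clamps at 0. This yields raw area
tables for end-to-end pipeline runs, not just pre-computed metrics.

What the generators do **not** emulate: real profiles' irregular section
spacing and oblique section planes, recess-depth tapering toward the ends
of the lumbosacral region, measurement error in manual boundary tracing,
and phylogenetic autocorrelation of metrics across species. Passing tests
therefore validate the computational pipeline, not these properties of
real data.

## Group comparison

Tests operate at the species level: multi-specimen species are collapsed by
the mean before grouping. The two-sample, two-sided KS statistic D is the
supremum of absolute ECDF differences over the pooled sample, computed
directly (and cross-checked against scipy); the p-value is exact by
enumeration when n₁·n₂ ≤ 10 000 and the pooled sample is tie-free,
otherwise the asymptotic Kolmogorov series with effective size
n₁n₂/(n₁+n₂) — the convention of the statistical environment deposited
analyses use, so p-values are comparable. D itself is method-independent
and is the primary surface; species are not phylogenetically independent,
so p-values are exploratory. No multiple-testing correction is applied (the
published comparisons report four raw tests). The within/between dispersion
check reports the df-weighted pooled within-species variance over the
variance of species means, per metric; < 1 is expected on conforming data
but reported, not enforced.

With the default exchangeable cohorts (22 vs 22 species, exact p), the
measured type-I error at α = 0.05 over 10 000 replicates is ≈ 0.050,
confirming calibration.

## Numerical and I/O conventions

Golden comparisons in tests use absolute 1e−3 (printed precision);
algebraic identities and invariances use relative 1e−9. Section indices are
0-based, anterior first; CSV is UTF-8, comma, "." decimal; species ids are
underscored binomials doubling as Newick tip labels; metric CSVs are
byte-deterministic for identical inputs, figures are not. Problem sizes
throughout (11-section windows, 5-canal phantoms at pitch r₀/20, 10⁴
calibration replicates) were chosen so a full validation cycle runs in
seconds to half a minute on one CPU while keeping voxelisation error well
inside the stated tolerances.

## Limitations

Only axis-orthogonal sections on synthetic volumes; no real µ-CT ingestion,
mesh segmentation, or oblique plane selection. No phylogenetically
corrected hypothesis tests. The two statistics summarise a 1-D area
profile and cannot capture 3-D recess orientation or inter-recess gap
shape. The cohort generator's log-normal family is a modelling convenience,
not an anatomical claim.
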