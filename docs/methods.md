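# Methods

## Design

The package implements a time-stratified, bidirectional case-crossover
analysis of effect modification. Each death is its own control: exposure
on the death day is contrasted with exposure on every other day of the
same calendar month falling on the same day of the week (3 or 4
referents, on both sides of the case). Matching on calendar month
removes confounding by anything fixed or slowly varying on that scale;
matching on weekday removes weekly cycles; bidirectional referents
remove bias from monotone exposure time trends, at the price of a small
post-death sampling bias that is negligible when the daily death hazard
is small. Because residence in a historically-redlined block group is
constant within a stratum, its main effect is structurally inestimable —
only its interaction with time-varying exposure is identified, and that
interaction is the estimand throughout.

## Grade apportionment

Block groups are assigned HOLC grades by population share at the Census
*block* level: each block's population is binned into the grade of the
HOLC polygon containing its centroid (blocks outside every polygon bin
to `Unclassified`), and the block group takes the label of the single
bin holding strictly more than a threshold fraction of its total
population, else `Ambiguous`. The default threshold is 0.90, with 0.50
and 0.99 as sensitivity settings. Compared with areal-overlap
apportionment this makes no uniform-density assumption. Conventions the
sources leave open, fixed here deterministically:

* a centroid on a polygon boundary counts as contained;
* a centroid inside several overlapping polygons takes the *worse*
  grade (latest in A<B<C<D<E), logged — conservative toward the
  exposure of concern;
* comparison with the threshold is strict (`>`), so a share exactly at
  the threshold yields `Ambiguous`; consequently raising the threshold
  can only move labels toward `Ambiguous`, never resolve one;
* grade E (meaning unknown in the historical maps) is carried as its
  own label, never merged into D;
* zero-population block groups are excluded with an error/ledger entry
  rather than labelled.

All geometry is planar in a single projected system; the package never
reprojects.

## Exposure assignment

PM2.5 travels grid → block → block group: a block's daily value is the
mean of grid-cell centroids its polygon contains (closed containment),
falling back to the Euclidean-nearest centroid for blocks containing
none; block groups take the population-weighted mean of member blocks.
Meteorology travels grid → block group directly as the areal-weighted
mean over intersecting cells, with cells modelled as squares of side
equal to the grid pitch centred on their centroids. Daily mean
temperature is (tmin + tmax)/2. All three rules are convex and invariant
to rescaling the weights.

The daily calendar uses 365-day years (no Dec 31 in leap years),
mirroring the Daymet meteorology product. The k-day moving average of
PM2.5 (k ∈ 2..5, lags 0..k−1) is missing whenever any lag is absent —
in particular when the window touches a leap-year Dec 31 — and analyses
of a moving-average exposure drop affected strata whole.

## Extreme heat

The cutoff is the p-th percentile (default 95, with 85/90/99 supported
for sensitivity work) of daily minimum temperature computed separately
per block group and calendar year, using linear interpolation between
the closest order statistics (the numpy default, pinned by an
order-statistic oracle test). A day is extreme when tmin **meets or
exceeds** the cutoff (the inclusive reading). Runs of ≥2 consecutive
extreme days are heat waves numbered 1..L from the run start; isolated
extreme days are singletons. Run detection operates on the continuous
calendar — a wave may cross Dec 31 → Jan 1 with each day judged against
its own year's cutoff, since physiology does not reset at New Year and
midwinter waves are vanishingly rare anyway — but a calendar gap (the
missing leap-year Dec 31) breaks a run. Wave days 1–4 are separate
indicator exposures; days ≥5 contribute only to the any-extreme-heat
exposure. One source table labels the heat column with the 90th
percentile while the text specifies the 95th for the main analysis; the
module supports both and the default is 95.

## Exclusion cascade

Records pass sequentially through: external causes (outside ICD-10
A00–R99); age < 18; geocode missing or coarser than block group; home
block group outside the reporting state; death outside the study window
(default Jan 5 2001 – Dec 31 2016; the Jan 5 start lets lag 4 reach
Jan 1); zero-population home block group; and death dates whose lag 0–4
window touches a leap-year Dec 31. Each step's count lands in a ledger
so planted-violation fixtures can verify the accounting exactly. A
stratum whose case **or any referent** day lacks an exposure row is
dropped whole rather than fitted with reduced referents — the
symmetric-treatment choice, since fitting on a subset of referents would
make stratum composition depend on exposure availability.

## Conditional logistic regression

Per stratum the likelihood contribution is the softmax log-probability
of the case day, `η_case − log Σ_rows exp(η_row)`; stratum-constant
terms cancel exactly (verified by injecting a fake redlined main effect,
which must not move the fit). The linear predictors are

* PM2.5 model: exposure (lag-0 or a 2–5-day moving average, per
  10 µg/m³) + 4-df natural cubic splines of TMEAN and VP + redlined ×
  exposure — 10 coefficients;
* heat model: exposure indicator (any extreme day, wave day 1–4, or
  singleton) + 4-df VP spline + redlined × exposure — 6 coefficients.
  The heat model adjusts for vapor pressure only, exactly as the
  analysis it re-implements specifies.

The spline basis is the truncated-power natural cubic spline with the
linear-tail constraint folded in: interior knots at the pooled
case+control 25/50/75% quantiles, boundary knots at the observed range,
exactly linear beyond the boundary. Tests verify linear tails, exact
representability of linear functions, and span-equivalence against an
independent B-spline-plus-null-space construction.

Maximisation is Newton–Raphson on the analytic gradient and Hessian
with step-halving (ascent guaranteed), starting at zero. Convergence
requires relative log-likelihood change < 1e−9 and max |gradient| <
1e−6. Overflow is guarded by within-stratum max-subtraction. Separation
(a coefficient passing |β| > 30) or a singular information matrix is
reported as non-convergence with a diagnostic, never as silent output.
The covariance is the inverse observed information; intervals are Wald
with z = 1.959964 on the log-odds scale, exponentiated; the
percent-excess-risk transform is (OR − 1) × 100. Fitting PM2.5 per
10 µg/m³ is implemented by scaling the design column, which tests show
is identical to rescaling the coefficient.

## Synthetic data

The generator emulates the study conditions end to end: a square city
of 8×8 block groups (2 km each, four blocks apiece, log-normal block
populations around 250) with an inner 4×4 HOLC core split into
quadrants graded A/B/C/D plus an E sliver, deliberately offset from the
Census lattice by 0.3 km so apportionment is non-trivial; daily tmin/
tmax as an annual sinusoid plus AR(1) city-wide noise (mean 12 °C,
amplitude 11 °C, diurnal range 8 °C, φ = 0.75) with a +0.5 °C
urban-heat excess in redlined cells; vapor pressure as a
relative-humidity fraction of the saturation curve; PM2.5 log-normal
AR(1) around 9 µg/m³ with a +1.3 µg/m³ additive offset inside redlined
polygons, echoing the observed contrast between redlined and other
areas. Demographics echo the published baseline table (age ≈ 76 ± 15,
higher Black population share in redlined areas).

Death days are drawn **within referent strata**: a block group and a
month/weekday stratum are chosen, then the death day among the
stratum's days with probability ∝ exp(η) at configurable true
coefficients (defaults: interaction log-ORs log 1.01 per 10 µg/m³ and
log 1.02 for extreme heat — the order of magnitude of the published
estimates, a calibration rather than a reproduction). Because the
generator and the conditional likelihood share the same discrete-choice
form, the estimator is exactly correctly specified and recovery bias
vanishes as the number of strata grows. To keep that exactness, the
true confounder effects of TMEAN and VP are *linear* — linear functions
lie in the span of any natural-spline basis plus intercept, so spline
adjustment introduces no approximation error. A per-day Bernoulli
hazard mode is available to demonstrate the small post-death sampling
bias the stratum-softmax form sidesteps.

What the generator does **not** emulate: spatial autocorrelation of
baseline mortality, demographic realism beyond marginal proportions,
commuting-induced exposure error, multi-city heterogeneity, or
real-data missingness patterns beyond the leap-year calendar gap.
Passing tests therefore certify the correctness of the pipeline's
algorithms and the calibration of the estimator under correct
specification — not the published effect sizes, which derive from
restricted mortality data.

## Validation scales and numerical choices

The replicated recovery study uses 20,000 strata per replicate and 50
replicates per model, sizes at which the interaction's Monte-Carlo
standard error (~0.01 on the log scale) makes bias detection meaningful
while a replicate simulates and fits in about a second; interval
coverage is required to land in [0.90, 0.98], the two-sided binomial
band around 0.95 at 50 replicates. The permutation-null check refits
100 within-stratum permutations of PM2.5 on a ~3,000-stratum study.
Monte-Carlo oracles for areal weights use 10⁵ (acceptance: 6×10⁴)
uniform points at 1–2% relative tolerance. Determinism is by seeded
`numpy` generators throughout; identical configs produce byte-identical
outputs, and the pipeline manifest records seed, config and versions.

## Known limitations

* The conditional-logit fitter assumes exactly one case per stratum
  (true by construction here); it does not implement the general
  Breslow/Efron machinery for matched sets with multiple cases.
* Robust/sandwich variances, distributed-lag nonlinear models and
  Bayesian fitting are out of scope.
* The areal-weighting step loops over block groups in Python; it is
  sized for thousands of polygons, not national-scale rasters.
* Subgroup cells with few redlined strata can be non-identifiable; such
  cells are reported as non-converged/no-data rather than estimated.
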