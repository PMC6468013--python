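# Methods

This note documents the models implemented in `herdtrack`, the synthetic
data they are validated against, and the numerical and design choices made
where the methodology left room.

## Study system and conventions

The package targets the analysis of partially migratory northern ungulates
tracked with GPS collars on a 2-hour fix schedule over full annual cycles.
Coordinates are planar projected kilometres; the synthetic landscape's
coastline is the `x = 0` meridian, so distance-to-coast is simply `|x|` of
the winter-range barycenter, and elevation rises inland. All timing is in
fractional Julian days (day-of-year, UTC). Distances are Euclidean
throughout — the regional scale of such study areas does not warrant
geodesy.

## The synthetic cohort generator

The generator is first-class, tested code; every downstream stage is
validated against it because the ground truth (tactic, timing, dwells,
behavioural states) is known exactly.

**Movement model.** An animal's position is a discrete mean-reverting
(Ornstein–Uhlenbeck) excursion around a moving activity center. For
residents the center is fixed; for migrants it follows the logistic
migration path, so the expected displacement from the winter range is
exactly `δ/(1+exp((θ−t)/φ))` per season — the same curve the analysis layer
fits, making generator and analysis consistent by construction (verified to
1e−9 on noiseless tracks). Defaults: within-range spread `ou_sd` = 0.5 km
per coordinate and relaxation time 3.6 h. The relaxation time was chosen so
that simulated 2-hourly step speeds fall in the 0.2–0.5 km/h band typical
of collared red deer; a slower OU produces multi-hour loiters that no real
fix series shows and that masquerade as stopovers.

**Stopovers** are generated as explicit stationary dwells: within a dwell
window the center pins to the stopover location, the excursion tightens to
0.15 km spread (0.1 km default scale) with fast (~2 h) relaxation. This
makes recall measurable: a dwell is an objectively distinct behaviour, not
a soft slowdown. Dwell windows are drawn disjoint within the migration
window, with residence ≥ 14 h (mean 30 h).

**Cohort defaults are the study conditions**: 55.1% migrants, roughly
two-thirds females, spring departures synchronised around Julian day 124
(SD 15–18 d by sex) and autumn around day 260–262 (SD 24–30 d), spring
temporal scales averaging 2 d (females) / 3.8 d (males) and shorter autumn
scales, inter-range distances ~15 ± 6 km (min 5 km), and stopover rates of
0.41/0.77 (F/M spring) and 0.18/0.35 (autumn). Males therefore migrate
longer, roam more, use more stopovers, and are slower in spring; spring
departure is more synchronised than autumn — the sign structure the
inference layer is expected to recover.

**Activity counts** are a two-component mixture: an "active" fix draws
`threshold + 1 + Poisson(60)` and an inactive fix `min(Poisson(5),
threshold)`, with state-dependent activity probability (traveling 0.85,
stationary 0.35). The clipping makes the active/inactive split exact by
construction while keeping realistic overdispersion.

**NDVI** series are 16-day composites of a per-pixel double-logistic curve
plus Gaussian noise (sd 0.02, small relative to the ~0.5 amplitude of real
composites). The landscape's phenology parameter fields default to
green-up peak-date SD 23.64 d vs dry-down 9.63 d and onset-to-peak
durations 11.45 d vs 6.57 d — the broad-scale asymmetry the synchrony
analysis is meant to detect.

**Seeds.** One master seed; animal *i* uses
`SeedSequence(master, spawn_key=(i,))`, so cohorts are reproducible and any
animal can be regenerated in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: habitat selection and terrain-driven route
choice, fix loss and GPS error correlated with canopy or topography,
behaviour-dependent fix schedules, snow phenology, inter-annual variation
within an animal, and social effects. Results on synthetic cohorts validate
the estimators' internal consistency, not ecological claims.

## Cleaning

Fixes within 24 h of collaring are discarded (capture effects). The outlier
screen is a two-rule procedure: "spike" fixes reached and left faster than
10 km/h with a turning reversal above 170° are removed first, then fixes
implying sustained speed above 15 km/h, iterating to a fixed point so the
screen is idempotent. The exact thresholds used in the original field
protocol are not published; these defaults are configurable and logged.

## Tactic classification and migration characteristics

Five candidate models are fitted to `nd(t)` by bounded nonlinear least
squares (`scipy.optimize.least_squares`, multi-start: θ from the steepest
smoothed displacement change, δ from the upper-quartile displacement,
φ ∈ {1, 5, 15} d). Mid-dates are bounded to the observed window ± 10 d and
temporal scales to ≤ 45 d: without these bounds the double sigmoids
degenerate into slow ramps that soak up within-range autocorrelation.
Candidates are ranked by AICc with Gaussian likelihood (`k` counts model
parameters plus the residual variance). Displacement, not squared
displacement, is fitted so the asymptote is directly the inter-range
distance in km; squared-scale fitting would weight the plateau
quadratically. The classification rule: lowest-AICc converged candidate,
with any range-shift model (disperser, migrant, mixed migrant) required to
*realize* at least 3 km of displacement over the data window — judged on
the fitted curve's amplitude, because degenerate near-cancelling double
sigmoids can report arbitrarily large raw asymptotes while realizing
nothing. Manual fit assessment is replaced by a review flag (top two
eligible candidates within 2 AICc, or amplitude within 20% of the
threshold); flagged animals are listed in the diagnostics JSON for human
override.

**The seasonal fit and the noise floor.** Net displacement is a folded
quantity: with within-range scatter σ per coordinate,
`E[nd²] = d² + 2σ²`, so the series sits on a ~0.9 km floor even while the
animal is on its range. A bare 3-parameter logistic can only absorb that
floor by inflating φ (we measured +12–18% bias on simulated tracks). The
default model is therefore `nd(t) = sqrt(δ²L(t)² + c)` with `L` the unit
logistic and `c ≥ 0` a nuisance floor: as `c → 0` it is exactly the
logistic, δ/θ/φ keep their definitions, and the bias drops below 5% on all
three parameters (measured: δ 0.4%, θ 0.03%, φ 3.7% at n = 200). The bare
logistic remains available (`noise_floor=False`).

**The ±2φ window.** Departure `θ − 2φ`, arrival `θ + 2φ`, duration `4φ`.
A logistic attains only ~88% of its asymptote at `θ + 2φ`, and the scale
parameter is sometimes verbally described through the 75% point
(`θ + φ·ln 3 ≈ θ + 1.0986φ`); the ±2φ convention is used for every output
because the derived characteristics are defined in its terms. Seasons are
split at the midpoint of the fitted mid-dates; the autumn movement is
fitted on displacement from the summer-range origin (mean position over the
mid-summer plateau). Julian dates are day-of-year; movements crossing New
Year are not generated by default and would need an unwrapped time axis.

## Brownian-bridge UD and stopovers

The bridge marginal at interior time `t` of an interval `[0, T]` is
Gaussian around the linear interpolation with per-coordinate variance
`σ²ₘ t(T−t)/T + σ²loc((1−t/T)² + (t/T)²)`. σ²ₘ is estimated by
leave-one-out likelihood of odd-indexed fixes under bridges spanning their
even-indexed neighbours, optimized by bounded scalar search on log σ²ₘ with
the σ²ₘ = 0 boundary checked explicitly. The UD is the time-weighted
average of bridge marginals (midpoint quadrature, ≥ 10 nodes per 2-h
interval), evaluated at cell centers (default 100–150 m cells, grid =
bounding box + 3 predictive SD) and normalized; marginals narrower than a
thousandth of a cell deposit a point mass. Location error defaults to
0.02 km.

"Highest 25% quantile" is read as the smallest cell set holding the top 25%
of probability mass (standard isopleth semantics; a per-cell percentile
variant is behind `threshold_mode="percell"`). Selected cells are clustered
by 8-connectivity. Because 25% of the mass is always selected, corridor
segments of slow travel inevitably form clusters too; the original
procedure resolved these visually. The automated stand-in applies, per
cluster (each decision logged):

1. **Range overlap** — drop clusters whose use-weighted centroid falls
   inside a seasonal-range circle. In the pipeline these circles come from
   the fixes within 15 d of the window, with radius at least
   `0.13·δ + 0.4 km` so they also cover the slow logistic tails (the ~12%
   of the displacement outside ±2φ is range-side by the window convention
   itself, and the tail hover centroid sits near `0.12·δ`).
2. **Residence** — drop clusters holding the track for under 12 h
   (membership on clusters dilated by one cell; a fix on a cell edge still
   counts).
3. **Stationarity** — the first-half to second-half mean position of the
   core-cell visit must drift ≤ 0.75 km, and the visit must show a
   sustained dwell signature: ≥ 20% of its core fixes, including an
   unbroken ≥ 10 h run of visiting fixes, moving below half the *en-route*
   step scale — the median step length of the fixes not visiting the
   cluster. Conditioning the scale on the complement matters: the
   segment-wide median collapses onto the dwell scale when a long dwell
   dominates the window. A stopover is a sustained reduced-movement
   episode; slow corridor travel keeps en-route step lengths, and chance
   loiters do not sustain slow runs.

Pooled over six independent 50-track benchmarks (dwells ≥ 14 h) this
yields recall 0.94 and precision 0.95; performance degrades gracefully for
shorter dwells or very slow migrations, where the task becomes genuinely
ill-posed at the 12-h scale.

## Phenology

The six-parameter symmetric-amplitude double logistic (single amplitude for
both seasons) is fitted per pixel by bounded least squares with a
multi-start grid on the two inflections; an optional winter-cleaning step
floors snow-season composites at the 10th-percentile baseline. IRG/IRD are
the analytic derivatives of the seasonal parts, reported as positive
magnitudes (the sign convention is stated in the report header). "Peak" is
the date of maximum IRG — the inflection — and "onset" the curvature
maximum, `S − ln(2+√3)/mS`, giving the closed-form onset-to-peak duration
`ln(2+√3)/m`. Peak NDVI date (plateau midpoint) is also emitted for anyone
preferring that convention; the synchrony report uses peak IRG. The
synchrony report compares peak-date spreads (Levene test + Fisher variance
ratio with CI) and durations (Welch t) between green-up and dry-down.

## Inference layer

* **Levene test**: Brown–Forsythe form (median-centered) by default,
  matching the standard implementation the field uses; mean-centering
  available. Verified against both a brute-force ANOVA on absolute
  deviations and `scipy.stats.levene`. Type-I error at α = 0.05 measured at
  0.04–0.06 over 10⁴ null replicates.
* **Fisher variance ratio** with central-F confidence interval on
  `(n₁−1, n₂−1)` degrees of freedom.
* **Transforms**: log for distance/duration/speed, `log(x+1)` for stopover
  counts (zeros), per-season median-centering for departure timing
  (departure variances are kept on raw Julian-day deviations — reported
  departure-variance magnitudes of order 10²–10³ d² are only consistent
  with the raw scale), z-scoring for continuous covariates, and the
  arcsine rescaling `arcsin(p)·2/π` for daily activity proportions. The
  conventional variance-stabilizing `arcsin(√p)` is available behind
  `variant="sqrt"`; the literal form is the default because it is the
  transform as printed, and the choice is config-exposed rather than
  guessed.
* **Candidate sets**: all subsets of the global model respecting
  marginality (interactions only with their main effects) and the
  `|r| ≤ 0.3` collinearity exclusions; capped with a warning at 5,000.
* **Fitting engines** are a pluggable contract (term set → log-likelihood,
  parameter count, coefficients, variance components). Gaussian responses
  use `statsmodels` MixedLM with crossed random intercepts for animal
  identity and year, fitted by **maximum likelihood** (not REML) so AICc is
  comparable across fixed-effect structures; several optimizers are tried
  in sequence because no single one converges on every candidate. Binary
  stopover-use models use a fixed-effects logistic GLM: statsmodels
  provides no ML-fit GLMM, and omitting the random intercepts leaves the
  AICc ranking of fixed-effect structures and coefficient signs intact for
  the calibrations performed here; the engine seam is where a GLMM backend
  would plug in.
* **Selection**: the parsimony rule — among candidates within 2 AICc of the
  top, the smallest parameter count wins; ties break by lower AICc, then
  lexicographic term order (logged). Under a null simulation with animal
  and year random effects, the intercept-only model is selected in ~83% of
  replicates.
* **R²**: Nakagawa marginal/conditional from the fitted variance
  components. p-values are reported to 3 dp; no multiple-testing
  correction is applied.

## Problem sizes

The default cohort is 40 animals × one year at 2-h fixes (~175k fixes) with
400 NDVI pixels; the validation experiments use 200 tracks for parameter
recovery, 100 animals for classification, 50 tracks for the stopover
benchmark, 289 grid-strided pixels for synchrony (spaced beyond the parameter fields' spatial correlation length), 10⁴ replicates for the Levene
calibration and 100 for the model-selection calibration. These sizes give
stable estimates (binomial and F-distribution sampling error well inside
the margins checked) while keeping a full run in minutes on one core.

## Known limitations

* The candidate movement models assume a single annual migration cycle;
  multi-year tracks must be split per animal-year upstream.
* Stopover detection near the range edges is intentionally conservative:
  dwells inside the range-exclusion circles are unknowable from the UD
  alone and are not claimed.
* The binary-response engine omits random intercepts (above).
* The Gaussian AICc used for movement-model ranking treats fixes as
  independent; OU autocorrelation makes the effective sample size smaller,
  which is why the mixed-migrant candidate often edges the shared-asymptote
  migrant. Classification is therefore assessed on the binary
  migrant/resident axis.
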