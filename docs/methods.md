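# Methods

This note records the models, the numerical choices, and what the
synthetic data do and do not establish.

## Data model

An observation is one radiotelemetry relocation: animal id, season id
(the animal-season is the analysis unit; females may change reproductive
class between seasons), timestamp, planar x/y in meters, and five
habitat covariates measured in a 1-m² quadrat at the position — percent
cover of canopy, coarse woody debris (cwd), ground-layer vegetation,
rock, and woody understory vegetation, each in [0, 100]. Coordinates
must be projected meters; geographic degrees are rejected rather than
silently projected because kernel bandwidths and MCP areas are metric.

## Home ranges

The percent minimum convex polygon peels outliers before hulling:
retain the ⌊percent·n⌋ points nearest the arithmetic centroid of all
points (Euclidean distance; ties at the retention boundary broken by
observation id so the peel is deterministic), then take the convex hull.
`percent = 1` retains everything. The peel variant and floor rounding
are declared conventions — different tools peel differently — and the
brute-force oracle in the tests pins this one. Seasons with fewer than
`min_obs_per_season = 20` relocations, or flagged incomplete (mortality,
transmitter loss), are removed before any spatial modeling; the
subsampling curve (`mcp_area_curve`) exists to justify the threshold
visually, and no asymptote model is fit to it.

## Utilization distributions

`kde_ud` evaluates density(c) = (1/n) Σᵢ N₂(center(c) − pᵢ; h²I) at
cell centers and renormalizes so Σ density · cellarea = 1 (tolerance
1e-6, enforced everywhere). The kernel is truncated at 5h; the
neglected mass is < 1e-6, which is also the order of the largest
pointwise error against the closed form. Grids use a lower-left origin,
row 0 south, point-to-cell by floor, right/top edges assigned inward.

A volume contour is the minimal high-density cell prefix: sort cells by
density descending (ties by row-major index), take the shortest prefix
whose cumulative volume reaches the isopleth. Labels later come from
cell membership, never from polygonized boundaries, so points cannot
sit ambiguously on a contour.

Bandwidth selection matches the home range: evaluate h on the grid
{h₀, h₀+step, …} (step = 1 m) and return the first h whose 95% contour
area reaches the 95% MCP area. Exact equality is unattainable on a
discrete raster; the first crossing is deterministic and consistent
with the (empirically monotone) growth of contour area in h. The
evaluation grid is fixed *before* tuning so area comparisons are
grid-consistent; its margin is max(50 m, 3·h_cap) where
h_cap = 1.5·sqrt(target / (π·χ²₀.₉₅,₂)) bounds the bandwidth any tuning
can need (a single Gaussian blob, the worst case, has 95% contour area
π·χ²₀.₉₅,₂·h²).

The population UD controls for unequal tracking durations: each
iteration draws one season per animal uniformly, pools the points,
recomputes the pooled 95% MCP, re-tunes h to its area, and evaluates on
the one shared grid; the cellwise mean is renormalized (means of
normalized surfaces on a shared grid are already normalized up to float
error). The pooled MCP is recomputed per iteration rather than fixed.
Tuning warm-starts at the previous iteration's h; the warm start moves
only the scan's entry point (the scan walks back down whenever the
entry point already crosses), so the returned h is identical to a cold
scan — a property the tests check directly. The analysis run uses 400
iterations and the acceptance script 150; independent 100-iteration
runs already correlate > 0.99 cellwise, so these sizes are past the
stabilization point of the averaged surface.

Autocorrelated kernel estimators and movement-bridge UDs are
deliberately out of scope: at multi-day relocation intervals they
oversmooth exactly the fine-scale use-intensity peaks this analysis
needs.

## Core labels and the level-contrasted models

Each retained observation gets `core_ind` (inside the 30% volume
contour of its season UD) and `core_pop` (inside the population UD's
30% contour). The 30% contour holds 30% of probability *volume*, not of
points; the labeled point fraction typically exceeds 0.30.

Both resource-utilization models are logistic regressions on the
z-scored covariates (so effect sizes are comparable within and across
models), screened for collinearity with VIF = 1/(1−R²) < 2. The
individual-level model is a single pooled logit: labels are
season-relative by construction, so a season random effect would carry
no information. The population-level model adds a Gaussian random
intercept per animal-season to absorb repeated sampling of individuals.
Its marginal likelihood is maximized by adaptive Gauss–Hermite
quadrature: per group, an inner Newton finds the conditional mode of
the log-concave integrand, nodes are centered there and scaled by the
conditional curvature, and 9 nodes suffice (the log-likelihood moves
< 1e-4 going to 25; the fit matches lme4's `glmer` nAGQ=9 to ~1e-6 in
log-likelihood on a shared fixture). The score is evaluated by
quadrature on the same adapted grid, which makes the optimization fast
enough for subset enumeration; standard errors come from the observed
information (finite differences of the analytic score). A variance
estimate collapsing below 5e-3 is returned as the pooled logit with a
boundary flag and σ_u = 0.

Model selection considers every covariate subset (32 models; intercept
always included, random intercept always included in the mixed case).
Candidates with ΔAIC < 2 of the best are averaged with renormalized
Akaike weights; the *full* average assigns β = 0 (and SE = 0) where a
covariate is absent, and the unconditional SE is
Σ w_m·sqrt(SE²_m + (β_m − β̄)²), the Burnham–Anderson combination of
within-model variance and between-model spread. AIC (not AICc) ranks
models — at n/k ≈ 170 the small-sample correction is negligible — and
the mixed-model k counts fixed effects + intercept + the variance.

The level contrast per covariate is Wald's
W = (β̄_ind − β̄_pop)²/(SE²_ind + SE²_pop) against χ²₁, treating the two
averaged coefficients as independent. The two labels derive from
different UD constructions over the same points, so their estimators
are not strictly independent; no covariance treatment is attempted, and
this is the main caveat on the p-values. Calibration under identical
planted effects at both levels is nevertheless close to nominal (the
acceptance test requires the rejection rate over 500 simulated datasets
to sit in [0.03, 0.08]). The five Wald p-values are reported raw, with
no multiple-testing correction. Confidence intervals everywhere are
Wald (±1.96·SE). Marginal-effect curves hold other covariates at their
standardized mean (0) and map delta-method CIs on the linear predictor
through the inverse logit, treating intercept and slope uncertainties
as independent components of the averaged model.

## Reproductive-class comparison

Model 1 regresses reproductive class (reference: gravid female) on the
standardized covariates over *individual-core* observations — class
preferences are expressed in the individually chosen summer cores.
Model 2 regresses ecological level (reference: individual); each core
observation contributes one row per level at which it is core, so an
observation core at both levels appears twice. This row construction
is a declared convention. Estimated marginal means are the multinomial
linear predictors at the covariate mean vector (all zeros under
standardization), unweighted; pairwise differences get delta-method SEs
and normal-approximation ratios (n is in the hundreds, so t vs normal
is immaterial). PCA uses the correlation matrix (the covariates share a
percent scale but not variances, and the correlation matrix matches the
Bartlett sphericity framing); loadings are sign-normalized so the
largest-magnitude element of each component is positive, making output
independent of the eigensolver; |loading| ≥ 0.5 and covariate–PC
correlation > 0.40 are the "strong" flags. Bootstrap class summaries
use seeded percentile intervals with 1000 resamples.

## Spatial diagnostics

The omnidirectional empirical semivariogram
γ(h) = (1/2N(h)) Σ (zᵢ−zⱼ)² over equal-width lag bins (default 15,
max lag = half the maximum pairwise distance) documents the spatial
autocorrelation of the covariates at relocation sites. No variogram
model is fit, and no spatially structured random effect enters the
regressions: when animal movement is strongly habitat-driven, a spatial
random effect competes with the covariates for the same variation
(spatial confounding) and can erase real habitat effects, so the
diagnostic is reported alongside unadjusted models instead.

## The synthetic study

The generator emulates the study conditions the pipeline is designed
for: 16 animals contributing ~27 animal-seasons (1–3 seasons each,
5:11 male:female, gravid probability 8/18 per female-season) of
32 ± 7 relocations truncated to [20, 49]. Each of the five covariate
surfaces is a stationary Gaussian random field with exponential
covariance (practical range 40 m; exact sampling by circulant embedding
on a doubled grid, tiny negative embedding eigenvalues clipped), shifted
by zone offsets and mapped to percent by a scaled logistic — bounded in
[0, 100] with no truncation artifacts. The communal zone (hibernaculum,
radius 80 m) carries elevated rock and canopy and depressed ground
vegetation; meadow patches the opposite canopy/ground pattern.

Seasons are phase-switched point processes, not movement models: 15% of
relocations cluster on the shared hibernaculum in spring (σ = 35 m),
10% interpolate outward with jitter (dispersal), 60% scatter around 1–3
individually drawn summer core sites (σ = 12 m), 15% return communally
in fall. At 48–72-h relocation intervals step autocorrelation is weak
and the pipeline consumes point patterns only, so a continuous-time
movement model would add realism the estimators never see. Summer core
cells are drawn with probability ∝ exp(w_class · z(covariates)):
gravid females prefer cwd-rich cells (w_cwd = +1.8, one core — communal
gestation at debris sites), males prefer grassy, open cells
(w_ground = +1.0, w_canopy = −2.0, up to three cores), nongravid
females are intermediate. The contrast magnitudes are sized for
identifiability at study scale: class contrasts must survive both the
canopy/ground-vegetation collinearity that meadows induce and the small
effective sample (~40 core *sites*, since covariates within a site are
spatially correlated, the information unit is the site rather than the
observation). Observed covariates are bilinear landscape samples plus
N(0, 6²) noise clipped to [0, 100].

`planted_truth` derives the expected effect *directions* from the
configuration itself: population-level signs from the covariate
contrast between the communal zone and the landscape mean,
individual-level signs from the class-mixture average covariate
contrast at preference-weighted cells, with |z| < 0.15 recorded as
"none". Under the defaults this plants the level-dependent signature —
canopy negative individually, positive at the population level.

What passing tests on these data show: the estimators implement their
contracts exactly (oracle-checked), the statistical machinery is
calibrated and has power under the planted effect sizes, and the
pipeline recovers planted structure end to end. What they do not show:
field realism of the effect sizes (no quantitative covariate contrast
between communal and summer habitats is available to calibrate
against), robustness to habitat-measurement protocols, or behavior
under missing-data patterns other than row-wise missingness.

## Reproducibility

One root seed; every stochastic stage (landscape, telemetry, population
resampling, bootstraps, area curve) derives an independent child stream
keyed by a hash of the stage name, so re-running or reordering stages
never perturbs the others, and identical configuration + seed gives
bit-identical outputs end to end. Problem sizes used by the shipped
runs: 400 population-UD iterations in the analysis drivers, 150 in the
acceptance script, 1000 bootstrap resamples, 100 area-curve iterations.

## Known limitations

- The Wald level contrast ignores dependence between the two labelings
  of the same points (conservative or anticonservative depending on the
  dependence sign; calibration is verified only under the generator's
  independence-like conditions).
- "Completeness" of a season is external metadata; it cannot be
  inferred from coordinates.
- The 95%-contour/MCP area match inherits grid discretization: the
  returned contour area can exceed the target by up to one bandwidth
  step's worth of growth (~15% in the shipped runs, ratio reported per
  season in `bandwidth_tuning.csv`).
- PCA assumes linear covariate relationships; nonlinear structure in
  core habitats is summarized only to the extent the correlation matrix
  captures it.
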