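# levelcore

Multilevel core-habitat analysis for radiotelemetry of episodically
gregarious animals.

Many temperate snakes (and other central-place or communally wintering
wildlife) alternate between gregarious phases — communal hibernacula,
spring basking, gestation sites — and solitary summer activity. Habitat
models fit at a single ecological level miss this: the places a
*population* uses intensely (shared hibernacula) can be spatially and
environmentally unlike the places each *individual* uses intensely
(its own foraging or gestation sites). `levelcore` implements the full
analysis chain for detecting and characterizing such level-dependent
habitat use from relocation data, plus a synthetic-telemetry generator
that plants known level-dependent effects so every stage can be verified
against ground truth. It is aimed at movement ecologists and analysts of
VHF/GPS telemetry with per-relocation habitat covariates.

## The method

Given relocations of animal-seasons with five habitat covariates
(percent cover of canopy, coarse woody debris, ground-layer vegetation,
rock, woody understory) measured at each point:

1. **Home ranges.** Seasons with fewer than 20 relocations are dropped
   (MCP area stabilizes by ~20 observations, checked by a subsampling
   curve). The 95% minimum convex polygon retains the ⌊0.95·n⌋ points
   nearest the arithmetic centroid and takes their convex hull.
2. **Utilization distributions.** A UD is the probability-density
   surface of space use. Each season's UD is a bivariate-Gaussian KDE
   whose bandwidth *h* grows in 1-m steps until the area of the 95%
   volume contour of the UD first reaches the 95% MCP area
   (home-range–matched bandwidth selection). The population UD draws
   one season per animal per iteration (so multi-season animals cannot
   dominate), pools the points, re-tunes *h* to the pooled MCP area,
   and averages the surfaces over many iterations on one fixed grid.
3. **Dual core labels.** Each observation gets two binary use-intensity
   labels: inside/outside the 30% volume contour (the "core") of its own
   season UD, and of the population UD.
4. **Resource-utilization models.** With z-scored covariates x, core
   use is modeled as logit P(core) = β₀ + xᵀβ — pooled at the individual
   level, with a Gaussian random intercept per animal-season at the
   population level (maximum marginal likelihood via adaptive
   Gauss–Hermite quadrature). All 2⁵ covariate subsets are fit;
   candidates with ΔAIC < 2 of the best are full-model-averaged with
   Akaike weights (absent covariates contribute β = 0) and unconditional
   SEs. Levels are contrasted per covariate with a Wald χ² statistic
   W = (β̄_ind − β̄_pop)² / (SE²_ind + SE²_pop), df = 1.
5. **Reproductive-class comparison.** Over core observations,
   multinomial logistic regressions compare habitat by class (gravid
   female reference) and by level (individual reference), with pairwise
   estimated-marginal-mean contrasts at average habitat, a
   Bartlett-checked PCA of the core covariates, and bootstrap class
   summaries. Semivariograms document the spatial autocorrelation of
   the covariates.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic dataset (one fixed seed; outputs under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_home_ranges.py
python analysis/03_utilization.py      # the slow step (~3 min)
python analysis/04_core_labels.py
python analysis/05_multilevel_models.py
python analysis/06_class_comparison.py
python analysis/07_spatial_diagnostics.py
```

Stage 01 simulates 816 relocations of 16 animals over 26 animal-seasons
(20–46 relocations each) on a landscape with a rocky, forested communal
(hibernaculum) zone and open meadows, and prints the planted effect
directions — canopy negative at the individual level but positive at the
population level. Stage 02 reports 95% MCP home ranges of 2.5 ± 1.0 ha
(gravid females), 3.5 ± 2.4 ha (nongravid females) and 7.2 ± 2.4 ha
(males). Stage 04 labels 57.1% of observations core at the individual
level and 41.3% at the population level, with canopy averaging 61.0%
inside population cores versus 46.5% inside individual cores. Stage 05
prints the central result, the level-contrasted model-averaged
coefficient table:

```
covariate    beta_ind [95% CI]        beta_pop [95% CI]        Wald W      p
canopy       -0.79 [-0.97,-0.61]     0.84 [ 0.62, 1.06]    128.43  0.0000*
cwd           0.34 [ 0.18, 0.50]    -0.22 [-0.40,-0.03]     19.71  0.0000*
ground_veg    0.22 [ 0.05, 0.38]    -0.08 [-0.27, 0.11]      5.10  0.0239*
rock         -0.04 [-0.17, 0.09]     0.35 [ 0.17, 0.53]     11.68  0.0006*
woody_veg     0.05 [-0.09, 0.19]    -0.20 [-0.38,-0.03]      4.80  0.0285*
```

Canopy cover has a strong negative effect on individual-level core use
and an equally strong *positive* effect at the population level — the
planted signature of episodic gregariousness (forested communal zone,
open summer sites), and exactly the kind of relationship a single-level
model would average away. Stage 06 recovers the planted class
preferences: male core areas hold significantly less coarse woody debris
than gravid-female cores (β = −0.69 ± 0.13), gravid cores are the
debris-rich ones (52.7% cwd vs 37.8% for males), and the first two
principal components (49.3% of variance) separate open/grassy male cores
from debris-associated gravid cores.

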