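# Methods

## Weighted-averaging niche estimation

Each taxon's position on an edaphic gradient is summarized by the
abundance-weighted mean of the gradient value over its occupied plots (the
optimum) and the abundance-weighted root-mean-squared deviation around it
(the tolerance). The estimator assumes a unimodal response sampled across
its full support: when plots cover the gradient evenly and the response
curve is not truncated at the gradient ends, the WA optimum is a consistent
estimator of the response peak. Under spatially clumped coverage —
inevitable when plots are placed uniformly in space but the soil itself is
patchy — WA keeps a coverage bias toward the gradient's center of mass
that does not vanish with sample size. The evaluation experiments
therefore separate two questions: *ranking* recovery (measured on
landscape-sampled plots, where the bias is shared across taxa and the rank
order survives) and *consistency* (measured under dense uniform gradient
coverage, where the mean absolute optimum error shrinks with n).

Gradient units: measured and model-predicted cation gradients are on the
natural-log cmol(+)/kg scale; CEC is used untransformed, as it is mapped.
A taxon observed in a single plot gets tolerance 0. Plots where a gradient
is undefined are dropped per taxon, not globally. Optima rankings are
compared with Kendall's tau-b (tie-corrected), because model-predicted
gradients can assign identical values to different plots; two-sided
p-values come from scipy.

## Map-evaluation statistics

- **Class summaries**: per dominant WRB class, the min/mean/max of
  measured cation concentration and the range in orders of magnitude,
  log10(max/min); classes spanning ≥ 2 are flagged as thematically
  heterogeneous.
- **ANOVA + Tukey**: one-way ANOVA of log cation by class; pairwise
  contrasts use the Tukey–Kramer studentized-range procedure
  (scipy.stats.tukey_hsd), which handles unequal group sizes and reduces
  to classical Tukey HSD on balanced designs. Groups with fewer than 2
  samples are dropped with a warning. Contrasts are flagged at
  p(adj) < 0.001.
- **Regression**: OLS of log cation on class-probability layers (or on
  one-hot dominant-class dummies for polygon maps), optionally plus CEC.
  Predictor subsets are chosen by forward–backward stepwise search
  minimizing AIC, starting from the intercept-only model (a `start="full"`
  option starts from the full model instead). The AIC convention is the
  Gaussian profile form n·ln(RSS/n) + 2(k + 1) with k design columns and
  the error variance counted; additive constants are dropped, so AIC is
  comparable only within one response vector — which is the only use made
  of it. Ties between moves resolve to the earliest candidate in input
  order, making selection deterministic. RSS is floored at
  n·(ε·‖y‖)² (ε machine epsilon) so that exact fits of different sizes are
  compared by the parameter penalty alone rather than by floating-point
  dust.

For polygon-source models the most frequent class is the dummy baseline
(avoiding the dummy-variable trap); predictions rebuild the full one-hot
set so any selected dummy is present, with absent classes contributing 0.

## Map extraction

Raster lookup is nearest-cell, never interpolated: class probabilities and
CEC are areal attributes, and interpolation would blur class identity.
Point-in-polygon uses shapely `covers`; a point on a shared boundary
resolves to the first covering polygon in layer order (documented,
deterministic). Plots without coverage are returned missing, counted in a
warning, and excluded from downstream fits. Detailed soil-class codes are
aggregated to dominant WRB classes through an editable CSV table; a
bundled default covers the common Amazonian classes, and unknown codes are
a hard error naming them.

## The synthetic landscape

The generator emulates the statistical structure of an Amazonian
soil-map-evaluation study, not its cartography:

- **Class mosaic**: a Voronoi tessellation of uniformly seeded points;
  the seed density sets the patch scale (`class_patch_scale`, default
  10 km on a 100 km × 100 km extent with 500 m cells). Every configured
  class is guaranteed at least one patch.
- **Cation field**: cell log-cation = class log-mean + class log-sd ×
  (mixed smooth/white standard-normal field). The smooth share
  (`smoothness`, default 0.5) makes neighboring cells co-vary; the
  marginal within each class is exactly the configured lognormal. Default
  class log-means span 0.3–15 cmol(+)/kg with log-sd 1.2, so the central
  95% of a class spans about two orders of magnitude — the within-class
  heterogeneity regime the method has to survive.
- **CEC layer**: the standardized log-cation field mixed with an
  orthogonalized independent smooth field, so the empirical correlation
  equals `cec_correlation` exactly (default 0.1, the weak-surrogate
  regime); then mapped affinely to a 10 ± 3 cmol(+)/kg scale and floored
  at 0.1 (< 0.1% of cells, leaving the correlation within ±0.05).
- **Probability rasters**: the true class has probability 1 in patch
  interiors and 1 − ε (ε = 0.2) at patch boundaries, with ε spread over
  the neighboring classes — mimicking probability layers that are
  confident away from boundaries. Per-cell probabilities sum to 1.
- **Displacement**: polygons translate rigidly by the exact (dx, dy);
  raster content shifts by the displacement snapped to whole cells on the
  fixed analysis grid, vacated cells becoming missing. Snapping keeps all
  displaced rasters on the common grid that extraction requires; at the
  displacement scales of interest (≥ patch scale ≫ cell size) the snap is
  negligible.
- **Plots and communities**: plot locations are uniform over the extent;
  measured cation is the true cell value times lognormal noise
  (`noise_sd`, default 0.1 log units, standing in for laboratory
  measurement error). Expected abundance of taxon k at log-cation x is
  A·exp(−(x − u)²/(2t²)); realized counts are Poisson — the simplest count
  law consistent with abundance data, chosen here since no empirical count
  distribution is available. The default community is 13 fern taxa used as
  edaphic indicators in Amazonian inventories, with optima evenly spaced
  on [−2, 3] log cmol(+)/kg, tolerance 0.5, and peak abundances 8–25.

The default study emulates three plot networks (UTU 879, PPBio 326,
SOTERLAC 300 plots; fern inventories in the first two) analyzed separately
and combined, with four model variants (polygon vs probability source,
± CEC) — 16 model rows per run.

What the generator does **not** emulate: floodplain geomorphology (so
displacement is a pure translation, not a misregistered river course),
spatial autocorrelation of plot placement (transects, road access),
detection error in inventories, inter-laboratory protocol differences
beyond a single noise level, and the machine-learning covariate stack
behind real probability maps. Passing tests therefore show the *pipeline*
behaves correctly under the stated statistical structure, not that any
particular real map is good or bad.

## Reproducibility and numerics

All randomness flows from one root seed; stage seeds are derived with a
stable string-keyed SeedSequence (`pipeline.derive_seed`), all below 2³¹.
Identical configs give byte-identical output files (floats are written
with enough digits to round-trip, rasters at 17 significant digits).
Experiment problem sizes — a 60 km × 60 km landscape at 500 m cells,
400–1,000 plots, 20 seeds per contrast — were chosen as the smallest
configurations at which the estimated quantities are stable across seeds;
a full default study runs in about a second.

## Known limitations

- WA tolerance uses the plain weighted-RMSE formula, without the
  degrees-of-freedom or tie corrections some transfer-function software
  applies; anyone comparing digit-for-digit against other WA
  implementations should check which variant theirs uses.
- No bootstrap confidence intervals on optima, no Gaussian-logit response
  fitting, no spatial autocorrelation correction, no CRS reprojection:
  inputs must share a planar CRS.
- The combined cross-dataset envelope merges tolerance intervals only;
  per-dataset optima are reported rather than a combined optimum, for
  which no principled definition exists here.
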