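# Methods

## Problem and data model

`macroniche` estimates the macronutrient composition — protein (P),
carbohydrate (C) and lipid (L) as fractions of metabolizable energy — of
wild-omnivore population diets from scat-content studies, and analyzes the
resulting 3-part compositions as points on the Aitchison simplex.

The measurement chain is:

1. **%Vol → %DDM.** Scat studies report each food item as a percent of
   fecal volume (%Vol). Differential digestibility biases these shares, so
   each %Vol is multiplied by the food's fecal correction factor (CF) and
   the products are renormalized: `ddm_i = vol_i·cf_i / Σ_j vol_j·cf_j`.
   The result is the food's share of digestible dry matter ingested. The
   operation is invariant to a global rescaling of all CFs and to record
   order; a food without a CF is an error, never silently dropped.
   Item-specific CFs override category-level CFs.
2. **Food masses → energy fractions.** Each food's macronutrient masses
   (grams per unit digestible dry matter) are converted to metabolizable
   energy with 17 kJ/g for protein and carbohydrate and 37 kJ/g for lipid,
   then closed to a 3-part composition.
3. **%DDM-weighted diet.** The population diet is the ddm-weighted mean of
   the food energy-fraction vectors, re-closed (`as-stated` mode, the
   default). A stricter energy bookkeeping — weighting additionally by each
   food's energy density, 17(P+C)+37L kJ per unit DDM — is available as
   `energy-weighted`; the two coincide when all foods have equal energy
   density. Both are kept because the published description of the
   weighting step is arithmetically ambiguous.
4. **Seasonal → annual.** Annual diets are the *unweighted* arithmetic mean
   of seasonal %DDM profiles over the union of foods (absent foods count
   as zero), re-closed, with macronutrients recomputed from the pooled
   annual profile. Seasons are treated as equally representative
   regardless of scat sample size. Averaging the seasonal macronutrient
   compositions directly is exposed only as a sensitivity flag
   (`average="composition"`).

Season labels are canonicalized to spring/summer/autumn/winter through an
explicit synonym map; an unmapped label with a month range is classified by
its midpoint month, and anything else is an error listing the accepted
synonyms — free-text guessing is deliberately avoided.

## Compositional statistics

All inference treats a diet as carrying only relative information. The
centred log-ratio clr(x)_i = ln(x_i / g(x)) maps the simplex to the
zero-sum hyperplane of R^D; the isometric log-ratio ilr(x) = V·clr(x) maps
it isometrically to R^(D-1) for an orthonormal zero-sum contrast basis V.
We fix a Helmert-type basis in part order (P, C, L); every reported
statistic is basis-invariant (asserted numerically in the tests), and the
basis is what gets recorded in model objects.

* **Centre**: the closed geometric mean (per-part geometric means,
  re-closed), identical to clr_inv of the mean clr vector; both routes are
  computed and asserted to agree to 1e-9.
* **Dispersion**: the variation matrix T with T_ij = var(ln x_i/x_j)
  (unbiased, N−1 denominator, matching the convention of the R toolchain
  this field uses). The total (metric) variance is ΣT/(2D), equal to the
  trace of the clr covariance.
* **Mean-ratio matrix**: M_ij = g_i/g_j = exp(mean ln x_i/x_j), with
  reciprocal symmetry M_ij·M_ji = 1.
* **acomp PCA**: eigen-decomposition of the clr covariance centred at the
  clr of the geometric mean. D−1 components; eigenvalues sum to the metric
  variance. Biplot rays are √λ_k-scaled loadings; for D=3 with both
  components kept, the link length between two rays equals the SD of that
  pairwise log-ratio exactly. Component signs are fixed by making each
  component's largest-magnitude loading positive.
* **Zero handling**: log-ratios require strict positivity; zeros are
  replaced multiplicatively (zeros → δ, non-zeros scaled by 1−zδ,
  default δ = 1e-3, warning logged). δ must stay below the smallest
  non-zero part divided by D.

### Regions on the simplex

Two ellipse constructions, both built in ilr coordinates and
back-transformed as 256-point closed polylines (the generating ellipse is
retained so membership tests are exact rather than polygon-based):

* **k-sigma regions** describe the spread of individual diets: Mahalanobis
  radius k under the ilr *sample covariance*, centred at the ilr mean. For
  3-part data the ilr space is bivariate, so the k=2 ellipse contains
  1−exp(−k²/2) ≈ 86.5% of logistic-normal mass, not the univariate 95%;
  the univariate 68-95-99.7 figures sometimes quoted for such plots do not
  carry over to two dimensions, and we implement (and test) the bivariate
  geometry.
* **Confidence regions** describe uncertainty of the *mean*: Hotelling-T²
  ellipse with shape S/N and squared radius p(N−1)/(N−p)·F_{p,N−p}(α),
  p = D−1. Coverage is verified by simulation (90% nominal, ±2% over
  1000 replicates).

## Inference

ilr-space linear models share one design matrix across the D−1
coordinates. Season is a 3-level factor (spring < summer < autumn) with
treatment coding and spring as the reference level; subsidy is binary with
natural as reference; winter diets (rare) are excluded from inference but
kept in estimates. Factor effects are tested jointly with Wilks' lambda
via the Rao F approximation — exact for two response coordinates, and
verified against an independent MANOVA implementation to machine
precision — with Pillai's trace as an option. The global test is invariant
to factor coding and ilr basis.

Univariate cross-checks fit OLS to the logit of each macronutrient's
decimal proportion with orthogonal polynomial contrasts over the ordered
seasons, reporting the linear-trend contrast. In simulation with a strong
seasonal trend, the logit models agree in sign with the compositional
group means in >95% of replicates.

Cook's distances are computed in stacked ilr coordinates: the coordinate
models share the design matrix, so each observation has one leverage; its
squared residuals are pooled across coordinates and scaled by
p_total = q·(D−1) parameters and the pooled residual variance. The
threshold is left to the user (the conventional 4/N is only a plotting
mark); sensitivity refits excluding flagged populations are supported via
the `--drop` CLI flag.

Diets are compared to the intake target of captive brown bears — the
self-selected optimum of 17% protein energy with a ±4 band — by
classifying the protein part as below/within/above the band and reporting
the signed gap.

## Synthetic data

The generator defines the study conditions used throughout the tests.

* **Composition level**: logistic-normal draws (Gaussian in ilr around
  ilr(mean), back-transformed). PCG64 generator, seed mandatory.
* **Study level**: 19 populations by default, three active seasons each,
  subsidy group assigned with probability 0.5. Each population-season
  draws a true diet around its group-by-season geometric mean; the
  defaults are the published group-by-season means of the brown-bear
  scat-study compilation this package is designed around (natural spring
  0.493/0.159/0.348 … anthropogenic autumn 0.142/0.532/0.326), so the
  synthetic group structure mimics the real one: subsidized populations
  higher in carbohydrate and lower in protein, protein declining from
  spring to autumn.
* The default ilr covariance is derived from the published annual
  variation matrix (P–C 0.700, P–L 0.197, C–L 0.577) by double-centring
  (clr covariance G = −HTH/2), scaled by 0.25 so it represents
  within-group-and-season scatter rather than total annual scatter;
  carbohydrate log-ratios remain the most variable by construction.
* The true diet is expressed as a %DDM profile over a 9-food library
  whose first three entries are near-pure P/C/L anchors (the rest are
  realistic mid-simplex foods receiving a random 20% share, halved until
  the anchors can absorb the remainder non-negatively); expected %Vol is
  obtained by dividing the profile by the CFs and renormalizing — the
  exact inverse of the estimation chain — and finally perturbed with
  Dirichlet noise of concentration 300 (np.inf = noise-free). In the
  noise-free limit the estimator recovers the truth to 1e-9, and the mean
  reconstruction error decreases with concentration.
* Presets: `natural-vs-anthropogenic` (default structure), `null` (all
  means equal — type-I calibration), `seasonal-trend` (season the only
  effect).

What the generator does **not** emulate: scat-count sampling error within
a season (noise is a single Dirichlet perturbation of the %Vol profile,
not per-scat multinomial sampling), food-nutrient measurement error,
correlation between a population's seasons beyond the shared group mean,
and any spatial or climatic structure. Passing tests therefore demonstrate
correctness of the algebra and calibration of the inference under a
logistic-normal/Dirichlet world, not robustness to every failure mode of
literature-derived diet data.

## Numerical choices

* Closure tolerance 1e-9; algebraic identities asserted at 1e-9; routes
  through eigen-decompositions at 1e-6 or better.
* Compositions are stored as decimal fractions; tables serialize to CSV
  at six decimals (presentation rounding to three is available in the
  CLI); SVG output uses a fixed hash salt and no timestamps so identical
  scenes are byte-identical.
* Simulation sizes in the test suite (600–1000 replicates for calibration
  checks, n = 10 000 for law-of-large-numbers recovery, 19–30 populations
  for pattern checks) were chosen as the smallest sizes at which the
  Monte-Carlo standard error is comfortably below the asserted tolerance.

## Known limitations

* The published per-population annual diet table ships with the original
  study's supplementary files and is not redistributed here; the
  full-study reproduction test states exactly what it would verify and
  fails with that explanation when the fixture is absent.
* Exact published p-values are not reproducible without knowing the exact
  test statistic used; only direction and significance patterns are
  checked.
* No robust (outlier-resistant) compositional estimators, no Bayesian
  treatment, no D>3 visualization.
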