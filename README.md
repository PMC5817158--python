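# macroniche

Macronutrient niche estimation for wild omnivores from scat data, with
compositional (Aitchison) statistics.

Diet studies of free-ranging omnivores such as the brown bear usually
report each food as a percent of fecal volume (%Vol). `macroniche` turns
those records into population diet compositions — protein (P),
carbohydrate (C) and lipid (L) as fractions of metabolizable energy — and
analyzes them on the 3-part simplex, where only relative information is
meaningful:

* **Estimation**: %Vol × fecal correction factor, renormalized to %DDM
  (digestible dry matter share); food macronutrient masses converted to
  energy with 17 kJ/g (protein, carbohydrate) and 37 kJ/g (lipid); diets
  composed as %DDM-weighted energy fractions; seasonal profiles averaged
  (unweighted) into annual diets.
* **Descriptive statistics**: closed geometric mean
  `g = C(∏ᵢ x₁ᵢ^(1/N), …)`, mean pairwise-ratio matrix `M_ij = g_i/g_j`,
  variation matrix `T_ij = var(ln x_i/x_j)`, total metric variance, and
  principal components in acomp geometry (eigen-decomposition of the clr
  covariance) with biplots and curvilinear simplex axes.
* **Inference**: linear models on isometric log-ratio (ilr) coordinates
  with multivariate ANOVA (Wilks' lambda / Pillai trace) for season and
  anthropogenic-subsidy effects, logit-LM univariate cross-checks,
  Cook's-distance influence diagnostics, 2σ/3σ spread regions and
  Hotelling-T² confidence regions for means.
* **Nutritional geometry**: equilateral and right-angled mixture
  triangles with isoportion lines (e.g. the 17% ± 4 protein intake target
  of captive bears) and 1:1 isoproportion lines, rendered to
  deterministic SVG.
* **Simulation**: logistic-normal composition sampling and a full
  forward model of the scat measurement process with known ground truth,
  so the whole pipeline is testable without any external data.

## Worked example

Simulate a 19-population study, estimate diets and summarize them:

```sh
macroniche simulate --preset natural-vs-anthropogenic --seed 11 --out sim
cat > cfg.yaml <<EOF
fecal_records: sim/fecal_records.csv
cf_table: sim/correction_factors.csv
food_table: sim/food_energy.csv
subsidy_table: sim/subsidy.csv
output_dir: out
EOF
macroniche estimate --config cfg.yaml
macroniche model --config cfg.yaml --table out/seasonal_diets.csv --factors season,subsidy
macroniche pca --config cfg.yaml --table out/annual_diets.csv
```

which prints

```
wrote 57 seasonal and 19 annual estimates
ANOVA season: Wilks' lambda=0.2927 F(4,104.0)=22.060 p=3.322e-13
ANOVA subsidy: Wilks' lambda=0.5352 F(2,52.0)=22.584 p=8.718e-08
explained shares: 90.2%, 9.8%
```

Season and subsidy both shift diet composition strongly (tiny Wilks'
lambda, p ≪ 0.001): subsidized populations eat relatively more
carbohydrate and less protein, and protein declines from spring to
autumn. The first acomp principal component — dominated by the
carbohydrate–protein contrast — carries ~90% of the log-ratio variance.
`out/` also receives per-group summary tables (geometric mean, mean-ratio
matrix, variance matrix), influence tables and logit-trend fits;
`macroniche plot` draws the diets in a mixture triangle with the intake
target band.

The same API is available from Python:

```python
>>> from macroniche import closure, CompositionSet, mean_ratio_matrix
>>> s = CompositionSet.from_compositions([closure((0.422, 0.212, 0.366))])
>>> mean_ratio_matrix(s).round(3)[1, 0]   # carbohydrate : protein
0.502
```

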