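# edaphoniche

Tools for estimating the edaphic niches of Amazonian understory plants from
field plots and digital soil maps, and for measuring how much of that niche
signal survives the maps' thematic and georeferencing errors.

## The problem

Species distribution models for Amazonia need soil information, but field
soil data are sparse: what is available wall-to-wall are digital soil maps —
polygon class maps, per-class occurrence-probability rasters, and a cation
exchange capacity (CEC) layer. The question this package addresses is
whether those map products carry enough signal about the **exchangeable
base-cation concentration** (Ca + Mg + K in surface soil, cmol(+)/kg) — the
soil variable that most strongly structures Amazonian plant communities —
to recover species' positions along that gradient without field sampling.

The core statistic is the weighted-averaging (WA) niche estimate. For taxon
*k* with abundance *y<sub>ik</sub>* in plot *i* and gradient value
*x<sub>i</sub>* (log cation concentration),

- optimum: *u<sub>k</sub>* = Σ<sub>i</sub> *y<sub>ik</sub> x<sub>i</sub>* / Σ<sub>i</sub> *y<sub>ik</sub>*
- tolerance: *t<sub>k</sub>* = √( Σ<sub>i</sub> *y<sub>ik</sub>* (*x<sub>i</sub>* − *u<sub>k</sub>*)² / Σ<sub>i</sub> *y<sub>ik</sub>* )

computed over the plots where the taxon occurs. Around it sit the
map-evaluation statistics: per-class cation summaries (with the
within-class range in orders of magnitude), one-way ANOVA with
Tukey–Kramer contrasts between soil classes, the cation–CEC Pearson
correlation, OLS regressions of log cation on class-probability layers
(± CEC) with forward–backward stepwise AIC selection, and Kendall tau-b
comparisons of optimum rankings between gradients.

Because real plot networks and map products are large external downloads,
the package ships a synthetic soil-landscape and coenocline community
generator (`edaphoniche.landscape`) that reproduces their statistical
structure — Voronoi class mosaics whose within-class cation values span two
orders of magnitude, a CEC surrogate correlated with log cation at r ≈ 0.1,
Gaussian-response fern communities, and rigid map displacement — so every
stage is testable at desk scale against known truth.

## Worked example

```python
import edaphoniche as en

report = en.run_study(en.StudyConfig(seed=1))   # bundled synthetic study
print("pearson r=%.3f p=%.3g" % report.pearson)
print(report.models.head(4)[["dataset", "source", "cec", "adj_r2", "n"]])
print(report.tau.round(2))
```

prints

```
pearson r=0.080 p=0.00196
dataset      source   cec   adj_r2   n
  PPBio     polygon False 0.435289 326
  PPBio     polygon  True 0.435289 326
  PPBio probability False 0.425918 326
  PPBio probability  True 0.425918 326
gradient   cec  predicted(polygon)  predicted(polygon+cec)  predicted(probability)  predicted(probability+cec)
dataset
Both      0.64                1.00                    1.00                    1.00                        1.00
PPBio    -0.28                0.97                    0.97                    0.95                        0.95
UTU       0.72                1.00                    1.00                    1.00                        1.00
```

Reading this: the CEC layer correlates with measured log cation at only
r = 0.08 on this landscape, and the optima ranked along it are erratic
(tau between −0.28 and 0.72 against the field ranking, depending on the
dataset), while optima ranked along the regression-predicted cation
gradients track the field ranking almost perfectly (tau ≥ 0.95). The model
table reports one stepwise-selected fit per dataset × map-source × ±CEC
combination (16 rows in the default study); `report.niches` holds the
optimum/tolerance table per gradient and `report.envelopes` the combined
UTU/PPBio tolerance envelopes.

The same study runs from a shell:

```sh
edaphoniche run --seed 1 --out study_out/
edaphoniche simulate --seed 3 --n-plots 500 --out sim/
edaphoniche extract --plots sim/plots.csv --stack sim/stack --out extracted.csv
edaphoniche model --extracted extracted.csv --cec --out fit.json
```

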