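# metidx

Metabolic-index habitat analysis for marine ectotherms: calibrate the
index from respirometry trials, project it over gridded ocean layers, and
extract the critical thresholds that delimit a species' geographic range.

## The model

The metabolic index φ is the ratio of environmental oxygen supply to
resting oxygen demand,

    φ = pO₂ / pO₂crit(T, B),      pO₂crit(T, B) = Bⁿ · A₀ · exp(E₀ / (k_B T)),

where pO₂ is ambient oxygen partial pressure (kPa), pO₂crit the critical
oxygen partial pressure below which a standard metabolic rate cannot be
sustained, B body mass (kg) with scaling exponent n, T absolute
temperature, and k_B the Boltzmann constant (8.617333×10⁻⁵ eV K⁻¹).
φ = 1 means the environment barely sustains resting metabolism; mobile
fish typically need φ of roughly 2–5.

Hypoxia tolerance can be *bidirectional* — pO₂crit minimal at an
intermediate temperature and rising both on warming (demand-driven) and on
cooling (supply-driven) — so (A₀, E₀) are fit piecewise around a breakpoint
temperature (default 12 °C) by OLS of ln(pO₂crit/Bⁿ) on the Arrhenius
coordinate 1/(k_B T). With a bidirectional calibration, φ can delimit
*both* edges of a coastal species' range: the warm edge through rising
demand, and the cool edge through upwelling-driven hypoxia.

The pipeline:

1. **respirometry** — SMR (0.2 quantile of routine rates), MMR (post-chase
   maximum), and O₂crit as the intersection of the SMR line with the OLS
   fit through the sub-SMR oxyconforming decline (≤ 15 lowest-saturation
   points, with an automated overestimate heuristic that refits with 4).
2. **calibration** — mass exponent n (iterated temperature/mass
   standardization) and the piecewise Arrhenius branches; group-effect
   (area, sex stage) pooling checks.
3. **env_layers** — coastal gap filling, factor-2 bilinear refinement,
   O₂ concentration → pO₂ (Garcia–Gordon solubility, Weiss–Price vapour
   pressure, Saunders pressure at depth), monthly φ / aerobic-scope layers
   and min/mean/max aggregates over a multi-year period.
4. **sdm** — k = 10 random forests on presence cells vs per-model
   pseudo-absence draws (80/20 splits); the critical index φ_crit from a
   logistic regression on the binarized sign of tree-path feature
   contributions (an exactly additive decomposition of each predicted
   probability), and the suitable-depth window from binned contribution
   zero crossings; ensemble agreement maps (0–100).
5. **synthetic_data** — planted-truth generators for respirometry cohorts,
   seasonal ocean grids with a warm edge and a hypoxic cool edge, and
   occurrence points, so every stage is testable by parameter recovery.

## Worked example

Simulate a planted world and run the full pipeline from the shell (a seed
makes everything reproducible):

```sh
metidx simulate --out data --seed 3
metidx pcrit   --traces data/respirometry.csv --out pcrit.csv
metidx phi-fit --pcrit pcrit.csv --out params.yaml
metidx project --params params.yaml --env data/env_contemporary.nc --out layers.nc
metidx sdm     --layers layers.nc --occurrences data/occurrences.csv \
               --out sdm_out --seed 3
```

which prints

```
wrote cohort (40 trials), environment and 150 occurrence points to data
40 trials -> pcrit.csv (0 adjusted to 4 regression points)
n = 0.158; upper E_o = -0.4774 eV, lower E_o = 1.0227 eV -> params.yaml
phi layers -> layers.nc
{
  "n_points": 150,
  "n_presence_cells": 125,
  "mean_accuracy": 0.968,
  "phi_crit": 2.911139872746007,
  ...
  "depth_window_m": [12.02825232123072, 75.88005219388486]
}
```

The planted truth behind this run was n = 0.17, E₀ = −0.4885 eV above and
+1.01 eV below 12 °C, φ_crit = 3.0 and a 13–75 m depth window: the fitted
exponent and branch slopes recover the planted respirometry law from 40
noisy trials, and the forest ensemble — trained only on occurrence cells
and pseudo-absences — localizes the planted habitat thresholds, with the
residual gap (2.91 vs 3.0) reflecting both calibration noise and grid
granularity.

The same stages are available as a library:

```python
import metidx

params = metidx.published_parameters()   # calibrated roman seabream values
metidx.po2crit_predict(params, 16.0, 1.0)   # 4.77 kPa
metidx.phi(params, 16.0, 1.0, 18.0)         # 3.77
```

## Layout

```
src/metidx/      respirometry, calibration, env_layers, sdm, synthetic_data, cli
tests/           pytest suite (unit, property and end-to-end recovery tests)
docs/methods.md  model, assumptions, numerical choices, limitations
```
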