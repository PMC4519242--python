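# pantherscape

Landscape-scale habitat modelling for the Florida panther (*Puma concolor
coryi*), packaged as a tested, reusable pipeline for grid-based
presence–absence species distribution analysis.

The Florida panther survives as a single breeding population in the
wetlands of south Florida. Deciding how much breeding habitat remains —
and where — requires turning heterogeneous spatial data (land-cover
polygons, water-level gauges, census blocks, roads, radio-telemetry) into
a per-km² probability of use by resident adults. `pantherscape`
implements that workflow end to end for anyone doing similar first-order
(range-within-region) habitat analysis:

* **Covariate engineering** on a 1-km² grid: exact polygon-overlay cover
  fractions for 10 aggregated cover classes, a forest-edge metric (prey
  proxy), seasonal water-depth surfaces from gauge stages and elevation
  (IDW interpolation; depth = stage − ground), area-weighted human
  density, and road density with trail classes excluded.
* **Presence labels from telemetry** filtered to resident breeding adults
  (2004–2013 window, age ≥ 3 yr at fix, ≥ 50 fixes per animal), plus 100%
  minimum-convex-polygon home ranges and a Wilcoxon rank-sum comparison
  of home-range quality between sexes.
* **A random-forest presence classifier** (500 trees, 3 variables per
  split) with out-of-bag probabilities, the equal-sensitivity/specificity
  habitat cutoff, accuracy metrics (PCC, sensitivity, specificity, kappa,
  AUC) under resubstitution / OOB / 10-fold CV, and permutation + Gini
  variable importance standardized to the top variable.
* **Stratified sensitivity analysis**: one-at-a-time response curves
  anchored at the mean covariate vectors of excellent (P 0.85–0.95),
  medium (0.45–0.55) and poor (0.05–0.15) habitat strata.
* **Habitat accounting**: thresholded habitat maps, zone summaries,
  category area tables, and carrying-capacity arithmetic.
* **A synthetic-landscape generator** with known ground truth (planted
  preference coefficients, a water-depth optimum at −0.6 m, two designated
  null covariates) so every stage is validated by parameter recovery —
  no external data needed.

The model and conventions are documented in [docs/methods.md](docs/methods.md).

## Worked example

Build a synthetic landscape, fit the model, and account for habitat:

```python
import pantherscape.model as pmodel
import pantherscape.synth as psynth
from pantherscape.cover import EdgeRules
from pantherscape.features import assemble_features
from pantherscape.hydrology import SeasonConfig, seasonal_depth
from pantherscape.mapping import capacity, classify_map
from pantherscape.synth import SyntheticConfig
from pantherscape.telemetry import filter_fixes, label_presence
from shapely.geometry import box

cfg = SyntheticConfig(seed=1)                      # 60 x 60 km, 20 animals
layer = psynth.generate_cover(cfg)
elevation, gauges, _ = psynth.generate_hydrology(cfg)
blocks, roads = psynth.generate_anthropogenic(cfg)

table = assemble_features(cfg.grid, layer, blocks, roads, EdgeRules())
table = table.join(seasonal_depth(gauges, elevation, cfg.grid, SeasonConfig()))

fixes, truth = psynth.simulate_telemetry(cfg, table)
kept, counts = filter_fixes(fixes, study_area=box(*cfg.grid.bounds))
table["presence"] = label_presence(cfg.grid, kept)

model = pmodel.fit(table, pmodel.ModelConfig(seed=1))
thr = pmodel.select_threshold(model.labels.to_numpy(), model.oob_P.to_numpy())
oob = pmodel.accuracy_metrics(model.labels, model.oob_P, thr.threshold, "out_of_bag")
habitat = classify_map(table.assign(P=model.oob_P), thr.threshold)

print(f"threshold (sens = spec): {thr.threshold:.3f}")
print(f"OOB: PCC {oob.pcc:.1f}%  sens {oob.sensitivity:.1f}%  "
      f"spec {oob.specificity:.1f}%  kappa {oob.kappa:.2f}  AUC {oob.auc:.2f}")
print(f"breeding habitat: {habitat.habitat_km2:.0f} km^2 "
      f"({habitat.habitat_km2 / cfg.grid.n_cells:.0%} of the landscape)")
print(f"capacity at 2.80 adults/100 km^2: {capacity(habitat.habitat_km2):.0f} adults")
```

Output:

```
threshold (sens = spec): 0.384
OOB: PCC 91.6%  sens 91.6%  spec 91.6%  kappa 0.80  AUC 0.97
breeding habitat: 1178 km^2 (33% of the landscape)
capacity at 2.80 adults/100 km^2: 33 adults
```

Reading this: the cutoff 0.384 is where the model's sensitivity and
specificity meet, so present and absent cells are classified equally well
(91.6% each) and the flagged habitat fraction (33%) approximates the
observed prevalence. Kappa 0.80 and AUC 0.97 say the separation is far
above chance. Because the generator planted the preferences, the
recovered effects are checkable: the importance ranking puts the depth,
forest and human-pressure covariates above the two β = 0 null covariates,
and the dry-depth response curve peaks within half a metre of the planted
−0.6 m optimum.

The same workflow runs from the shell:

```bash
pantherscape synth --seed 1 --out work/           # landscape + telemetry inputs
pantherscape run --config run.yaml                # whole pipeline, manifest + outputs
```

`pantherscape run` executes synth → features → hydro → telemetry → fit →
cv → importance → sensitivity → map, writes every intermediate artifact
(GeoJSON layers, feature-table CSV, accuracy JSON, importance CSV,
response-curve CSV/PNG, habitat map, zone summary) plus a manifest with a
config fingerprint and result hash; re-running a config reproduces the
hash bit-for-bit.

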