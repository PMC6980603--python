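# windstrike

Collision-potential and strike-susceptibility modelling for birds at
wind turbines.

Carcass searches beneath wind turbines yield presence/pseudo-absence
records of collision victims. For wide-ranging raptors such as the
common buzzard (*Buteo buteo*), which occur almost everywhere in a
planning region, simple distance-to-nest buffers do not work; instead,
collision risk can be related to the landscape context of each turbine.
`windstrike` implements that workflow end to end:

1. **DELVs** — signed Euclidean distance-to-edge land-use variables.
   For each of 12 land-use classes (fields, forests, grass/forbs,
   flowing and still watercourses, bushlands, shrublands, settlements,
   green areas around settlements, ruderal areas, special biotopes,
   wetlands) the class polygons are rasterized at 100 m and every cell
   receives the Euclidean distance to the nearest class edge, negative
   inside the class and positive outside.
2. **Training data** — turbines with target-species carcass detections
   are presences; turbines where only other bird groups were detected
   are pseudo-absences; detections of the target's own family
   (Accipitridae) are excluded, and the majority label is down-sampled
   to a 1:1 balance.
3. **Boosted regression trees (BRT)** — a from-scratch forward-stagewise
   ensemble of shallow regression trees fitted to the Bernoulli-deviance
   gradient (logit link), with tree complexity *tc*, learning rate
   *lr*, bag fraction *bf*, and the tree count *nt* selected by stepped
   10-fold cross-validation, walking down a learning-rate ladder
   (0.05 … 0.0005) until the selected ensemble holds at least 1000
   trees. Interpretation: relative influence from squared split
   improvements, partial-dependence curves, pairwise interaction sizes,
   and backward simplification (drop the least influential predictors,
   refit, compare cross-validated deviance).
4. **Risk maps** — the fitted model predicts a collision potential
   CP ∈ [0, 1] per cell; combined with the regional breeding-pair
   density map (6 classes with lower borders 1, 2, 4, 8, 21, 51 BP) it
   yields the strike-susceptibility index

   SC = CP × BPDrel × 100,  BPDrel = BPDobs / BPDmax,  BPDmax = 51,

   which is binned into five zones (0–20 … 81–100 %) and intersected
   with the turbine table to count planned turbines per zone.

Because the original state-wide carcass, turbine and biotope data are
not publicly deposited, the package ships a fully synthetic landscape
generator with known ground truth (a seeded region-growing mosaic
matching the published class coverages, uniform turbine scatter, and a
four-driver generative risk surface), so every stage is testable.

## Worked example

```python
import numpy as np
import windstrike as ws
from windstrike.brt import BRTConfig, boost, evaluate, relative_influence
from windstrike.delv import build_delv_stack, sample_delv
from windstrike.training import TrainingSet, downsample_balance

# 1. synthetic study region: 12-class mosaic on a 100 m grid
config = ws.LandscapeConfig(extent=(10000, 10000), seed=1)
layers = ws.generate_landscape(config)
stack = build_delv_stack(layers, config.grid)

# 2. turbines, collision outcomes, balanced training table
turbines = ws.generate_turbines(800, config.grid, seed=2)
sim = ws.simulate_collisions(turbines, stack, ws.default_risk_spec(), seed=3)
feats = sample_delv(stack, sim)
feats["label"] = sim["outcome"].to_numpy()
training = TrainingSet(downsample_balance(feats, seed=4))

# 3. boosted regression trees, influence and holdout discrimination
idx = np.arange(len(training))
train, test = training.subset(idx % 4 != 0), training.subset(idx % 4 == 0)
model = boost(train, BRTConfig(tc=5, lr=0.05, seed=5), nt_fixed=300)
print(relative_influence(model).head(4).round(1).to_string())
print(f"holdout AUC: {evaluate(model, test).auc:.3f}")

# 4. strike susceptibility across the region
density = ws.generate_density_map(config.grid, 5000, seed=6)
cp = ws.predict_cp_raster(model, stack)
sc = ws.strike_susceptibility(cp, ws.relative_density(density, config.grid))
print(f"SC range: {sc.values.min():.2f} .. {sc.values.max():.2f} %")
```

Output:

```
GF    26.8
B     12.5
GS    12.2
FW     7.8
holdout AUC: 0.922
SC range: 0.05 .. 15.65 %
```

The four variables with the highest relative influence are exactly the
four classes whose distances drive the simulated risk surface
(grass/forbs, bushlands, green areas around settlements, flowing
watercourses); the holdout AUC shows the ensemble recovers most of the
generative signal. SC stays far below 100 % wherever either the
collision potential or the local breeding-pair density is moderate.

## Command line

```sh
windstrike run-all --seed 7 --out run7          # full synthetic pipeline
windstrike run-all --config my_config.yaml      # custom configuration
```

`run-all` writes land-use layers (GeoJSON), DELV rasters (GeoTIFF),
the turbine and training tables (CSV), the fitted model (JSON), CP/SC
class rasters, the zone-count table, point-density surfaces and a
manifest with seeds, metrics and file hashes. Subcommands `simulate`,
`delv`, `train`, `predict`, `susceptibility` and `report` expose the
individual stages.

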