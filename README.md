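# riverwq

Water Quality Index scoring and multiscale land-use/land-cover (LULC)
buffer analysis for river monitoring networks.

River water quality responds to what happens on the land around it:
wastewater outfalls and urban runoff act as point sources, while cropland
fertilization and the loss of natural vegetation act as diffuse pressures.
`riverwq` is a toolkit for analysts who have (a) repeated physicochemical and
microbiological measurements at fixed sites along a river and (b) categorical
LULC rasters of the surrounding landscape, and who want to quantify how
landscape composition at different spatial scales relates to water quality,
season by season.

## The model

Each measurement record is scored with a banded Water Quality Index:

```
WQI = Σᵢ Cᵢ · Pᵢ / Σᵢ Pᵢ
```

where, for each of twelve parameters (conductivity, dissolved oxygen,
turbidity, nitrite, nitrate, ammonium, hardness, chloride, sulfate, total
coliform bacteria, temperature, pH), `Cᵢ ∈ {0, 10, …, 100}` is a
normalization score from a banded lookup table (Pesce–Wunderlin convention)
and `Pᵢ` is an integer relative weight (dissolved oxygen weighs 4, ammonium
and coliforms 3, …; the weights sum to 24). WQI runs from 0 (worst) to 100
(best) and is reported overall and stratified into the warm/wet season
(December–April) and the cold/dry season (May–November).

Landscape composition is extracted per site at two scales: a **local**
1,000 m circular buffer and a **regional** corridor following the river
channel 20 km upstream with a 5 km total width. Composition (percentage of
valid pixels per LULC class, pixel-center rule) is then related to
site-level water quality through Pearson correlation matrices with
two-sided t-transform p values, one-way ANOVA across sites, PCA on the
correlation matrix with eigenvalue ≥ 1 retention, and Ward-linkage
hierarchical clustering of sites on standardized variables. Cropland can be
refined into seasonal crop subtypes (corn, soy, alfalfa, fallow, winter
cereals, horticulture) before the seasonal correlation pass.

Because real monitoring datasets of this kind are rarely public, the package
ships a first-class synthetic riverscape generator (`riverwq.synth`) with a
known generative model — planted landscape→chemistry effects, seasonal
offsets, a wastewater dissolved-oxygen crash with downstream decay, and
controlled class fractions — so the entire pipeline is testable end to end
and effect recovery can be scored against ground truth.

## Worked example

```python
from riverwq import SceneConfig, generate_scene, RunConfig, run_pipeline, write_scene
import pandas as pd

cfg = SceneConfig(seed=1, river_length_m=30_000, cell_size_m=40,
                  margin_m=2600, sinuosity_amplitude_m=800,
                  sinuosity_wavelength_m=12_000, blob_size_m=1200)
scene = generate_scene(cfg)
write_scene(scene, "demo_scene")
run_pipeline(RunConfig(scene_dir="demo_scene", out_dir="demo_run"))

wqi = pd.read_csv("demo_run/wqi.csv")
print(wqi[wqi.scope == "overall"].set_index("site_id")["wqi"].round(1).to_string())
```

prints the overall WQI of the eleven sites, ordered SS1 (upstream) to SS11:

```
SS1     80.9
SS2     81.2
SS3     68.1
SS4     68.8
SS5     68.2
SS6     68.8
SS7     36.2
SS8     37.9
SS9     39.4
SS10    40.2
SS11    46.1
```

The two upstream sites (natural vegetation) score best; quality degrades
through the urban reach, bottoms out at SS7 — the site at the synthetic
wastewater outfall, where dissolved oxygen crashes — and only partially
recovers downstream under cropland pressure. Continuing,

```python
corr = pd.read_csv("demo_run/correlation.csv")
cell = corr[(corr.scale == "local") & (corr.season == "base")
            & (corr.variable == "wqi") & (corr.lulc_class == "cropland")].iloc[0]
print(f"cropland vs WQI (local): r={cell.r:.2f} ({cell.tier})")

pca = pd.read_csv("demo_run/pca_summary.csv")
print(f"retained PCs: {int(pca.retained.sum())}, "
      f"variance shares: {pca.pct_variance.round(0).astype(int).tolist()[:3]}")
```

```
cropland vs WQI (local): r=-0.97 (p<0.01)
retained PCs: 3, variance shares: [60, 15, 12]
```

The planted negative cropland effect is recovered as a strong negative
correlation, and three principal components pass the eigenvalue ≥ 1
retention rule on this scene. The same analysis is available from the shell:

```
riverwq simulate --seed 1 --n-sites 11 --out demo_scene
riverwq run --scene demo_scene --out demo_run
```

with additional subcommands `wqi`, `buffers`, `correlate`, `pca`, `cluster`
and `report` for the individual stages.

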