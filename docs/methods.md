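# Methods

This note documents the scientific conventions implemented in `riverwq`:
the index model, the buffer geometry, the association statistics, the
synthetic riverscape generator, and the numerical choices made where the
underlying convention is ambiguous.

## Water Quality Index

The index is the weighted mean `WQI = Σ Cᵢ·Pᵢ / Σ Pᵢ` over twelve
parameters. Each parameter value is normalized to a score
`Cᵢ ∈ {0, 10, …, 100}` by a banded lookup table (Pesce–Wunderlin
convention for Argentine river monitoring); the integer weights are
conductivity 2, dissolved oxygen 4, turbidity 2, nitrite 2, nitrate 2,
ammonium 3, hardness 1, chloride 1, sulfate 2, total coliforms 3,
temperature 1, pH 1 (sum 24). Assumed units follow the same convention:
µS/cm (conductivity), mg/L (solutes and dissolved oxygen), NTU
(turbidity), MPN/100 mL (coliforms, scored on the raw scale with no log
transform), °C, and pH units.

Band semantics, where the printed table is ambiguous, are resolved as
follows and apply uniformly:

* **Strict comparators are literal.** A value equal to a strict threshold
  fails that band and falls to the next: turbidity 5 scores 90 (not 100),
  dissolved oxygen 7.0 scores 80.
* **Second-worst band is inclusive.** For the nine "smaller is better"
  rows the score-10 cell is an inclusive upper bound (e.g. nitrite
  ≤ 1.00 → 10, > 1.00 → 0); this is the only reading that leaves no gap
  before the residual 0 band.
* **Temperature** bands are widening nested closed intervals
  ([16, 21] → 100 out to [−6, 45] → 10); outside the widest interval
  scores 0.
* **pH** bands are overlapping closed intervals resolved by first match
  scanning from the best score down ([7, 8] → 100, …, [1, 14] → 10); the
  worst non-zero band is taken as the full usual pH scale, so only
  pH < 1 (or > 14, which the record model already rejects) scores 0.
* Scoring always takes the **first matching band from 100 downward**, so
  every finite value in a parameter's domain maps to exactly one score.

Seasonal aggregation indexes each record first and then averages:
per-site seasonal WQI is the mean of the per-record WQIs in that season,
the overall WQI is the mean over all records, and a scope with no records
is reported absent rather than zero. The alternative (average the raw
measurements, then index) is deliberately not used — the band
nonlinearity makes the two orders differ, and indexing first keeps each
record's violations visible.

Missing parameters are an error by default (`missing_policy="strict"`);
`"renormalize"` drops them and shrinks `Σ Pᵢ`, reporting the omissions.
With all twelve present the two policies agree exactly.

Guideline exceedance flagging is configuration-driven; only three limits
ship as defaults (nitrite ≤ 0.2 mg/L, dissolved oxygen ≥ 4 mg/L, and the
ammonium safe window 0.05–0.47 mg/L). A "range" guideline is only
violated above its upper edge: toxicity increases with concentration, so
a value below the window is not flagged. The season calendar (summer =
December–April) is configurable.

## Buffer geometry and zonal composition

The local buffer is a circle (default radius 1,000 m) discretized at 256
segments, keeping its area within ~0.01% of πr². The regional buffer
follows the channel: the river sub-polyline of arc length up to 20,000 m
upstream of the site's projection onto the line, dilated by half the
5,000 m width on each side with flat ends. On a straight river this is an
exact 20 km × 5 km rectangle; on a sinuous river it hugs the bends, which
we consider truer to "upstream influence" than an axis-aligned box. A
site whose upstream reach is shorter than the configured length gets a
truncated corridor with the truncation reported; a site more than 200 m
(configurable) from the line is an error. Arbitrary radii/lengths are
accepted so users can scan intermediate scales; the defaults are the two
published scales.

Composition uses the pixel-center rule by default (a pixel belongs to the
buffer if its center is inside the polygon), matching the "% of pixels"
definition; an exact area-weighted rule is available
(`center_rule="area"`). Nodata pixels are excluded from the denominator
and counted separately, percentages are over valid pixels and sum to 100,
the water class (the river itself) counts like any other class, and
overlapping buffers of neighboring sites are independent rows.

Cropland refinement replaces base-map cropland pixels with the seasonal
crop map's code where present and with `not_classified_crops` where the
crop map has nodata; non-cropland pixels are never altered, so collapsing
the subtypes reproduces the base cropland mask pixel for pixel.

Rasters are single-band integer grids, north-up with square cells in a
projected meter CRS, exchanged as Esri ASCII grids with a YAML sidecar
(CRS label, season tag, code→name legend). CRS handling is an equality
check on the label — reprojection is out of scope, inputs must share one
projected CRS.

## Association statistics

* **ANOVA**: one-way fixed effects across sites; every site needs ≥ 2
  records. Zero within-group variance with unequal means is reported as
  the p → 0 limit with an explanatory note.
* **Pearson matrices**: pairwise-complete r between LULC class
  percentages and site-level variable means (or WQI), with two-sided p
  from the exact t transform and the conventional star tiers (ns,
  p < 0.05, p < 0.01). Zero-variance columns yield an *undefined* r
  (NaN), never 0. No multiple-testing correction by default, mirroring
  per-cell star reporting; Benjamini–Hochberg is available behind a flag.
  Sites are aggregated to means per scope before correlating (overall
  means against the base map; seasonal means against the seasonal crop
  maps), so n is the number of sites.
* **PCA** runs on the correlation matrix — the variables mix units, so
  covariance PCA would be dominated by conductivity and coliforms.
  Columns are standardized (SD with ddof = 1), eigenvalues/eigenvectors
  come from a symmetric eigendecomposition, components are signed so each
  component's largest-magnitude loading is positive, variance shares are
  eigenvalue/p, and the retained set is {eigenvalue ≥ 1} (Kaiser-type
  rule on standardized data). Zero-variance columns are an error
  instructing removal.
* **Clustering**: agglomerative, Ward linkage on Euclidean distances over
  standardized columns (defaults; both configurable), cut to k = 5
  clusters by default. Labels are renumbered 1…k by first appearance
  along the site index, so row reordering changes labels only up to
  relabeling, never the partition.

## Synthetic riverscape generator

The generator emulates the study system the package targets: a ~200 km
river in a semi-arid agricultural basin, 11 monitoring sites, two
seasonal sampling campaigns per year over two years (2 replicates per
season), an urban core mid-basin whose wastewater outfall crashes
dissolved oxygen, and a longitudinal land-cover gradient (natural
vegetation upstream → urban core → cropland downstream).

Layout: the river is a sine-meander polyline; the raster covers it plus a
margin. Classes are assigned by rank-thresholding smooth random "blob"
fields (coarse white noise, bilinear upsampling, default blob scale
1,500 m) with chainage-dependent zone weights. Rank-thresholding pins the
realized built-up and cropland pixel fractions to their targets (defaults
4.5% and 54%) to within a pixel; the natural remainder is split by
zone-weighted argmax. Cropland pixels get seasonal subtypes by quantiles
of another blob field with season-specific shares (summer dominated by
soy 48% and corn 35% of cropland; winter dominated by fallow 70%).

Water chemistry follows a linear mean model on the *local-buffer* class
fractions `f_c ∈ [0, 1]` computed from the base map with the package's
own zonal engine:

```
value = baseline + Σ_c β[c,param]·f_c + γ[param]·1[summer]
        + δ[param]·exp(−d_downstream/L) + Normal(0, sd[param])
```

clipped at 0 (pH to [4, 10]; temperature unclipped below). Total
coliforms are generated on the log10 scale and exponentiated (positivity,
heavy tail). The wastewater term applies from the outfall site (default
the 7th of 11) downstream with e-folding length L = 25 km. Default
baselines describe a lightly impacted reach (dissolved oxygen 8 mg/L,
conductivity 800 µS/cm, …); the default spike δ = (−6 mg/L DO,
+0.9 ammonium, +0.75 nitrite, +1.2 log10 coliforms) reproduces the
outfall pattern of an oxygen crash to ~2 mg/L with reduced-nitrogen
spikes. Default planted effects make cropland raise ammonium, nitrate,
chloride and turbidity, built-up raise conductivity, nitrite and
coliforms, and natural classes lower conductivity/hardness; the effect
magnitudes were chosen so that moving across the observed range of
cropland fraction shifts several parameters by a few bands (≈ 10 WQI
points), comfortably above the record-level noise. All randomness flows
from one numpy PCG64 generator seeded by the config, so a fixed seed
reproduces the scene byte for byte.

What the generator does *not* emulate: hydrological routing or pollutant
transport (effects are static site-level means), spatial autocorrelation
of measurement error, inter-annual trends, rating-curve/flow dependence
of concentrations, and real geography. Passing recovery tests therefore
show that the pipeline correctly extracts planted monotone
landscape–chemistry associations of realistic magnitude from realistic
composition variation — not that such associations are identifiable in
any particular real basin, where confounding between co-located classes
(which the generator does reproduce, e.g. built-up vs downstream
wastewater influence) can dominate.

## Problem sizes

The study-scale defaults (200 km river at 10 m cells) produce ~2·10⁷-pixel
rasters. The test suite and the acceptance script instead use two
down-scaled configurations chosen as the smallest scenes that still
exercise every code path: a *demo* scene (30 km river, 40 m cells, 11
sites — large enough to hold untruncated 20 km regional corridors for the
downstream sites) and a *recovery* scene (40 km river, 50 m cells, 50
sites, local scale only). Recovery studies default to 50 sites because 11
sites give weak power for moderate effects; both are plain config
switches. The Monte-Carlo checks run 200 scenes for effect recovery and
1,000 (tests) / 300 (acceptance script) null scenes for type-I
calibration, where the false-positive rate is pooled over the
(class, parameter) cells — each cell is a valid 5%-level test, and
pooling reduces the Monte-Carlo standard error of the estimated rate.

## Known limitations

* No reprojection: all inputs must already share one projected CRS.
* No unit conversion: measurements must arrive in the index's assumed
  units.
* The regional corridor is a fixed-width channel dilation; it does not
  clip to the watershed divide or exclude the far bank.
* Pearson correlation on ~11 sites has wide sampling error; the star
  tiers are per-cell and uncorrected by default, exactly like the
  reporting convention they mirror.
* The WQI's 10-point band quantization makes site WQI a step function of
  the underlying chemistry; small planted effects can be invisible to the
  index while visible in the raw parameters.
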