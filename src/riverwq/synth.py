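"""Synthetic riverscape generator with a known ground truth.

Emulated system: a ~200 km river in a semi-arid agricultural basin, eleven
monitoring sites, two sampling seasons (warm/wet "summer", cold/dry
"winter"), an urban core whose wastewater outfall produces a dissolved-
oxygen crash with ammonium/nitrite spikes decaying downstream, and a
longitudinal land-cover gradient (natural vegetation upstream, urban core
mid-basin, cropland downstream) so that buffer compositions vary between
sites.

The landscape is zoned random blobs, not real geography: class fractions
are controlled by rank-thresholding a smooth noise field, which pins the
realized cropland pixel fraction to the configured target. Water-quality
records follow a linear mean model on the local buffer composition,

    value(site, season, rep) = baseline
                             + sum_c beta[c, param] * frac_c(site)
                             + gamma[param] * 1[summer]
                             + delta[param] * exp(-downstream_dist / L)
                             + Normal(0, sd[param])

clipped to physical ranges (values at 0, pH to [4, 10]); total coliforms are
generated on the log10 scale and exponentiated to keep positivity and a
heavy tail. The wastewater term applies from the outfall site downstream
with e-folding length L (default 25 km). All randomness comes from one
numpy PCG64 generator seeded from the config, so a fixed seed reproduces
the scene byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from .geo import (
    BASE_LEGEND,
    CROP_LEGEND,
    CROPLAND_CODE,
    FULL_LEGEND,
    NOT_CLASSIFIED_CROPS_CODE,
    BufferSpec,
    LULCRaster,
    SampleSite,
    class_composition,
    make_local_buffer,
    reclassify_cropland,
)
from .wqi import PARAMETER_IDS, WaterQualityRecord, build_normalization_table, compute_wqi
from . import stats as rstats

_CODE = {name: code for code, name in BASE_LEGEND.items()}
_CROP_CODE = {name: code for code, name in CROP_LEGEND.items()}

#: typical baseline water chemistry for a lightly impacted reach
DEFAULT_BASELINES: dict[str, float] = {
    "conductivity": 800.0,   # uS/cm
    "dissolved_oxygen": 8.0, # mg/L, near saturation
    "turbidity": 10.0,       # NTU
    "nitrite": 0.05,         # mg/L
    "nitrate": 2.0,          # mg/L
    "ammonium": 0.10,        # mg/L
    "hardness": 150.0,       # mg/L
    "chloride": 50.0,        # mg/L
    "sulfate": 60.0,         # mg/L
    "total_coliforms": 1e3,  # MPN/100 mL (log10 = 3)
    "temperature": 12.0,     # degC, winter baseline
    "ph": 7.8,
}

#: planted landscape effects: (class, parameter) -> shift per unit class
#: fraction (0-1). Coliform betas act on the log10 scale.
DEFAULT_BETA: dict[tuple[str, str], float] = {
    ("cropland", "ammonium"): 1.0,
    ("cropland", "nitrate"): 25.0,
    ("cropland", "chloride"): 150.0,
    ("cropland", "turbidity"): 20.0,
    ("built_up", "conductivity"): 800.0,
    ("built_up", "nitrite"): 0.15,
    ("built_up", "total_coliforms"): 1.5,
    ("forest", "conductivity"): -300.0,
    ("grassland", "hardness"): -80.0,
}

#: summer - winter seasonal offsets
DEFAULT_GAMMA: dict[str, float] = {
    "temperature": 10.0,
    "dissolved_oxygen": -1.0,
    "turbidity": 4.0,
}

#: wastewater-outfall spikes at the source site (decaying downstream)
DEFAULT_DELTA: dict[str, float] = {
    "dissolved_oxygen": -6.0,
    "ammonium": 0.9,
    "nitrite": 0.75,
    "total_coliforms": 1.2,  # log10 scale
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "conductivity": 60.0,
    "dissolved_oxygen": 0.4,
    "turbidity": 3.0,
    "nitrite": 0.01,
    "nitrate": 0.8,
    "ammonium": 0.04,
    "hardness": 15.0,
    "chloride": 8.0,
    "sulfate": 8.0,
    "total_coliforms": 0.3,  # log10 scale
    "temperature": 1.5,
    "ph": 0.15,
}

#: crop-subtype shares of cropland pixels per season
DEFAULT_CROP_SHARES: dict[str, dict[str, float]] = {
    "summer": {
        "soy": 0.48,
        "corn": 0.35,
        "not_classified_crops": 0.165,
        "horticulture": 0.003,
        "alfalfa": 0.002,
    },
    "winter": {
        "fallow": 0.70,
        "not_classified_crops": 0.24,
        "winter_cereals": 0.055,
        "alfalfa": 0.002,
        "horticulture": 0.003,
    },
}


@dataclass
class SceneConfig:
    """Parameters of one synthetic riverscape.

    Defaults mirror the emulated study reach: 11 sites on a ~200 km river,
    10 m cells, ~54% cropland, the wastewater outfall at the 7th site.
    """

    seed: int = 0
    n_sites: int = 11
    river_length_m: float = 200_000.0
    sinuosity_amplitude_m: float = 1500.0
    sinuosity_wavelength_m: float = 40_000.0
    cell_size_m: float = 10.0
    margin_m: float = 3000.0
    crs: str = "EPSG:32720"  # UTM 20S (meters)
    cropland_fraction: float = 0.54
    builtup_fraction: float = 0.045
    urban_center_frac: float = 0.33
    urban_halfwidth_m: float = 8000.0
    blob_size_m: float = 1500.0
    river_width_m: float = 60.0
    crop_shares: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CROP_SHARES.items()})
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    gamma: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    delta: dict = field(default_factory=lambda: dict(DEFAULT_DELTA))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    wastewater_site: Optional[int] = None  # 0-based; default ~55% downstream
    decay_length_m: float = 25_000.0
    n_replicates: int = 2  # records per site per season
    buffer_spec: BufferSpec = field(default_factory=BufferSpec)

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not 0 <= self.cropland_fraction <= 1:
            raise ValueError("cropland_fraction must lie in [0, 1]")
        if self.margin_m < self.buffer_spec.local_radius:
            raise ValueError(
                "raster margin is smaller than the local buffer radius; "
                "buffers would extend past the raster extent"
            )

    @property
    def wastewater_index(self) -> int:
        if self.wastewater_site is not None:
            return self.wastewater_site
        return min(self.n_sites - 1, round(0.55 * (self.n_sites - 1)))


def recovery_config(seed: int = 0, n_sites: int = 50) -> SceneConfig:
    """Down-scaled scene used for Monte-Carlo effect-recovery studies.

    More sites (power) on a shorter river with coarser cells (speed); the
    effect model, baselines and noise are the study defaults.
    """
    return SceneConfig(
        seed=seed,
        n_sites=n_sites,
        river_length_m=40_000.0,
        sinuosity_amplitude_m=400.0,
        sinuosity_wavelength_m=15_000.0,
        cell_size_m=50.0,
        margin_m=1100.0,
        blob_size_m=1200.0,
    )


def null_config(seed: int = 0, n_sites: int = 50) -> SceneConfig:
    """Recovery-study scene with no planted effects (beta = 0, delta = 0)."""
    cfg = recovery_config(seed=seed, n_sites=n_sites)
    cfg.beta = {}
    cfg.delta = {}
    return cfg


@dataclass
class SyntheticScene:
    config: SceneConfig
    river: LineString
    sites: list[SampleSite]
    rasters: dict[str, LULCRaster]  # base | summer | winter
    records: list[WaterQualityRecord]
    local_fractions: pd.DataFrame  # site x class fraction (0-1) used for planting
    truth: dict  # beta/gamma/delta/seed actually used


def _blob_field(rng: np.ndarray, shape: tuple[int, int], blob_cells: float) -> np.ndarray:
    """Smooth N(0,1)-ish field: coarse white noise, bilinear upsampling."""
    coarse_shape = (
        max(2, int(np.ceil(shape[0] / blob_cells)) + 1),
        max(2, int(np.ceil(shape[1] / blob_cells)) + 1),
    )
    coarse = rng.standard_normal(coarse_shape)
    zoom = (shape[0] / coarse_shape[0], shape[1] / coarse_shape[1])
    f = ndimage.zoom(coarse, zoom, order=1, grid_mode=True, mode="nearest")
    return f[: shape[0], : shape[1]]


def _rank_threshold(score: np.ndarray, mask: np.ndarray, count: int) -> np.ndarray:
    """Boolean mask selecting the ``count`` highest scores within ``mask``."""
    sel = np.zeros(score.shape, dtype=bool)
    idx = np.flatnonzero(mask)
    if count <= 0 or len(idx) == 0:
        return sel
    count = min(count, len(idx))
    order = np.argsort(score.ravel()[idx], kind="stable")
    sel.ravel()[idx[order[-count:]]] = True
    return sel


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Deterministically generate a full synthetic riverscape."""
    rng = np.random.default_rng(config.seed)
    cell = config.cell_size_m

    # --- river polyline (source at x=0, flowing +x with a sine meander)
    xs = np.linspace(0.0, config.river_length_m, max(int(config.river_length_m / 250), 8))
    ys = config.sinuosity_amplitude_m * np.sin(2 * np.pi * xs / config.sinuosity_wavelength_m)
    river = LineString(np.column_stack([xs, ys]))

    # --- raster grid covering the river plus margin
    xmin = -config.margin_m
    xmax = config.river_length_m + config.margin_m
    ymax = config.sinuosity_amplitude_m + config.margin_m
    ymin = -ymax
    ncols = int(np.ceil((xmax - xmin) / cell))
    nrows = int(np.ceil((ymax - ymin) / cell))
    xc = xmin + (np.arange(ncols) + 0.5) * cell
    yc = ymin + (nrows - np.arange(nrows) - 0.5) * cell
    X, Y = np.meshgrid(xc, yc)

    u = np.clip(X / config.river_length_m, 0.0, 1.0)  # chainage fraction proxy
    river_y = config.sinuosity_amplitude_m * np.sin(2 * np.pi * X / config.sinuosity_wavelength_m)

    base = np.zeros((nrows, ncols), dtype=np.int32)

    # water: the channel corridor
    water = np.abs(Y - river_y) <= config.river_width_m / 2
    base[water] = _CODE["water"]

    n_cells = base.size
    unassigned = ~water

    # built-up: blob around the urban-core chainage, hugging the river
    urb_score = (
        -(((u - config.urban_center_frac) * config.river_length_m / config.urban_halfwidth_m) ** 2)
        - (np.abs(Y - river_y) / (6 * config.urban_halfwidth_m)) ** 2 * 40
        + 0.35 * _blob_field(rng, base.shape, config.blob_size_m / cell)
    )
    n_urban = int(round(config.builtup_fraction * n_cells))
    urban = _rank_threshold(urb_score, unassigned, n_urban)
    base[urban] = _CODE["built_up"]
    unassigned &= ~urban

    # cropland: downstream-weighted blobs, exact pixel count
    crop_score = 1.8 * u + 0.8 * _blob_field(rng, base.shape, config.blob_size_m / cell)
    n_crop = int(round(config.cropland_fraction * n_cells))
    crop = _rank_threshold(crop_score, unassigned, n_crop)
    base[crop] = CROPLAND_CODE
    unassigned &= ~crop

    # natural remainder: forest / shrubland / grassland / bare soil by
    # zone-weighted argmax over per-class blob fields
    nat_scores = np.stack(
        [
            1.1 * (1 - u) + 0.6 * _blob_field(rng, base.shape, config.blob_size_m / cell),  # forest
            0.45 * (1 - u) + 0.6 * _blob_field(rng, base.shape, config.blob_size_m / cell),  # shrubland
            0.8 + 0.6 * _blob_field(rng, base.shape, config.blob_size_m / cell),  # grassland
            0.15 + 0.6 * _blob_field(rng, base.shape, config.blob_size_m / cell),  # bare soil
        ]
    )
    nat_codes = np.array([_CODE["forest"], _CODE["shrubland"], _CODE["grassland"], _CODE["bare_soil"]])
    base[unassigned] = nat_codes[np.argmax(nat_scores, axis=0)][unassigned]

    base_raster = LULCRaster(base, xmin, ymin, cell, config.crs,
                             legend=dict(BASE_LEGEND), season="base")

    # --- seasonal crop-subtype maps over the cropland mask
    subtype_field = _blob_field(rng, base.shape, config.blob_size_m / cell)
    crop_mask = base == CROPLAND_CODE
    seasonal = {}
    for season in ("summer", "winter"):
        shares = config.crop_shares[season]
        crop_map = np.full(base.shape, -9999, dtype=np.int32)
        idx = np.flatnonzero(crop_mask)
        if len(idx):
            order = np.argsort(subtype_field.ravel()[idx], kind="stable")
            start = 0
            names = sorted(shares)  # deterministic allocation order
            for i, name in enumerate(names):
                cnt = int(round(shares[name] * len(idx)))
                stop = len(idx) if i == len(names) - 1 else min(start + cnt, len(idx))
                crop_map.ravel()[idx[order[start:stop]]] = (
                    NOT_CLASSIFIED_CROPS_CODE if name == "not_classified_crops" else _CROP_CODE[name]
                )
                start = stop
        crop_raster = LULCRaster(crop_map, xmin, ymin, cell, config.crs,
                                 legend=dict(CROP_LEGEND), season=season)
        seasonal[season] = reclassify_cropland(base_raster, crop_raster, season)

    rasters = {"base": base_raster, **seasonal}

    # --- sites along the river, ordered downstream
    chainages = np.linspace(0.06, 0.97, config.n_sites) * river.length
    sites = []
    for i, s in enumerate(chainages):
        pt = river.interpolate(s)
        sites.append(SampleSite(site_id=f"SS{i + 1}", x=pt.x, y=pt.y,
                                distance_km=round(s / 1000.0, 3)))

    # --- local buffer composition fractions used to plant effects
    frac_rows = {}
    for site in sites:
        comp = class_composition(base_raster, make_local_buffer(site, config.buffer_spec))
        frac_rows[site.site_id] = {k: v / 100.0 for k, v in comp.percentages.items()}
    local_fractions = pd.DataFrame(frac_rows).T.loc[[s.site_id for s in sites]]

    # --- water-quality records
    ww = config.wastewater_index
    ww_chainage = chainages[ww]
    records = []
    sample_dates = {
        "summer": [date(2018 + j, 1, 15) for j in range(config.n_replicates)],
        "winter": [date(2018 + j, 7, 15) for j in range(config.n_replicates)],
    }
    log_params = {"total_coliforms"}
    for site, s_chain in zip(sites, chainages):
        fracs = local_fractions.loc[site.site_id]
        downstream = s_chain - ww_chainage
        decay = np.exp(-downstream / config.decay_length_m) if downstream >= 0 else 0.0
        for season in ("summer", "winter"):
            for d in sample_dates[season]:
                values = {}
                for pid in PARAMETER_IDS:
                    mean = config.baselines[pid]
                    if pid in log_params:
                        mean = np.log10(mean)
                    for (cls, p), b in config.beta.items():
                        if p == pid and cls in fracs.index:
                            mean += b * fracs[cls]
                    if season == "summer":
                        mean += config.gamma.get(pid, 0.0)
                    mean += config.delta.get(pid, 0.0) * decay
                    value = mean + rng.normal(0.0, config.noise_sd.get(pid, 0.0))
                    if pid in log_params:
                        value = 10.0**value
                    if pid == "ph":
                        value = float(np.clip(value, 4.0, 10.0))
                    elif pid != "temperature":
                        value = max(0.0, float(value))
                    values[pid] = float(value)
                records.append(
                    WaterQualityRecord(site_id=site.site_id, date=d, season=season, values=values)
                )

    truth = {
        "seed": config.seed,
        "beta": {f"{cls}:{p}": v for (cls, p), v in config.beta.items()},
        "gamma": dict(config.gamma),
        "delta": dict(config.delta),
        "wastewater_site": sites[ww].site_id,
        "decay_length_m": config.decay_length_m,
    }
    return SyntheticScene(
        config=config,
        river=river,
        sites=sites,
        rasters=rasters,
        records=records,
        local_fractions=local_fractions,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo effect recovery
# ---------------------------------------------------------------------------

def scene_site_metrics(scene: SyntheticScene, scope: str = "overall") -> pd.DataFrame:
    """Site-level mean parameters and WQI for one scope (overall/summer/winter)."""
    table = build_normalization_table()
    rows = []
    for r in scene.records:
        if scope != "overall" and r.season != scope:
            continue
        row = {"site_id": r.site_id, **r.values}
        row["wqi"] = compute_wqi(r, table).wqi
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby("site_id", sort=False).mean().reset_index()


def _expected_wqi_sign(config: SceneConfig, cls: str) -> int:
    """Direction a class should push the WQI, from the planted betas and the
    monotone band structure (all parameters except dissolved oxygen degrade
    as they increase)."""
    signs = set()
    for (c, p), b in config.beta.items():
        if c != cls or b == 0:
            continue
        signs.add(int(np.sign(-b)) if p != "dissolved_oxygen" else int(np.sign(b)))
    if len(signs) == 1:
        return signs.pop()
    return 0


def make_parameter_recovery_suite(
    config: SceneConfig,
    n_scenes: int,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Run the full pipeline on ``n_scenes`` seeded scenes and score how often
    each planted (class, parameter) effect is recovered by the local-scale
    Pearson matrix.

    Returns one row per cell with the planted ``beta``, the fraction of
    scenes with the correct r sign at p < 0.05 (``recovery_rate``; NaN where
    no effect was planted), and the plain p < 0.05 frequency (``sig_rate``,
    the type-I rate for null cells). Rows with variable ``wqi`` score the
    index against the direction implied by the planted parameter effects.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    base_seed = config.seed if base_seed is None else base_seed
    classes = list(BASE_LEGEND.values())
    variables = list(PARAMETER_IDS) + ["wqi"]
    hits = {(c, v): 0 for c in classes for v in variables}
    sigs = {(c, v): 0 for c in classes for v in variables}
    counts = {(c, v): 0 for c in classes for v in variables}

    for i in range(n_scenes):
        scene = generate_scene(replace(config, seed=base_seed + i))
        metrics = scene_site_metrics(scene, scope="overall")
        fr = scene.local_fractions
        for cls in classes:
            x = fr[cls].to_numpy() if cls in fr.columns else np.zeros(len(fr))
            for var in variables:
                y = metrics.set_index("site_id").loc[fr.index, var].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                r, p, _ = rstats.pearson_with_p(x, y)
                counts[(cls, var)] += 1
                sig = np.isfinite(p) and p < 0.05
                if sig:
                    sigs[(cls, var)] += 1
                if var == "wqi":
                    want = _expected_wqi_sign(config, cls)
                else:
                    want = int(np.sign(config.beta.get((cls, var), 0.0)))
                if want != 0 and sig and np.sign(r) == want:
                    hits[(cls, var)] += 1

    rows = []
    for cls in classes:
        for var in variables:
            n = counts[(cls, var)]
            if var == "wqi":
                planted = float(_expected_wqi_sign(config, cls))
            else:
                planted = config.beta.get((cls, var), 0.0)
            rows.append(
                {
                    "lulc_class": cls,
                    "variable": var,
                    "beta": planted,
                    "n_scenes": n,
                    "recovery_rate": hits[(cls, var)] / n if (n and planted != 0) else np.nan,
                    "sig_rate": sigs[(cls, var)] / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
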