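"""End-to-end orchestration: scene/survey inputs -> WQI tables, buffer
compositions, correlation/PCA/cluster summaries, longitudinal profile
report, and a hash manifest making reruns verifiable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .geo import BufferSpec, SampleSite, composition_table
from .stats import cluster_sites, correlation_matrix, run_pca
from .wqi import (
    PARAMETER_IDS,
    GuidelineSet,
    SeasonCalendar,
    aggregate_seasonal,
    build_normalization_table,
    compute_wqi,
    default_guidelines,
    flag_exceedances,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options for one pipeline run (YAML round-trippable)."""

    scene_dir: str
    out_dir: str
    seed: int = 0
    missing_policy: str = "strict"
    guidelines_path: str | None = None
    scales: tuple[str, ...] = ("local", "regional")
    k_clusters: int = 5
    cluster_method: str = "ward"
    cluster_metric: str = "euclidean"
    bh_correction: bool = False
    local_radius: float = 1000.0
    regional_length: float = 20000.0
    regional_width: float = 5000.0
    summer_months: tuple[int, ...] = (12, 1, 2, 3, 4)
    make_plots: bool = False

    @property
    def buffer_spec(self) -> BufferSpec:
        return BufferSpec(self.local_radius, self.regional_length, self.regional_width)

    @property
    def season_calendar(self) -> SeasonCalendar:
        return SeasonCalendar(frozenset(self.summer_months))

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["scales"] = list(self.scales)
        doc["summer_months"] = list(self.summer_months)
        rio.dump_yaml(doc, path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = rio.load_yaml(path)
        doc["scales"] = tuple(doc.get("scales", ("local", "regional")))
        doc["summer_months"] = tuple(doc.get("summer_months", (12, 1, 2, 3, 4)))
        return cls(**doc)


def load_scene_dir(scene_dir, calendar: SeasonCalendar | None = None):
    """Read a scene directory (rasters, vectors, records) into memory."""
    scene_dir = Path(scene_dir)
    for name in ("river.geojson", "sites.geojson", "waterquality.csv", "lulc_base.asc"):
        if not (scene_dir / name).exists():
            raise FileNotFoundError(f"scene input missing: {scene_dir / name}")
    rasters = {}
    for season in ("base", "summer", "winter"):
        p = scene_dir / f"lulc_{season}.asc"
        if p.exists():
            rasters[season] = rio.read_ascii_grid(p)
    river = rio.read_river_geojson(scene_dir / "river.geojson")
    sites = rio.read_sites_geojson(scene_dir / "sites.geojson")
    records = rio.read_records_csv(scene_dir / "waterquality.csv", calendar)
    return river, sites, rasters, records


def write_scene(scene, scene_dir) -> None:
    """Write a SyntheticScene as a scene directory of text artifacts."""
    scene_dir = Path(scene_dir)
    scene_dir.mkdir(parents=True, exist_ok=True)
    rio.write_river_geojson(scene.river, scene_dir / "river.geojson", scene.config.crs)
    rio.write_sites_geojson(scene.sites, scene_dir / "sites.geojson", scene.config.crs)
    for season, raster in scene.rasters.items():
        rio.write_ascii_grid(raster, scene_dir / f"lulc_{season}.asc")
    rio.write_records_csv(scene.records, scene_dir / "waterquality.csv")
    rio.dump_yaml({int(c): n for c, n in scene.rasters["base"].legend.items()},
                  scene_dir / "legend.yaml")
    rio.dump_yaml(scene.truth, scene_dir / "truth.yaml")


def wqi_tables(records, table=None, missing_policy="strict"):
    """Per-site WQI for the three scopes plus the per-record breakdown."""
    table = table or build_normalization_table()
    by_site: dict[str, list] = {}
    for r in records:
        by_site.setdefault(r.site_id, []).append(r)
    rows = []
    breakdowns = []
    for site_id, recs in by_site.items():
        for scope, res in aggregate_seasonal(recs, table, missing_policy).items():
            rows.append(
                {"site_id": site_id, "scope": scope, "wqi": res.wqi, "n_records": res.n_records}
            )
        for r in recs:
            res = compute_wqi(r, table, missing_policy)
            breakdowns.append(
                {
                    "site_id": r.site_id,
                    "date": r.date.isoformat(),
                    "season": r.season,
                    "wqi": res.wqi,
                    "breakdown": res.breakdown,
                    "missing": res.missing,
                }
            )
    return pd.DataFrame(rows), breakdowns


def site_metrics(records, table=None, missing_policy="strict", scope="overall") -> pd.DataFrame:
    """Site-level mean of every measured variable plus WQI, for one scope."""
    table = table or build_normalization_table()
    rows = []
    for r in records:
        if scope != "overall" and r.season != scope:
            continue
        rows.append(
            {"site_id": r.site_id, **r.values,
             "wqi": compute_wqi(r, table, missing_policy).wqi}
        )
    if not rows:
        raise ValueError(f"no records in scope {scope!r}")
    return pd.DataFrame(rows).groupby("site_id", sort=False).mean().reset_index()


def profile_report(records, sites, guidelines: GuidelineSet, wqi_df: pd.DataFrame) -> pd.DataFrame:
    """Longitudinal profile: per-site scope means, WQI and guideline flags,
    ordered by downstream distance."""
    missing = [s.site_id for s in sites if s.distance_km is None]
    if missing:
        raise ValueError(
            f"sites {missing} lack downstream distances; project them onto the "
            "river line first"
        )
    dist = {s.site_id: s.distance_km for s in sites}
    flags: dict[tuple[str, str], set] = {}
    for r in records:
        for v in flag_exceedances(r, guidelines):
            flags.setdefault((r.site_id, r.season), set()).add(v.parameter)
            flags.setdefault((r.site_id, "overall"), set()).add(v.parameter)
    rows = []
    for scope in ("overall", "summer", "winter"):
        sub = [r for r in records if scope == "overall" or r.season == scope]
        if not sub:
            continue
        df = pd.DataFrame([{"site_id": r.site_id, **r.values} for r in sub])
        means = df.groupby("site_id").mean()
        for site_id, row in means.iterrows():
            w = wqi_df[(wqi_df.site_id == site_id) & (wqi_df.scope == scope)]["wqi"]
            rows.append(
                {
                    "site_id": site_id,
                    "scope": scope,
                    "distance_km": dist.get(site_id),
                    **row.to_dict(),
                    "wqi": float(w.iloc[0]) if len(w) else np.nan,
                    "violations": ";".join(sorted(flags.get((site_id, scope), set()))),
                }
            )
    out = pd.DataFrame(rows).sort_values(["scope", "distance_km"], kind="stable")
    return out.reset_index(drop=True)


_SEASON_SCOPE = {"base": "overall", "summer": "summer", "winter": "winter"}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Stages: WQI scoring -> buffer compositions -> correlation matrices per
    scale and season -> PCA -> site clustering -> profile report. Rerunning
    with identical inputs reproduces byte-identical tables.
    """
    out_dir = Path(config.out_dir)
    river, sites, rasters, records = load_scene_dir(
        config.scene_dir, config.season_calendar
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    guidelines = (
        GuidelineSet.from_yaml(config.guidelines_path)
        if config.guidelines_path
        else default_guidelines()
    )
    table = build_normalization_table()
    outputs: dict[str, Path] = {}

    def emit_csv(name: str, df: pd.DataFrame):
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
        outputs[name] = path

    # stage 1: WQI
    try:
        wqi_df, breakdowns = wqi_tables(records, table, config.missing_policy)
    except ValueError as e:
        raise RuntimeError(f"stage wqi failed: {e}") from e
    emit_csv("wqi.csv", wqi_df.sort_values(["site_id", "scope"], kind="stable"))
    bpath = out_dir / "wqi_breakdown.json"
    bpath.write_text(json.dumps(breakdowns, indent=1, sort_keys=True))
    outputs["wqi_breakdown.json"] = bpath

    # stage 2: buffers + composition
    try:
        comp = composition_table(rasters, sites, river, config.buffer_spec,
                                 scales=config.scales)
    except ValueError as e:
        raise RuntimeError(f"stage buffers failed: {e}") from e
    emit_csv("composition.csv", comp)

    # stage 3: correlations per scale x season
    corr_frames = []
    for scale in config.scales:
        for season in comp["season"].unique():
            scope = _SEASON_SCOPE.get(season, "overall")
            try:
                metrics = site_metrics(records, table, config.missing_policy, scope)
                corr_frames.append(
                    correlation_matrix(comp, metrics, scale, season,
                                       bh_correction=config.bh_correction)
                )
            except ValueError as e:
                log.warning("correlation %s/%s skipped: %s", scale, season, e)
    if corr_frames:
        emit_csv("correlation.csv", pd.concat(corr_frames, ignore_index=True))

    # stage 4: PCA on site-level means of the measured variables
    metrics_overall = site_metrics(records, table, config.missing_policy, "overall")
    pca_input = metrics_overall.drop(columns=["wqi"])
    keep = ["site_id"] + [
        c for c in pca_input.columns
        if c != "site_id" and pca_input[c].std(ddof=1) > 0
    ]
    try:
        pca = run_pca(pca_input[keep])
        loadings = pca.loadings.copy()
        loadings.insert(0, "variable", loadings.index)
        emit_csv("pca_loadings.csv", loadings.reset_index(drop=True))
        emit_csv(
            "pca_summary.csv",
            pd.DataFrame(
                {
                    "component": pca.loadings.columns,
                    "eigenvalue": pca.eigenvalues,
                    "pct_variance": pca.pct_variance,
                    "retained": [i < pca.n_retained for i in range(len(pca.eigenvalues))],
                }
            ),
        )
    except ValueError as e:
        raise RuntimeError(f"stage pca failed: {e}") from e

    # stage 5: clustering
    try:
        clus = cluster_sites(metrics_overall.drop(columns=["wqi"]),
                             k=min(config.k_clusters, len(metrics_overall)),
                             method=config.cluster_method, metric=config.cluster_metric)
    except ValueError as e:
        raise RuntimeError(f"stage cluster failed: {e}") from e
    emit_csv("clusters.csv", pd.DataFrame(
        {"site_id": list(clus.labels), "cluster": list(clus.labels.values())}
    ))
    emit_csv("cluster_merges.csv", pd.DataFrame(
        clus.linkage, columns=["child_a", "child_b", "height", "size"]
    ))

    # stage 6: profile report
    profile = profile_report(records, sites, guidelines, wqi_df)
    emit_csv("profile.csv", profile)

    if config.make_plots:
        _make_plots(profile, wqi_df, out_dir)

    manifest = {
        "seed": config.seed,
        "config": {**asdict(config), "scales": list(config.scales),
                   "summer_months": list(config.summer_months)},
        "inputs": {
            p.name: rio.sha256_file(p)
            for p in sorted(Path(config.scene_dir).iterdir())
            if p.is_file()
        },
        "outputs": {name: rio.sha256_file(path) for name, path in sorted(outputs.items())},
        "n_sites": len(sites),
        "n_records": len(records),
        "versions": _versions(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _versions() -> dict:
    import scipy
    import shapely
    import sklearn

    from . import __version__

    return {
        "riverwq": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "shapely": shapely.__version__,
    }


def _make_plots(profile: pd.DataFrame, wqi_df: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for scope, sub in profile.groupby("scope"):
        ax.plot(sub["distance_km"], sub["wqi"], marker="o", label=scope)
    ax.set_xlabel("downstream distance (km)")
    ax.set_ylabel("WQI")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "wqi_profile.png", dpi=120)
    plt.close(fig)
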