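"""Buffer geometry and categorical-raster zonal composition.

Two spatial scales are analyzed around each monitoring site: a local circular
buffer (default radius 1000 m) and a regional corridor following the river
channel upstream of the site (default 20 km long, 5 km total width). Land
use / land cover (LULC) composition inside a buffer is the percentage of
valid raster pixels per class, with the pixel-center inclusion rule by
default.

All coordinates are planar meters in one projected CRS; rasters are north-up
square-cell integer grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import substring

# canonical class codes shared by the generator and the pipeline
BASE_LEGEND: dict[int, str] = {
    1: "forest",
    2: "shrubland",
    3: "grassland",
    4: "cropland",
    5: "built_up",
    6: "bare_soil",
    7: "water",
}
CROP_LEGEND: dict[int, str] = {
    10: "not_classified_crops",
    11: "corn",
    12: "soy",
    13: "alfalfa",
    14: "fallow",
    15: "winter_cereals",
    16: "horticulture",
}
CROPLAND_CODE = 4
NOT_CLASSIFIED_CROPS_CODE = 10
FULL_LEGEND = {**BASE_LEGEND, **CROP_LEGEND}

#: vertex density used for circular buffers; 256 segments keep the polygon
#: area within ~0.01% of pi r^2
CIRCLE_QUAD_SEGS = 64


@dataclass
class LULCRaster:
    """Single-band categorical raster, north-up, square cells in meters."""

    data: np.ndarray  # (nrows, ncols) int codes, row 0 = north
    xll: float  # west edge
    yll: float  # south edge
    cell: float  # cell size, m
    crs: str
    nodata: int = -9999
    legend: dict[int, str] = field(default_factory=dict)
    season: str = "base"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        codes = set(np.unique(self.data).tolist()) - {self.nodata}
        unknown = codes - set(self.legend)
        if self.legend and unknown:
            raise ValueError(f"codes missing from legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        nrows, ncols = self.data.shape
        return (self.xll, self.yll, self.xll + ncols * self.cell, self.yll + nrows * self.cell)

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        nrows = self.data.shape[0]
        x = self.xll + (np.asarray(col) + 0.5) * self.cell
        y = self.yll + (nrows - np.asarray(row) - 0.5) * self.cell
        return x, y

    def translated(self, dx: float, dy: float) -> "LULCRaster":
        return LULCRaster(self.data, self.xll + dx, self.yll + dy, self.cell,
                          self.crs, self.nodata, self.legend, self.season)


@dataclass(frozen=True)
class SampleSite:
    site_id: str
    x: float
    y: float
    distance_km: float | None = None

    @property
    def point(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class BufferSpec:
    """The two analysis scales; lengths in meters."""

    local_radius: float = 1000.0
    regional_length: float = 20000.0
    regional_width: float = 5000.0

    def __post_init__(self):
        if min(self.local_radius, self.regional_length, self.regional_width) <= 0:
            raise ValueError("all buffer dimensions must be positive")
        if self.regional_width > 2 * self.regional_length:
            raise ValueError("regional width may not exceed twice the upstream length")


@dataclass
class RegionalBuffer:
    polygon: Polygon
    upstream_length: float
    truncated: bool


def make_local_buffer(site: SampleSite, spec: BufferSpec | float = BufferSpec()) -> Polygon:
    """Circular buffer of the configured radius centered on the site."""
    radius = spec if isinstance(spec, (int, float)) else spec.local_radius
    if radius <= 0:
        raise ValueError("local buffer radius must be positive")
    return site.point.buffer(radius, quad_segs=CIRCLE_QUAD_SEGS)


def make_regional_buffer(
    site: SampleSite,
    river_line: LineString,
    spec: BufferSpec = BufferSpec(),
    tolerance: float = 200.0,
) -> RegionalBuffer:
    """Upstream channel corridor: the river sub-polyline of arc length up to
    ``regional_length`` ending at the site's projection, dilated by half the
    width each side with flat ends.

    The river line's vertex order must run downstream (source first). A site
    near the source yields a shorter corridor, reported via ``truncated``.
    """
    d = river_line.distance(site.point)
    if d > tolerance:
        raise ValueError(
            f"site {site.site_id} lies {d:.0f} m from the river line "
            f"(tolerance {tolerance:.0f} m)"
        )
    chainage = river_line.project(site.point)
    if chainage <= 0:
        raise ValueError(f"site {site.site_id} has zero upstream river length")
    length = min(spec.regional_length, chainage)
    upstream = substring(river_line, chainage - length, chainage)
    polygon = upstream.buffer(spec.regional_width / 2.0, cap_style="flat")
    return RegionalBuffer(polygon=polygon, upstream_length=length,
                          truncated=length < spec.regional_length)


@dataclass
class CompositionRow:
    """Class percentages of valid pixels inside one buffer."""

    percentages: dict[str, float]
    n_valid: int
    n_nodata: int
    coverage: float  # fraction of the polygon area covered by the raster grid


def class_composition(
    raster: LULCRaster,
    polygon: Polygon,
    center_rule: Literal["center", "area"] = "center",
    crs: str | None = None,
) -> CompositionRow:
    """Zonal class composition of ``polygon`` over a categorical raster.

    With the default ``center`` rule a pixel belongs to the buffer when its
    center lies inside the polygon; ``area`` weights every pixel by the
    fraction of its cell covered. Nodata pixels are excluded from the
    denominator and counted separately.
    """
    if crs is not None and crs != raster.crs:
        raise ValueError(f"CRS mismatch: polygon {crs!r} vs raster {raster.crs!r}")
    nrows, ncols = raster.shape
    minx, miny, maxx, maxy = polygon.bounds
    rxmin, rymin, rxmax, rymax = raster.bounds

    c0 = max(0, int(np.floor((minx - rxmin) / raster.cell)))
    c1 = min(ncols, int(np.ceil((maxx - rxmin) / raster.cell)))
    r0 = max(0, int(np.floor((rymax - maxy) / raster.cell)))
    r1 = min(nrows, int(np.ceil((rymax - miny) / raster.cell)))
    if c0 >= c1 or r0 >= r1:
        raise ValueError("polygon does not intersect the raster grid")

    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    cc, rr = np.meshgrid(cols, rows)
    x, y = raster.cell_center(rr.ravel(), cc.ravel())
    window = raster.data[r0:r1, c0:c1].ravel()

    if center_rule == "center":
        inside = contains_xy(polygon, x, y)
        weights = inside.astype(float)
    elif center_rule == "area":
        weights = _area_weights(raster, polygon, rr.ravel(), cc.ravel(), x, y)
    else:
        raise ValueError(f"unknown center_rule {center_rule!r}")

    sel = weights > 0
    if not sel.any():
        raise ValueError("polygon does not cover any raster pixel")
    codes = window[sel]
    w = weights[sel]
    valid = codes != raster.nodata
    n_nodata = int(np.round(w[~valid].sum()))
    total_valid = w[valid].sum()
    if total_valid == 0:
        raise ValueError("no valid (non-nodata) pixels inside the polygon")

    legend = raster.legend or {int(c): str(int(c)) for c in np.unique(codes)}
    percentages = {name: 0.0 for name in legend.values()}
    for code, name in legend.items():
        mask = codes == code
        if mask.any():
            percentages[name] = 100.0 * w[mask].sum() / total_valid

    cell_area = raster.cell**2
    coverage = min(1.0, weights.sum() * cell_area / polygon.area)
    return CompositionRow(
        percentages=percentages,
        n_valid=int(np.round(total_valid)),
        n_nodata=n_nodata,
        coverage=coverage,
    )


def _area_weights(raster, polygon, rows, cols, x, y):
    """Per-pixel covered-area fraction; exact shapely intersection on the
    boundary cells, 0/1 elsewhere."""
    half = raster.cell / 2.0
    # cells whose bounding box is entirely inside / outside by corner tests
    corners_in = np.ones(len(x), dtype=int)
    corners_out = np.zeros(len(x), dtype=int)
    for sx in (-half, half):
        for sy in (-half, half):
            c = contains_xy(polygon, x + sx, y + sy)
            corners_in &= c
            corners_out |= c
    weights = corners_in.astype(float)
    boundary = (~corners_in.astype(bool)) & corners_out.astype(bool)
    # cells with no corner inside may still intersect (polygon vertex inside)
    maybe = boundary | (~corners_out.astype(bool))
    cell_area = raster.cell**2
    for i in np.flatnonzero(maybe):
        cell_box = box(x[i] - half, y[i] - half, x[i] + half, y[i] + half)
        weights[i] = polygon.intersection(cell_box).area / cell_area
    return weights


def reclassify_cropland(
    base: LULCRaster,
    crop_map: LULCRaster,
    season: str,
    cropland_code: int = CROPLAND_CODE,
    fallback_code: int = NOT_CLASSIFIED_CROPS_CODE,
) -> LULCRaster:
    """Refine the base map's cropland pixels with seasonal crop subtypes.

    Cropland pixels take the crop map's code where one is present; cropland
    with no crop information becomes ``not_classified_crops``. Every
    non-cropland pixel is carried through unchanged.
    """
    if base.shape != crop_map.shape:
        raise ValueError("base and crop map grids differ in shape")
    if (base.xll, base.yll, base.cell) != (crop_map.xll, crop_map.yll, crop_map.cell):
        raise ValueError("base and crop map grids are not co-registered")
    if base.crs != crop_map.crs:
        raise ValueError(f"CRS mismatch: {base.crs!r} vs {crop_map.crs!r}")

    out = base.data.copy()
    cropland = base.data == cropland_code
    has_crop = cropland & (crop_map.data != crop_map.nodata)
    out[has_crop] = crop_map.data[has_crop]
    out[cropland & ~has_crop] = fallback_code
    legend = {**base.legend, **{c: n for c, n in FULL_LEGEND.items() if c in np.unique(out)}}
    return LULCRaster(out, base.xll, base.yll, base.cell, base.crs,
                      base.nodata, legend, season)


def merge_crop_subclasses(raster: LULCRaster, cropland_code: int = CROPLAND_CODE) -> LULCRaster:
    """Collapse seasonal crop subtypes back to the single cropland class."""
    out = raster.data.copy()
    out[np.isin(out, list(CROP_LEGEND))] = cropland_code
    legend = {c: n for c, n in raster.legend.items() if c not in CROP_LEGEND}
    legend[cropland_code] = BASE_LEGEND[cropland_code]
    return LULCRaster(out, raster.xll, raster.yll, raster.cell, raster.crs,
                      raster.nodata, legend, "base")


def composition_table(
    rasters: dict[str, LULCRaster],
    sites: list[SampleSite],
    river_line: LineString | None,
    spec: BufferSpec = BufferSpec(),
    scales: tuple[str, ...] = ("local", "regional"),
    center_rule: Literal["center", "area"] = "center",
) -> pd.DataFrame:
    """Tidy composition table over site x scale x season.

    Each raster in ``rasters`` is keyed by its season tag; the regional scale
    requires ``river_line``.
    """
    rows = []
    for site in sites:
        geoms = {}
        if "local" in scales:
            geoms["local"] = make_local_buffer(site, spec)
        if "regional" in scales:
            if river_line is None:
                raise ValueError("regional scale requires a river line")
            geoms["regional"] = make_regional_buffer(site, river_line, spec).polygon
        for scale, geom in geoms.items():
            for season, raster in rasters.items():
                comp = class_composition(raster, geom, center_rule=center_rule)
                row = {"site_id": site.site_id, "scale": scale, "season": season}
                row.update(comp.percentages)
                row["n_valid"] = comp.n_valid
                row["n_nodata"] = comp.n_nodata
                rows.append(row)
    df = pd.DataFrame(rows)
    class_cols = [c for c in df.columns if c not in
                  ("site_id", "scale", "season", "n_valid", "n_nodata")]
    df[class_cols] = df[class_cols].fillna(0.0)
    return df
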