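"""File formats: ASCII-grid rasters, GeoJSON vectors, YAML sidecars, record CSVs.

Rasters travel as single-band Esri ASCII grids (plain text, integer codes)
with a YAML sidecar carrying the CRS label, the class legend and the season
tag. Vectors are GeoJSON with coordinates in the same projected CRS (meters).
"""

from __future__ import annotations

import csv
import hashlib
import json
from datetime import date
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import LineString, Point, mapping, shape


def write_ascii_grid(raster, path) -> None:
    """Write an LULCRaster as an Esri ASCII grid plus a ``.yaml`` sidecar."""
    path = Path(path)
    header = (
        f"ncols {raster.data.shape[1]}\n"
        f"nrows {raster.data.shape[0]}\n"
        f"xllcorner {raster.xll!r}\n"
        f"yllcorner {raster.yll!r}\n"
        f"cellsize {raster.cell!r}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data.astype(int), fmt="%d")
    sidecar = {
        "crs": raster.crs,
        "season": raster.season,
        "legend": {int(k): v for k, v in raster.legend.items()},
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_ascii_grid(path):
    """Read an Esri ASCII grid written by :func:`write_ascii_grid`."""
    from .geo import LULCRaster

    path = Path(path)
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = value
        data = np.loadtxt(fh, dtype=np.int32)
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    sidecar_path = path.with_suffix(".yaml")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = yaml.safe_load(fh)
    else:
        sidecar = {"crs": "unknown", "season": "base", "legend": {}}
    return LULCRaster(
        data=data,
        xll=float(header["xllcorner"]),
        yll=float(header["yllcorner"]),
        cell=float(header["cellsize"]),
        crs=sidecar["crs"],
        nodata=int(header["nodata_value"]),
        legend={int(k): v for k, v in sidecar.get("legend", {}).items()},
        season=sidecar.get("season", "base"),
    )


def write_sites_geojson(sites, path, crs: str) -> None:
    features = []
    for s in sites:
        props = {"site_id": s.site_id}
        if s.distance_km is not None:
            props["distance_km"] = s.distance_km
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(Point(s.x, s.y)),
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "crs": crs, "features": features}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_sites_geojson(path):
    from .geo import SampleSite

    doc = json.loads(Path(path).read_text())
    sites = []
    for feat in doc["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        sites.append(
            SampleSite(
                site_id=str(props["site_id"]),
                x=geom.x,
                y=geom.y,
                distance_km=props.get("distance_km"),
            )
        )
    return sites


def write_river_geojson(line: LineString, path, crs: str) -> None:
    doc = {
        "type": "FeatureCollection",
        "crs": crs,
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(line),
                # vertex order runs source -> mouth
                "properties": {"downstream_orientation": "along_vertex_order"},
            }
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_river_geojson(path) -> LineString:
    doc = json.loads(Path(path).read_text())
    return shape(doc["features"][0]["geometry"])


def write_records_csv(records, path) -> None:
    from .wqi import ASSOCIATION_PARAMETERS, PARAMETER_IDS

    params = list(PARAMETER_IDS) + [
        p for p in ASSOCIATION_PARAMETERS if any(p in r.values for r in records)
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["site_id", "date", "season"] + params)
        for r in records:
            row = [r.site_id, r.date.isoformat(), r.season]
            row += [repr(r.values[p]) if p in r.values else "" for p in params]
            writer.writerow(row)


def read_records_csv(path, calendar=None):
    from .wqi import SeasonCalendar, WaterQualityRecord

    calendar = calendar or SeasonCalendar()
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            d = date.fromisoformat(row.pop("date"))
            site = row.pop("site_id")
            season = row.pop("season", "") or calendar.season_for(d)
            values = {k: float(v) for k, v in row.items() if v not in ("", None)}
            records.append(
                WaterQualityRecord(site_id=site, date=d, season=season, values=values)
            )
    return records


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def dump_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
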