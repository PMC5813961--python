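"""Reading raw input tables and writing standard-format outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .projection import EquidistantConic

__all__ = [
    "read_sightings",
    "read_telemetry",
    "corridors_to_geojson",
    "read_geojson_polygons",
    "write_run_report",
]


def read_sightings(path: str | Path) -> pd.DataFrame:
    """Read an opportunistic-sighting CSV (id, lat, lon, date, country,
    classification, group_size)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sightings file not found: {path}")
    df = pd.read_csv(path, dtype={"id": str, "country": str, "classification": str})
    required = {"id", "lat", "lon", "date", "country", "classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sightings file {path} missing columns {sorted(missing)}")
    return df


def read_telemetry(path: str | Path) -> pd.DataFrame:
    """Read a telemetry CSV (bird_id, timestamp ISO-8601 UTC, lat, lon,
    velocity_ms)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"telemetry file not found: {path}")
    df = pd.read_csv(path, dtype={"bird_id": str})
    required = {"bird_id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"telemetry file {path} missing columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    if "velocity_ms" not in df.columns:
        df["velocity_ms"] = np.nan
    return df


def _polygon_feature(poly: Polygon, projection: EquidistantConic, properties: dict) -> dict:
    xs, ys = np.asarray(poly.exterior.xy[0]), np.asarray(poly.exterior.xy[1])
    lon, lat = projection.inverse(xs, ys)
    coords = [[float(a), float(b)] for a, b in zip(lon, lat)]
    return {
        "type": "Feature",
        "properties": properties,
        "geometry": {"type": "Polygon", "coordinates": [coords]},
    }


def corridors_to_geojson(results, path: str | Path, projection: EquidistantConic | None = None) -> Path:
    """Write corridor and confidence-band polygons as WGS84 GeoJSON."""
    projection = projection or EquidistantConic()
    features = []
    for level, est in sorted(results.estimates.items()):
        features.append(_polygon_feature(est.polygon, projection, {"level": level, "band": "point"}))
        for band, poly in [("outer", est.band_outer), ("inner", est.band_inner)]:
            if poly is not None:
                features.append(_polygon_feature(poly, projection, {"level": level, "band": band}))
    doc = {"type": "FeatureCollection", "features": features}
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def read_geojson_polygons(path: str | Path, projection: EquidistantConic | None = None) -> dict:
    """Read corridor GeoJSON back into projected shapely polygons.

    Returns ``{(level, band): Polygon}`` in meters.
    """
    projection = projection or EquidistantConic()
    doc = json.loads(Path(path).read_text())
    out = {}
    for feat in doc["features"]:
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        x, y = projection.forward(ring[:, 0], ring[:, 1])
        props = feat["properties"]
        out[(props["level"], props["band"])] = Polygon(np.column_stack([x, y]))
    return out


def write_run_report(path: str | Path, report: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return path
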