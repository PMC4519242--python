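"""Reading and writing the pipeline's file formats.

Vector layers travel as GeoJSON FeatureCollections (plain ``json`` plus
``shapely.geometry.shape``/``mapping``), tables as CSV, elevation as an
ESRI ASCII grid.  All coordinates are planar metres; no CRS handling.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import LineString, Polygon, mapping, shape

from .cover import CategoryMap
from .features import CoverLayer
from .hydrology import GaugeSeries
from .telemetry import FIX_COLUMNS, HomeRange


def _write_feature_collection(path: str | Path, features: list[dict]) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _read_feature_collection(path: str | Path) -> list[dict]:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    return fc["features"]


# --- cover -----------------------------------------------------------------


def write_cover(path: str | Path, layer: CoverLayer) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"code": code},
        }
        for geom, code in zip(layer.geometries, layer.codes)
    ]
    _write_feature_collection(path, feats)
    map_path = Path(path).with_suffix(".categories.json")
    with open(map_path, "w") as fh:
        json.dump(layer.category_map.mapping, fh, indent=0)


def read_cover(path: str | Path, category_map: CategoryMap | None = None) -> CoverLayer:
    if category_map is None:
        map_path = Path(path).with_suffix(".categories.json")
        if map_path.exists():
            with open(map_path) as fh:
                category_map = CategoryMap(json.load(fh))
        else:
            category_map = CategoryMap.identity()
    feats = _read_feature_collection(path)
    geoms, codes = [], []
    for f in feats:
        geoms.append(shape(f["geometry"]))
        codes.append(str(f["properties"]["code"]))
    return CoverLayer(geometries=geoms, codes=codes, category_map=category_map)


# --- blocks and roads ------------------------------------------------------


def write_blocks(path: str | Path, blocks: list[tuple[Polygon, float]]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"population": pop},
        }
        for geom, pop in blocks
    ]
    _write_feature_collection(path, feats)


def read_blocks(path: str | Path) -> list[tuple[Polygon, float]]:
    return [
        (shape(f["geometry"]), float(f["properties"]["population"]))
        for f in _read_feature_collection(path)
    ]


def write_roads(path: str | Path, roads: list[tuple[LineString, str]]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"road_class": cls},
        }
        for geom, cls in roads
    ]
    _write_feature_collection(path, feats)


def read_roads(path: str | Path) -> list[tuple[LineString, str]]:
    return [
        (shape(f["geometry"]), str(f["properties"]["road_class"]))
        for f in _read_feature_collection(path)
    ]


# --- gauges ----------------------------------------------------------------


def write_gauges(path: str | Path, gauges: list[GaugeSeries]) -> None:
    frames = []
    for g in gauges:
        frames.append(
            pd.DataFrame(
                {
                    "station_id": g.station_id,
                    "x": g.x,
                    "y": g.y,
                    "date": g.records.index.strftime("%Y-%m-%d"),
                    "stage_m": g.records.to_numpy(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gauges(path: str | Path) -> list[GaugeSeries]:
    df = pd.read_csv(path, parse_dates=["date"], float_precision="round_trip")
    gauges = []
    for sid, sub in df.groupby("station_id", sort=True):
        gauges.append(
            GaugeSeries(
                station_id=str(sid),
                x=float(sub["x"].iloc[0]),
                y=float(sub["y"].iloc[0]),
                records=pd.Series(sub["stage_m"].to_numpy(), index=pd.DatetimeIndex(sub["date"])),
            )
        )
    return gauges


# --- telemetry and home ranges --------------------------------------------


def write_telemetry(path: str | Path, fixes: pd.DataFrame) -> None:
    fixes[FIX_COLUMNS].to_csv(path, index=False)


def read_telemetry(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, parse_dates=["birth_date", "fix_datetime"], float_precision="round_trip"
    )


def write_home_ranges(path: str | Path, home_ranges: list[HomeRange]) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(hr.mcp),
            "properties": {
                "animal_id": hr.animal_id,
                "sex": hr.sex,
                "n_fixes": hr.n_fixes,
                "area_km2": hr.area_km2,
                "mean_P": hr.mean_P,
            },
        }
        for hr in home_ranges
    ]
    _write_feature_collection(path, feats)


# --- feature table ---------------------------------------------------------


def write_features(path: str | Path, table: pd.DataFrame) -> None:
    out = table.reset_index()
    out.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"col", "row"} <= set(df.columns):
        raise ValueError("feature CSV must carry col and row cell-id columns")
    return df.set_index(["col", "row"])


# --- zones -----------------------------------------------------------------


def write_zones(path: str | Path, zones: dict[str, Polygon]) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(poly), "properties": {"name": name}}
        for name, poly in zones.items()
    ]
    _write_feature_collection(path, feats)


def read_zones(path: str | Path) -> dict[str, Polygon]:
    return {
        str(f["properties"]["name"]): shape(f["geometry"])
        for f in _read_feature_collection(path)
    }
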