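"""Raster, point, table and configuration I/O.

Rasters are written as plain TIFF via :mod:`tifffile` with a JSON sidecar
(``<name>.tif.json``) carrying the geotransform, CRS identifier and nodata
value; reading restores both array and metadata losslessly.  Points travel
as GeoJSON (WGS84 lon/lat) with label/provenance properties, tables as CSV,
configuration as YAML.  Grid or CRS mismatches raise explicit errors —
nothing is silently resampled.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phenology import PhenoRecord
from .samples import SamplePool
from .stack import BANDS, DEFAULT_CRS


@dataclasses.dataclass
class RasterMeta:
    geotransform: tuple[float, ...]
    crs: str = DEFAULT_CRS
    nodata: float | int | None = None

    def to_dict(self) -> dict[str, Any]:
        return {"geotransform": list(self.geotransform), "crs": self.crs,
                "nodata": self.nodata}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RasterMeta":
        return cls(geotransform=tuple(d["geotransform"]), crs=d["crs"],
                   nodata=d.get("nodata"))


def write_raster(path: str | pathlib.Path, array: np.ndarray,
                 meta: RasterMeta | None = None) -> pathlib.Path:
    """Write a (H, W) or (C, H, W) array as TIFF plus a JSON metadata sidecar."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    array = np.asarray(array)
    kw = {}
    if array.ndim == 3:
        kw = {"photometric": "minisblack", "planarconfig": "separate"}
    tifffile.imwrite(path, array, **kw)
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta.to_dict(), indent=1))
    return path


def read_raster(path: str | pathlib.Path) -> tuple[np.ndarray, RasterMeta | None]:
    path = pathlib.Path(path)
    array = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = None
    if sidecar.exists():
        meta = RasterMeta.from_dict(json.loads(sidecar.read_text()))
    return array, meta


def check_grid(meta_a: RasterMeta, meta_b: RasterMeta) -> None:
    """Raise if two rasters disagree on geotransform or CRS."""
    if meta_a.crs != meta_b.crs:
        raise ValueError(f"CRS mismatch: {meta_a.crs!r} vs {meta_b.crs!r}")
    if not np.allclose(meta_a.geotransform, meta_b.geotransform):
        raise ValueError("geotransform mismatch between rasters")


# ---------------------------------------------------------------------------
# points
# ---------------------------------------------------------------------------

def write_points_geojson(path: str | pathlib.Path,
                         records: list[PhenoRecord]) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for rec in records:
        props = {"id": rec.id, "year": rec.year, "label": rec.label,
                 "flowering_doy": rec.flowering_doy, "source": rec.source}
        if rec.true_doy is not None:
            props["true_doy"] = rec.true_doy
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [rec.longitude, rec.latitude]},
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_points_geojson(path: str | pathlib.Path) -> list[PhenoRecord]:
    doc = json.loads(pathlib.Path(path).read_text())
    records = []
    for feat in doc["features"]:
        lon, lat = feat["geometry"]["coordinates"]
        p = feat["properties"]
        records.append(PhenoRecord(
            id=p["id"], longitude=lon, latitude=lat, year=p["year"],
            label=p["label"], flowering_doy=p.get("flowering_doy"),
            source=p.get("source", "field"), true_doy=p.get("true_doy")))
    return records


def write_pool_geojson(path: str | pathlib.Path, pool: SamplePool) -> pathlib.Path:
    """Sample pool as GeoJSON points (pixel row/col as coordinates) with the
    spectra carried in the properties."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for _, row in pool.table.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["col"]), float(row["row"])]},
            "properties": {
                "id": int(row["id"]), "label": int(row["label"]),
                "provenance": row["provenance"],
                **{b: float(row[b]) for b in BANDS},
            },
        })
    doc = {"type": "FeatureCollection",
           "properties": {"block_id": pool.block_id},
           "features": features}
    path.write_text(json.dumps(doc))
    return path


def read_pool_geojson(path: str | pathlib.Path) -> SamplePool:
    doc = json.loads(pathlib.Path(path).read_text())
    rows = []
    for feat in doc["features"]:
        col, row = feat["geometry"]["coordinates"]
        p = feat["properties"]
        rows.append((p["id"], int(row), int(col), p["label"], p["provenance"],
                     *[p[b] for b in BANDS]))
    table = pd.DataFrame(rows, columns=["id", "row", "col", "label",
                                        "provenance", *BANDS])
    block_id = doc.get("properties", {}).get("block_id")
    if isinstance(block_id, list):
        block_id = tuple(block_id)
    return SamplePool(table=table, block_id=block_id)


# ---------------------------------------------------------------------------
# whole scenes and truths (directory layouts used by the CLI)
# ---------------------------------------------------------------------------

def write_scene(dirpath: str | pathlib.Path, stack) -> pathlib.Path:
    """Write a scene stack: per-date 4-band reflectance TIFF plus validity
    mask, and an ``index.json`` listing dates and sensors."""
    from .stack import SceneStack  # noqa: F401  (type reference)

    dirpath = pathlib.Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    meta = RasterMeta(geotransform=stack.geotransform, crs=stack.crs,
                      nodata=-9999.0)
    entries = []
    for img in stack:
        stem = img.date.isoformat()
        write_raster(dirpath / f"{stem}_bands.tif",
                     img.bands.astype(np.float32), meta)
        write_raster(dirpath / f"{stem}_valid.tif",
                     img.valid.astype(np.uint8), meta)
        entries.append({"date": stem, "sensor": img.sensor})
    (dirpath / "index.json").write_text(json.dumps(
        {"images": entries, "geotransform": list(stack.geotransform),
         "crs": stack.crs}, indent=1))
    return dirpath


def read_scene(dirpath: str | pathlib.Path):
    import datetime

    from .stack import SceneImage, SceneStack

    dirpath = pathlib.Path(dirpath)
    index = json.loads((dirpath / "index.json").read_text())
    images = []
    for entry in index["images"]:
        stem = entry["date"]
        bands, _ = read_raster(dirpath / f"{stem}_bands.tif")
        valid, _ = read_raster(dirpath / f"{stem}_valid.tif")
        images.append(SceneImage(date=datetime.date.fromisoformat(stem),
                                 sensor=entry["sensor"],
                                 bands=bands.astype(float),
                                 valid=valid.astype(bool)))
    return SceneStack(images=images, geotransform=tuple(index["geotransform"]),
                      crs=index["crs"])


def write_truth(dirpath: str | pathlib.Path, truth) -> pathlib.Path:
    dirpath = pathlib.Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    meta = RasterMeta(geotransform=truth.geotransform)
    write_raster(dirpath / "class_map.tif", truth.class_map.astype(np.int16), meta)
    write_raster(dirpath / "peak_doy.tif",
                 np.nan_to_num(truth.peak_flowering_doy, nan=-9999.0).astype(np.float32),
                 dataclasses.replace(meta, nodata=-9999.0))
    write_raster(dirpath / "slope_deg.tif", truth.slope_deg.astype(np.float32), meta)
    write_raster(dirpath / "cropland.tif", truth.cropland_truth.astype(np.uint8), meta)
    (dirpath / "truth.json").write_text(json.dumps(
        {"season": truth.season, "year": truth.year,
         "pixel_size": truth.pixel_size,
         "geotransform": list(truth.geotransform)}, indent=1))
    return dirpath


def read_truth(dirpath: str | pathlib.Path):
    from .synth import SceneTruth

    dirpath = pathlib.Path(dirpath)
    info = json.loads((dirpath / "truth.json").read_text())
    class_map, _ = read_raster(dirpath / "class_map.tif")
    peak, _ = read_raster(dirpath / "peak_doy.tif")
    peak = peak.astype(float)
    peak[peak == -9999.0] = np.nan
    slope, _ = read_raster(dirpath / "slope_deg.tif")
    cropland, _ = read_raster(dirpath / "cropland.tif")
    return SceneTruth(class_map=class_map.astype(np.int16),
                      peak_flowering_doy=peak,
                      slope_deg=slope.astype(float),
                      cropland_truth=cropland.astype(bool),
                      season=info["season"], year=info["year"],
                      pixel_size=info["pixel_size"],
                      geotransform=tuple(info["geotransform"]))


# ---------------------------------------------------------------------------
# tables and configuration
# ---------------------------------------------------------------------------

def write_table(path: str | pathlib.Path, frame: pd.DataFrame) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_table(path: str | pathlib.Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_yaml(path: str | pathlib.Path, payload: dict[str, Any]) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def read_yaml(path: str | pathlib.Path) -> dict[str, Any]:
    return yaml.safe_load(pathlib.Path(path).read_text())
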