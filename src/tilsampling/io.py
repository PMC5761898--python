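"""File I/O for the documented CSV and GeoJSON dialects.

CSV: comma-separated, dot decimal, UTF-8, mandatory header row.
GeoJSON: ROI polygons with coordinates in μm (winding per the GeoJSON
standard).  Readers validate records and report violations with row
numbers; writers round-trip losslessly through the readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic import SlideGeometry

MEASUREMENT_COLUMNS = [
    "patient_id",
    "group",
    "section",
    "percent_cd8",
    "n_cells",
    "tissue_loss",
]
CELL_COLUMNS = ["x_um", "y_um", "positive"]


class ValidationError(ValueError):
    """A file violated the documented dialect; message cites the row."""


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["percent_cd8"] < 0) | (df["percent_cd8"] > 100)]
    if len(bad):
        raise ValidationError(
            f"{path}: percent_cd8 outside [0, 100] at row {bad[0] + 2}"
        )
    dupes = df.duplicated(subset=["patient_id", "section"])
    if dupes.any():
        raise ValidationError(
            f"{path}: duplicate (patient_id, section) at row {df.index[dupes][0] + 2}"
        )
    df["tissue_loss"] = df["tissue_loss"].astype(bool)
    return df


def write_cells(cells: pd.DataFrame, path) -> None:
    out = cells.loc[:, CELL_COLUMNS].copy()
    out["positive"] = out["positive"].astype(int)
    out.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if not df[["x_um", "y_um"]].map(lambda v: pd.notna(v)).all().all():
        raise ValidationError(f"{path}: non-finite cell coordinates")
    df["positive"] = df["positive"].astype(bool)
    return df


def write_geometry(geometry: SlideGeometry, path) -> None:
    features = [
        {"type": "Feature", "properties": {"units": "um"}, "geometry": mapping(p)}
        for p in geometry.roi_polygons
    ]
    payload = {
        "type": "FeatureCollection",
        "bbox": list(geometry.bounding_box),
        "features": features,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_geometry(path) -> SlideGeometry:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    polys = []
    for i, feat in enumerate(payload.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValidationError(f"{path}: feature {i} is not a Polygon")
        polys.append(geom)
    bbox = tuple(payload["bbox"]) if "bbox" in payload else None
    return SlideGeometry(roi_polygons=tuple(polys), bounding_box=bbox)
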