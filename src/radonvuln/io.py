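"""Table schemas and CSV / GeoJSON / JSON readers and writers.

Every documented table has a fixed set of mandatory columns; readers fail
with the missing column's name and preserve any extra columns verbatim.
Writers emit UTF-8 comma-separated files with '.' decimals and floats at 10
significant digits, so repeated runs with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "write_units_geojson",
    "file_sha256",
]

FLOAT_FORMAT = "%.10g"

#: Mandatory columns per documented table (docs/data_dictionary.md).
SCHEMAS: dict[str, tuple[str, ...]] = {
    "units": (
        "unit_id", "parent_id", "region_id", "health_area_id", "geology",
        "area_km2", "parent_area_km2", "parent_population", "population",
    ),
    "measurements": ("unit_id", "concentration_bq_m3"),
    "deaths": ("unit_id", "health_area_id", "year", "sex", "age", "cause_code"),
    "health_areas": ("health_area_id", "smoking_prevalence"),
    "truth": ("unit_id", "gm_true", "gsd_true", "p95_true", "true_high"),
    "labels": ("unit_id", "p95"),
    "map": ("unit_id",),
    "regional_summary": (
        "region_id", "threshold", "fraction_units_high",
        "population_high", "population_low", "population_ineligible",
    ),
    "report": ("threshold", "kappa"),
    "stratum_summary": (
        "stratum", "threshold", "natural_deaths", "lung_deaths",
        "pct_natural", "pct_lung", "ratio_of_percentages",
    ),
}


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


def _check(df: pd.DataFrame, table: str) -> None:
    if table not in SCHEMAS:
        raise KeyError(f"unknown table schema {table!r}")
    for col in SCHEMAS[table]:
        if col not in df.columns:
            raise SchemaError(f"table {table!r} is missing mandatory column {col!r}")


def read_table(path, table: str) -> pd.DataFrame:
    """Read a documented CSV table, validating its mandatory columns."""
    df = pd.read_csv(path)
    _check(df, table)
    return df


def write_table(df: pd.DataFrame, path, table: str) -> Path:
    """Write a documented CSV table with fixed float formatting."""
    _check(df, table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_units_geojson(units: pd.DataFrame, path) -> Path:
    """RFC 7946 FeatureCollection with rectangular placeholder polygons.

    Each unit becomes a square of its area centred on its planar centroid
    (synthetic coordinates, no CRS); properties carry unit_id, region and
    class columns when present.
    """
    prop_cols = [
        c for c in units.columns
        if c in ("unit_id", "parent_id", "region_id", "geology") or c.startswith("class_")
    ]
    features = []
    for _, r in units.iterrows():
        half = float(np.sqrt(r["area_km2"]) / 2.0)
        x, y = float(r["x"]), float(r["y"])
        ring = [
            [x - half, y - half], [x + half, y - half],
            [x + half, y + half], [x - half, y + half], [x - half, y - half],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {c: r[c] for c in prop_cols},
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
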