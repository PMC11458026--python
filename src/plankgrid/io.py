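"""Readers and writers for the pipeline's text artifact formats.

Station tables are long-format CSV (one row per station × taxon), the study
polygon is WKT or GeoJSON, grids and cluster maps round-trip through GeoJSON
FeatureCollections, and every tabular result is plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon, mapping, shape

from .surveys import StationSample, SurveyDataset

STATION_COLUMNS = ("station_id", "lon", "lat", "taxon", "abundance")

ENV_VARIABLES = (
    "temperature",
    "salinity",
    "depth",
    "no3",
    "no2",
    "nh4",
    "po4",
    "sioh4",
    "pom",
    "chla",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class FormatError(ValueError):
    """A geometry or file format violates the expected structure."""


def read_survey_csv(
    path: str | Path, dataset_name: str, units: str = "ind·m⁻³",
    min_stations_per_cell: int = 1,
) -> SurveyDataset:
    """Read a long-format station CSV into a :class:`SurveyDataset`.

    Expected columns: station_id, lon, lat, taxon, abundance (an optional
    ``date`` column is carried through; an optional ``dataset`` column is
    used to filter rows to ``dataset_name``).  A taxon absent at a station
    is an absence and appears as abundance 0 in the wide view.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    if "dataset" in df.columns:
        df = df[df["dataset"] == dataset_name]
    bad = df.index[df["abundance"] < 0]
    if len(bad):
        raise ValueError(
            f"{path}: negative abundance at row {int(bad[0]) + 2}"  # header + 1-based
        )
    stations: list[StationSample] = []
    for sid, grp in df.groupby("station_id", sort=True):
        lon = float(grp["lon"].iloc[0])
        lat = float(grp["lat"].iloc[0])
        date = None
        if "date" in grp.columns and pd.notna(grp["date"].iloc[0]):
            date = str(grp["date"].iloc[0])
        abundance = {
            str(t): float(a) for t, a in zip(grp["taxon"], grp["abundance"])
        }
        stations.append(StationSample(str(sid), lon, lat, abundance, date))
    return SurveyDataset(dataset_name, stations, units, min_stations_per_cell)


def write_survey_csv(dataset: SurveyDataset, path: str | Path) -> None:
    """Write a dataset as long-format CSV (inverse of :func:`read_survey_csv`)."""
    rows = []
    for s in dataset.stations:
        for taxon in sorted(s.abundance):
            rows.append(
                {
                    "dataset": dataset.name,
                    "station_id": s.station_id,
                    "lon": s.lon,
                    "lat": s.lat,
                    "date": s.date if s.date is not None else "",
                    "taxon": taxon,
                    "abundance": repr(float(s.abundance[taxon])),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_env_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-station environmental table.

    Required columns: station_id, lon, lat plus the standard abiotic set
    (temperature … chla); extra columns (e.g. phyto-microplankton groups)
    are carried through untouched.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    required = ("station_id", "lon", "lat", *ENV_VARIABLES)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_polygon(path: str | Path) -> Polygon:
    """Read a single polygon from a WKT or GeoJSON file (lon/lat degrees)."""
    text = Path(path).read_text().strip()
    if text.startswith("{"):
        geo = json.loads(text)
        if geo.get("type") == "FeatureCollection":
            feats = geo.get("features", [])
            if len(feats) != 1:
                raise FormatError(f"{path}: expected exactly one feature")
            geo = feats[0]
        if geo.get("type") == "Feature":
            geo = geo["geometry"]
        geom = shape(geo)
    else:
        geom = shapely_wkt.loads(text)
    if geom.geom_type != "Polygon":
        raise FormatError(f"{path}: expected a single Polygon, got {geom.geom_type}")
    if not geom.is_valid:
        raise FormatError(f"{path}: polygon ring is invalid (self-intersecting?)")
    return geom


def write_polygon(polygon: Polygon, path: str | Path) -> None:
    Path(path).write_text(polygon.wkt + "\n")


def write_grid_geojson(grid, cells, labels: dict[str, int] | None, path: str | Path,
                       max_membership: dict[str, float] | None = None) -> None:
    """Write grid cells, station counts and cluster labels as GeoJSON.

    ``cells`` is the CellTable (or None for a bare grid); ``labels`` maps
    cell_id → crisp cluster label.  Round-trips through
    :func:`read_grid_geojson`.
    """
    known = set(grid.kept_cells)
    if labels:
        unknown = set(labels) - known
        if unknown:
            raise ValueError(f"labels refer to unknown cell(s): {sorted(unknown)}")
    features = []
    cell_ids = list(cells.frame.index) if cells is not None else []
    for cell_id in cell_ids:
        poly = grid.cell_polygon(cell_id)
        props: dict = {"cell_id": cell_id}
        if cells is not None:
            for ds, counts in cells.n_stations.items():
                props[f"n_stations_{ds}"] = int(counts.get(cell_id, 0))
        if labels is not None and cell_id in labels:
            props["cluster"] = int(labels[cell_id])
        if max_membership is not None and cell_id in max_membership:
            props["max_membership"] = float(max_membership[cell_id])
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(collection, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_grid_spec(grid, path: str | Path) -> None:
    """Persist a GridSpec as JSON so later CLI steps can rebuild it."""
    data = {
        "origin": list(grid.origin),
        "cell_size": grid.cell_size,
        "n_cols": grid.n_cols,
        "n_rows": grid.n_rows,
        "kept_cells": list(grid.kept_cells),
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def read_grid_spec(path: str | Path):
    from .gridding import GridSpec

    data = json.loads(Path(path).read_text())
    return GridSpec(
        tuple(data["origin"]), data["cell_size"], data["n_cols"],
        data["n_rows"], list(data["kept_cells"]),
    )


def read_grid_geojson(path: str | Path) -> pd.DataFrame:
    """Read back a grid GeoJSON as a properties table indexed by cell_id."""
    with open(path) as fh:
        collection = json.load(fh)
    rows = [feat["properties"] for feat in collection.get("features", [])]
    if not rows:
        return pd.DataFrame(columns=["cell_id"]).set_index("cell_id")
    return pd.DataFrame(rows).set_index("cell_id")
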