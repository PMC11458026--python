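"""Analysis grid, station assignment and bootstrap cell means.

Heterogeneous surveys (different vessels, gears and station densities) are
made comparable by averaging onto a common square grid in degrees.  Cell
means are bootstrap means (B resamples of the cell's stations, default
10 000) of both raw and log(x+1)-transformed abundance, which damps the
influence of unequal station counts per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .surveys import SurveyDataset

__all__ = [
    "GridSpec",
    "CellTable",
    "build_grid",
    "assign_stations",
    "bootstrap_cell_mean",
    "build_cell_table",
    "empty_cell_report",
]


@dataclass
class GridSpec:
    """Axis-aligned square grid in degrees clipped to the study polygon."""

    origin: tuple[float, float]
    cell_size: float
    n_cols: int
    n_rows: int
    kept_cells: list[str]

    def cell_id(self, row: int, col: int) -> str:
        return f"r{row:02d}c{col:02d}"

    def cell_index(self, cell_id: str) -> tuple[int, int]:
        r, c = cell_id[1:].split("c")
        return int(r), int(c)

    def cell_polygon(self, cell_id: str) -> Polygon:
        row, col = self.cell_index(cell_id)
        ox, oy = self.origin
        s = self.cell_size
        return box(ox + col * s, oy + row * s, ox + (col + 1) * s, oy + (row + 1) * s)

    def cell_centroid(self, cell_id: str) -> tuple[float, float]:
        row, col = self.cell_index(cell_id)
        ox, oy = self.origin
        s = self.cell_size
        return ox + (col + 0.5) * s, oy + (row + 0.5) * s

    def locate(self, lon: float, lat: float) -> str | None:
        """Half-open cell lookup: [x, x+s) × [y, y+s), or None if off-grid."""
        ox, oy = self.origin
        col = int(np.floor((lon - ox) / self.cell_size))
        row = int(np.floor((lat - oy) / self.cell_size))
        if 0 <= col < self.n_cols and 0 <= row < self.n_rows:
            return self.cell_id(row, col)
        return None


def build_grid(
    polygon: Polygon, cell_size: float, origin: tuple[float, float] | None = None
) -> GridSpec:
    """Lay a square grid over the polygon, keeping intersecting cells.

    Cells are half-open [x, x+s) × [y, y+s); a cell is kept when its
    intersection with the polygon has positive area.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    minx, miny, maxx, maxy = polygon.bounds
    if origin is None:
        origin = (minx, miny)
    ox, oy = origin
    if ox > minx + 1e-12 or oy > miny + 1e-12:
        raise ValueError("grid origin must lie at or below/left of the polygon bounds")
    n_cols = int(np.ceil((maxx - ox) / cell_size - 1e-12))
    n_rows = int(np.ceil((maxy - oy) / cell_size - 1e-12))
    n_cols = max(n_cols, 1)
    n_rows = max(n_rows, 1)
    spec = GridSpec(origin, cell_size, n_cols, n_rows, [])
    kept = []
    for row in range(n_rows):
        for col in range(n_cols):
            cell = spec.cell_polygon(spec.cell_id(row, col))
            if polygon.intersection(cell).area > 0:
                kept.append(spec.cell_id(row, col))
    if not kept:
        raise ValueError("no grid cell intersects the polygon")
    spec.kept_cells = kept
    return spec


def assign_stations(
    dataset: SurveyDataset, grid: GridSpec, polygon: Polygon
) -> dict[str, str]:
    """Map station_id → cell_id; stations outside the polygon are dropped.

    Points on the polygon boundary count as inside; points on an interior
    cell edge go to the cell on the greater side (half-open convention).
    """
    from shapely.geometry import Point

    kept = set(grid.kept_cells)
    out: dict[str, str] = {}
    for s in dataset.stations:
        if not polygon.covers(Point(s.lon, s.lat)):
            continue
        cell = grid.locate(s.lon, s.lat)
        if cell is not None and cell in kept:
            out[s.station_id] = cell
    return out


def _cell_rng(seed: int, row: int, col: int, var_index: int, tflag: int) -> np.random.Generator:
    # counter-based stream keyed by cell and variable: reproducible and
    # independent of processing order
    return np.random.default_rng(np.random.SeedSequence((seed, row, col, var_index, tflag)))


def bootstrap_cell_mean(
    values: np.ndarray,
    B: int,
    rng: np.random.Generator | int,
    transform: str = "raw",
) -> float:
    """Mean over B bootstrap replicates of the resample mean.

    ``transform`` is "raw" or "log1p" (natural log).  The expectation equals
    the plain sample mean; the bootstrap standard error shrinks as
    s/sqrt(n·B).  A single value is returned exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty cell: no values to aggregate")
    if B < 1:
        raise ValueError("B must be >= 1")
    if transform == "log1p":
        values = np.log1p(values)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    n = values.size
    if n == 1:
        return float(values[0])
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    idx = rng.integers(0, n, size=(B, n))
    return float(values[idx].mean(axis=1).mean())


@dataclass
class CellTable:
    """Per-cell bootstrap means for every taxon, plus station counts."""

    mean_raw: pd.DataFrame
    mean_log: pd.DataFrame
    n_stations: dict[str, pd.Series]
    total_raw: pd.Series
    centroids: pd.DataFrame
    excluded: list[tuple[str, str, int]] = field(default_factory=list)
    B: int = 0
    seed: int = 0

    @property
    def frame(self) -> pd.DataFrame:
        """Summary table indexed by cell_id (centroids, counts, totals)."""
        out = self.centroids.copy()
        for ds, counts in self.n_stations.items():
            out[f"n_{ds}"] = counts
        out["total_raw"] = self.total_raw
        return out

    @property
    def cell_ids(self) -> list[str]:
        return list(self.mean_raw.index)


def build_cell_table(
    datasets: list[SurveyDataset],
    grid: GridSpec,
    polygon: Polygon,
    B: int = 10_000,
    seed: int = 0,
) -> CellTable:
    """Aggregate every dataset onto the grid.

    A cell enters the table only when each dataset meets its own
    ``min_stations_per_cell`` there; excluded cells are reported as
    (cell_id, dataset, station_count).  Taxon columns are the union over
    datasets; a taxon present in several datasets pools their stations.
    """
    assignments = {ds.name: assign_stations(ds, grid, polygon) for ds in datasets}
    frames = {ds.name: ds.to_frame() for ds in datasets}

    counts: dict[str, pd.Series] = {}
    for ds in datasets:
        per_cell = pd.Series(0, index=grid.kept_cells, dtype=int)
        for cell in assignments[ds.name].values():
            per_cell[cell] += 1
        counts[ds.name] = per_cell

    kept, excluded = [], []
    for cell in grid.kept_cells:
        short = [
            (ds.name, int(counts[ds.name][cell]))
            for ds in datasets
            if counts[ds.name][cell] < ds.min_stations_per_cell
        ]
        if short:
            excluded.extend((cell, name, n) for name, n in short)
        else:
            kept.append(cell)
    if not kept:
        raise ValueError("no grid cell satisfies the per-dataset station minima")

    # stable taxon ordering drives the per-(cell, taxon) RNG streams
    all_taxa = sorted({t for ds in datasets for t in ds.taxa})
    taxon_index = {t: i for i, t in enumerate(all_taxa)}

    # station values per (cell, taxon), pooled over datasets carrying the taxon
    values: dict[tuple[str, str], list[np.ndarray]] = {}
    for ds in datasets:
        frame = frames[ds.name]
        amap = assignments[ds.name]
        cells = pd.Series({sid: amap.get(sid) for sid in frame.index})
        for cell, sids in cells.groupby(cells).groups.items():
            if cell not in kept:
                continue
            sub = frame.loc[list(sids)]
            for t in ds.taxa:
                values.setdefault((cell, t), []).append(sub[t].to_numpy())

    mean_raw = pd.DataFrame(0.0, index=kept, columns=all_taxa)
    mean_log = pd.DataFrame(0.0, index=kept, columns=all_taxa)
    for (cell, taxon), chunks in values.items():
        vals = np.concatenate(chunks)
        row, col = grid.cell_index(cell)
        j = taxon_index[taxon]
        mean_raw.loc[cell, taxon] = bootstrap_cell_mean(
            vals, B, _cell_rng(seed, row, col, j, 0), "raw"
        )
        mean_log.loc[cell, taxon] = bootstrap_cell_mean(
            vals, B, _cell_rng(seed, row, col, j, 1), "log1p"
        )

    centroids = pd.DataFrame(
        [grid.cell_centroid(c) for c in kept], index=kept, columns=["lon", "lat"]
    )
    return CellTable(
        mean_raw=mean_raw,
        mean_log=mean_log,
        n_stations={name: s.loc[kept] for name, s in counts.items()},
        total_raw=mean_raw.sum(axis=1),
        centroids=centroids,
        excluded=excluded,
        B=B,
        seed=seed,
    )


def aggregate_env_table(
    env: pd.DataFrame,
    grid: GridSpec,
    polygon: Polygon,
    B: int = 10_000,
    seed: int = 0,
    cells: list[str] | None = None,
) -> pd.DataFrame:
    """Bootstrap cell means of environmental (and extra) station columns.

    Uses the same seeded bootstrap as the abundance table; variable streams
    are keyed by column position after the coordinate columns.
    """
    from shapely.geometry import Point

    var_cols = [c for c in env.columns if c not in ("station_id", "lon", "lat")]
    amap = {}
    for _, r in env.iterrows():
        if not polygon.covers(Point(r["lon"], r["lat"])):
            continue
        cell = grid.locate(float(r["lon"]), float(r["lat"]))
        if cell is not None and cell in set(grid.kept_cells):
            amap.setdefault(cell, []).append(r)
    wanted = cells if cells is not None else sorted(amap)
    rows = {}
    for cell in wanted:
        if cell not in amap:
            continue
        sub = pd.DataFrame(amap[cell])
        row, col = grid.cell_index(cell)
        rows[cell] = {
            v: bootstrap_cell_mean(
                sub[v].to_numpy(dtype=float),
                B,
                _cell_rng(seed, row, col, 1000 + j, 0),
                "raw",
            )
            for j, v in enumerate(var_cols)
        }
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(wanted)
    out.index.name = "cell_id"
    return out


def empty_cell_report(
    grid: GridSpec, datasets: list[SurveyDataset], polygon: Polygon
) -> dict[str, tuple[int, int]]:
    """Per dataset: (number of empty kept cells, min stations per occupied cell)."""
    out = {}
    for ds in datasets:
        amap = assign_stations(ds, grid, polygon)
        per_cell = pd.Series(0, index=grid.kept_cells, dtype=int)
        for cell in amap.values():
            per_cell[cell] += 1
        empty = int((per_cell == 0).sum())
        occupied = per_cell[per_cell > 0]
        out[ds.name] = (empty, int(occupied.min()) if len(occupied) else 0)
    return out
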