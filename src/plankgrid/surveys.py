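"""In-memory containers for point-sampled survey data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StationSample:
    """One station's position and per-taxon abundance.

    ``abundance`` maps taxon label to a non-negative density (e.g. ind·m⁻³);
    taxa not observed at a station are absences (zero), not missing values.
    """

    station_id: str
    lon: float
    lat: float
    abundance: dict[str, float]
    date: str | None = None

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(
                f"station {self.station_id}: coordinates out of range "
                f"({self.lon}, {self.lat})"
            )
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValueError(f"station {self.station_id}: non-finite coordinates")
        for taxon, value in self.abundance.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"station {self.station_id}, taxon {taxon}: invalid abundance {value}"
                )


@dataclass
class SurveyDataset:
    """A named collection of stations sharing units and sampling design."""

    name: str
    stations: list[StationSample]
    units: str = "ind·m⁻³"
    min_stations_per_cell: int = 1

    def __post_init__(self) -> None:
        ids = [s.station_id for s in self.stations]
        if len(ids) != len(set(ids)):
            raise ValueError(f"dataset {self.name}: duplicate station ids")
        if self.min_stations_per_cell < 1:
            raise ValueError("min_stations_per_cell must be >= 1")

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stations:
            for t in s.abundance:
                seen.setdefault(t, None)
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        """Wide station × (lon, lat, taxa) table; absent taxa filled with 0."""
        taxa = self.taxa
        rows = []
        for s in self.stations:
            row = {"station_id": s.station_id, "lon": s.lon, "lat": s.lat}
            for t in taxa:
                row[t] = float(s.abundance.get(t, 0.0))
            rows.append(row)
        frame = pd.DataFrame(rows, columns=["station_id", "lon", "lat", *taxa])
        return frame.set_index("station_id")

    def coords(self) -> np.ndarray:
        return np.array([[s.lon, s.lat] for s in self.stations], dtype=float)
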