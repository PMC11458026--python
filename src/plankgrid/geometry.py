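"""Planar working coordinates for geographic survey data.

All geostatistics run in km on an equirectangular projection with the
documented constants 111.320 km per degree of longitude at the equator and
110.574 km per degree of latitude, so distances are exact, testable
arithmetic.  The projection is anchored at a reference point (by default the
polygon centroid) and is adequate at the few-hundred-km scale of a shelf-sea
survey.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

KM_PER_DEG_LON_EQ = 111.320
KM_PER_DEG_LAT = 110.574


def lonlat_to_km(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to x/y (km) around the anchor (lon0, lat0)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = (lon - lon0) * KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(lat0))
    y = (lat - lat0) * KM_PER_DEG_LAT
    return x, y


def polygon_anchor(polygon: Polygon) -> tuple[float, float]:
    """Reference (lon0, lat0) for the projection: the polygon centroid."""
    c = polygon.centroid
    return float(c.x), float(c.y)


def polygon_area_km2(polygon: Polygon) -> float:
    """Polygon area in km² under the equirectangular projection."""
    lon0, lat0 = polygon_anchor(polygon)
    ext = np.asarray(polygon.exterior.coords)
    x, y = lonlat_to_km(ext[:, 0], ext[:, 1], lon0, lat0)
    return float(Polygon(np.column_stack([x, y])).area)


def km_to_degrees(L: float) -> float:
    """Convert a cell side length in km to degrees of latitude (2 decimals)."""
    if L <= 0:
        raise ValueError("cell size must be positive")
    return round(L / KM_PER_DEG_LAT, 2)
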