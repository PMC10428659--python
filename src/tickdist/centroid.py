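"""Centroid of binary suitable habitat and scenario-to-scenario shift.

The centroid is the area-weighted mean of suitable-cell centres (cos-lat
weighting for cell area). The shift between two scenarios reports
great-circle distance (haversine, sphere radius 6371.0088 km), initial
bearing, and the nearest of the 16 compass winds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from tickdist.env_layers import GridGeometry
from tickdist.suitability import cell_areas_km2

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

WINDS = (
    "north", "north-northeast", "northeast", "east-northeast",
    "east", "east-southeast", "southeast", "south-southeast",
    "south", "south-southwest", "southwest", "west-southwest",
    "west", "west-northwest", "northwest", "north-northwest",
)


class CentroidError(ValueError):
    """Fatal problem during centroid computation."""


@dataclass(frozen=True)
class Centroid:
    lon: float
    lat: float


@dataclass(frozen=True)
class ShiftReport:
    from_: Centroid
    to: Centroid
    distance_km: float
    delta_lon: float
    delta_lat: float
    bearing_deg: float
    cardinal: str

    def to_geojson(self) -> dict:
        return {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [
                    [self.from_.lon, self.from_.lat],
                    [self.to.lon, self.to.lat],
                ],
            },
            "properties": {
                "distance_km": self.distance_km,
                "bearing_deg": self.bearing_deg,
                "cardinal": self.cardinal,
                "delta_lon": self.delta_lon,
                "delta_lat": self.delta_lat,
            },
        }

    def write_geojson(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_geojson(), indent=1))


def habitat_centroid(binary: np.ndarray, geometry: GridGeometry) -> Centroid:
    """Area-weighted centroid of cells flagged suitable (1)."""
    binary = np.asarray(binary)
    suitable = binary == 1
    if not np.any(suitable):
        raise CentroidError("no suitable cells: centroid undefined")
    lon, lat = geometry.cell_centers()
    w = cell_areas_km2(geometry)[suitable]
    return Centroid(
        lon=float(np.average(lon[suitable], weights=w)),
        lat=float(np.average(lat[suitable], weights=w)),
    )


def haversine_km(a: Centroid, b: Centroid) -> float:
    """Great-circle distance on the mean sphere."""
    la1, la2 = math.radians(a.lat), math.radians(b.lat)
    dlat = la2 - la1
    dlon = math.radians(b.lon - a.lon)
    h = math.sin(dlat / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def initial_bearing_deg(a: Centroid, b: Centroid) -> float:
    """Initial great-circle bearing from a to b, clockwise from north."""
    la1, la2 = math.radians(a.lat), math.radians(b.lat)
    dlon = math.radians(b.lon - a.lon)
    y = math.sin(dlon) * math.cos(la2)
    x = math.cos(la1) * math.sin(la2) - math.sin(la1) * math.cos(la2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0


def cardinal_16(bearing_deg: float) -> str:
    """Nearest of the 16 compass winds (22.5 degree sectors centred on N, NNE, ...)."""
    idx = int(round((bearing_deg % 360.0) / 22.5)) % 16
    return WINDS[idx]


def shift(from_: Centroid, to: Centroid) -> ShiftReport:
    """Displacement between two centroids: distance, bearing, cardinal wind."""
    d = haversine_km(from_, to)
    if d == 0.0:
        return ShiftReport(
            from_=from_, to=to, distance_km=0.0,
            delta_lon=0.0, delta_lat=0.0, bearing_deg=0.0, cardinal="none",
        )
    b = initial_bearing_deg(from_, to)
    return ShiftReport(
        from_=from_,
        to=to,
        distance_km=d,
        delta_lon=to.lon - from_.lon,
        delta_lat=to.lat - from_.lat,
        bearing_deg=b,
        cardinal=cardinal_16(b),
    )
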