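"""Species occurrence records: reading, validation, and spatial thinning.

Occurrence records are presence-only georeferenced points, one species per
set (each species is modelled independently). Spatial thinning keeps at most
one record per 10 x 10 km grid cell to reduce sampling bias from uneven
collection effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

KM_PER_DEG = 111.32  # kilometres per degree of latitude (spherical)


class OccurrenceError(ValueError):
    """Fatal problem with occurrence input."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single georeferenced presence point.

    lon/lat are WGS84 decimal degrees; ``source`` is a free-text
    provenance tag (literature citation, collection id, ...).
    """

    species: str
    lon: float
    lat: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise OccurrenceError(f"longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise OccurrenceError(f"latitude {self.lat} outside [-90, 90]")


@dataclass
class OccurrenceSet:
    """Ordered presence records sharing one species label."""

    species: str
    records: list[OccurrenceRecord] = field(default_factory=list)
    n_dropped: int = 0  # rows rejected on read for malformed coordinates

    def __post_init__(self) -> None:
        for r in self.records:
            if r.species != self.species:
                raise OccurrenceError(
                    f"record species {r.species!r} != set species {self.species!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[OccurrenceRecord]:
        return iter(self.records)

    @property
    def lons(self) -> list[float]:
        return [r.lon for r in self.records]

    @property
    def lats(self) -> list[float]:
        return [r.lat for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "lon": self.lons,
                "lat": self.lats,
                "source": [r.source for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_occurrences(path: str | Path, species: str) -> OccurrenceSet:
    """Read a presence CSV and keep rows of one species.

    The file must have a header with at least ``species``, ``lon`` and
    ``lat`` columns; ``source`` is optional. Rows whose coordinates do not
    parse as finite numbers inside WGS84 bounds are dropped and counted in
    ``OccurrenceSet.n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise OccurrenceError(f"occurrence file not found: {path}")
    df = pd.read_csv(path, dtype={"species": str, "source": str})
    for col in ("species", "lon", "lat"):
        if col not in df.columns:
            raise OccurrenceError(f"occurrence CSV missing required column {col!r}")
    if "source" not in df.columns:
        df["source"] = ""
    df = df[df["species"] == species]
    if len(df) == 0:
        raise OccurrenceError(f"no rows for species {species!r} in {path}")

    records: list[OccurrenceRecord] = []
    dropped = 0
    for _, row in df.iterrows():
        lon = pd.to_numeric(row["lon"], errors="coerce")
        lat = pd.to_numeric(row["lat"], errors="coerce")
        if pd.isna(lon) or pd.isna(lat):
            dropped += 1
            continue
        try:
            rec = OccurrenceRecord(
                species=species,
                lon=float(lon),
                lat=float(lat),
                source="" if pd.isna(row["source"]) else str(row["source"]),
            )
        except OccurrenceError:
            dropped += 1
            continue
        records.append(rec)
    if not records:
        raise OccurrenceError(f"all rows for species {species!r} had malformed coordinates")
    return OccurrenceSet(species=species, records=records, n_dropped=dropped)


def _cell_index(lon: float, lat: float, cell_km: float) -> tuple[int, int]:
    # North/east distance from (lon 0, lat 0) via a local equirectangular
    # approximation; cell index by floor division. Deterministic and
    # projection-free at the 10-km analysis resolution.
    import math

    north_km = KM_PER_DEG * lat
    east_km = KM_PER_DEG * math.cos(math.radians(lat)) * lon
    return (math.floor(north_km / cell_km), math.floor(east_km / cell_km))


def thin_occurrences(occ: OccurrenceSet, cell_km: float = 10.0) -> OccurrenceSet:
    """Spatially thin so at most one record survives per cell_km grid cell.

    Cells are defined on a fixed origin (lon 0, lat 0); the first record in
    input order wins each occupied cell, so the operation is deterministic
    and idempotent.
    """
    if cell_km <= 0:
        raise OccurrenceError(f"cell_km must be positive, got {cell_km}")
    if len(occ) == 0:
        raise OccurrenceError("cannot thin an empty occurrence set")
    seen: set[tuple[int, int]] = set()
    kept: list[OccurrenceRecord] = []
    for rec in occ.records:
        key = _cell_index(rec.lon, rec.lat, cell_km)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return OccurrenceSet(species=occ.species, records=kept)
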