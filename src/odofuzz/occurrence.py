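"""Occurrence records: CSV IO, year filtering, grid indexing, stratified split.

A record is one historical observation of a species: who, when, where
(WGS84 decimal degrees + altitude), in what habitat, how many, and
optionally which colours an observer would report.  Locations are binned
into a latitude/longitude graticule; the default cell is 6' of latitude by
10' of longitude (the Central European KFME faunistic grid), which at Czech
latitudes measures roughly 11.1 x 11.9 km.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .knowledge_base import COLOURS

ABUNDANCE_CLASSES: tuple[str, ...] = (
    "1", "2-5", "6-10", "11-20", "21-50", "51-100", "100+",
)

CSV_COLUMNS: tuple[str, ...] = (
    "species_id", "sex", "date", "lat", "lon",
    "altitude", "biotope", "count", "colours",
)

MAX_COLOURS = 3


@dataclass(frozen=True)
class GridCell:
    row: int
    col: int


@dataclass(frozen=True)
class GridConfig:
    """Graticule definition: origin and cell size in decimal degrees.

    Cells are half-open: ``[low, high)`` on both axes, so a point exactly on
    a cell's northern/eastern boundary belongs to the higher-indexed cell.
    """

    lat0: float = 0.0
    lon0: float = 0.0
    dlat: float = 6.0 / 60.0   # 6 arc-minutes
    dlon: float = 10.0 / 60.0  # 10 arc-minutes

    def cell(self, lat: float, lon: float) -> GridCell:
        return GridCell(
            row=math.floor((lat - self.lat0) / self.dlat),
            col=math.floor((lon - self.lon0) / self.dlon),
        )

    def cell_bounds(self, cell: GridCell) -> tuple[float, float, float, float]:
        """(lat_low, lat_high, lon_low, lon_high) of a cell."""
        return (
            self.lat0 + cell.row * self.dlat,
            self.lat0 + (cell.row + 1) * self.dlat,
            self.lon0 + cell.col * self.dlon,
            self.lon0 + (cell.col + 1) * self.dlon,
        )


def gps_to_grid_cell(lat: float, lon: float,
                     grid: GridConfig | None = None) -> GridCell:
    """Map WGS84 coordinates to their graticule cell (half-open bins)."""
    return (grid or GridConfig()).cell(lat, lon)


@dataclass(frozen=True)
class OccurrenceRecord:
    species_id: str
    sex: str  # "male" | "female" | "unknown"
    date: dt.date
    lat: float
    lon: float
    altitude: float | None = None
    biotope: str | None = None
    count: str = "1"
    colours: frozenset[str] | None = None

    def with_colours(self, colours: Iterable[str]) -> "OccurrenceRecord":
        return replace(self, colours=frozenset(colours))


class ReadReport(NamedTuple):
    records: list[OccurrenceRecord]
    rejected: list[tuple[int, str]]  # (1-based data row number, reason)


def _parse_row(i: int, row: pd.Series) -> OccurrenceRecord:
    species_id = str(row["species_id"]).strip()
    if not species_id:
        raise ValueError("empty species_id")
    sex = str(row["sex"]).strip().lower() or "unknown"
    if sex not in ("male", "female", "unknown"):
        raise ValueError(f"invalid sex {sex!r}")
    try:
        date = dt.date.fromisoformat(str(row["date"]).strip())
    except ValueError:
        raise ValueError(f"invalid date {row['date']!r}") from None
    try:
        lat = float(row["lat"])
        lon = float(row["lon"])
    except ValueError:
        raise ValueError("non-numeric coordinates") from None
    if not -90.0 <= lat <= 90.0:
        raise ValueError("latitude out of range")
    if not -180.0 <= lon <= 180.0:
        raise ValueError("longitude out of range")
    altitude_raw = str(row["altitude"]).strip()
    altitude = float(altitude_raw) if altitude_raw else None
    biotope = str(row["biotope"]).strip() or None
    count = str(row["count"]).strip() or "1"
    if count not in ABUNDANCE_CLASSES and not count.isdigit():
        raise ValueError(f"invalid count {count!r}")
    colours_raw = str(row["colours"]).strip()
    colours: frozenset[str] | None = None
    if colours_raw:
        parts = [c.strip().lower() for c in colours_raw.split("|") if c.strip()]
        if len(parts) > MAX_COLOURS:
            raise ValueError(f"more than {MAX_COLOURS} colours")
        unknown = [c for c in parts if c not in COLOURS]
        if unknown:
            raise ValueError(f"unknown colour {unknown[0]!r}")
        colours = frozenset(parts)
    return OccurrenceRecord(species_id=species_id, sex=sex, date=date,
                            lat=lat, lon=lon, altitude=altitude,
                            biotope=biotope, count=count, colours=colours)


def read_records(path: str | Path) -> ReadReport:
    """Read occurrence records from CSV.

    Every row either yields a valid record or is listed in the rejection
    report as ``(row_number, reason)`` with 1-based data row numbers.
    A missing mandatory column raises ``OSError``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise OSError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[OccurrenceRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            records.append(_parse_row(i, row))
        except ValueError as exc:
            rejected.append((i, str(exc)))
    return ReadReport(records, rejected)


def write_records(records: Sequence[OccurrenceRecord],
                  path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "species_id": r.species_id,
            "sex": r.sex,
            "date": r.date.isoformat(),
            "lat": r.lat,
            "lon": r.lon,
            "altitude": "" if r.altitude is None else r.altitude,
            "biotope": r.biotope or "",
            "count": r.count,
            "colours": "|".join(sorted(r.colours)) if r.colours else "",
        })
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def filter_from_year(records: Sequence[OccurrenceRecord],
                     year: int) -> list[OccurrenceRecord]:
    """Keep records observed in ``year`` or later, preserving order."""
    return [r for r in records if r.date.year >= year]


def stratified_split(records: Sequence[OccurrenceRecord],
                     test_fraction: float,
                     seed: int) -> tuple[list[OccurrenceRecord],
                                         list[OccurrenceRecord]]:
    """Split records into train/test, stratified by species.

    Within each species, ``round(n * test_fraction)`` records go to the
    test set, sampled without replacement.  Deterministic given the seed;
    per-species proportions are preserved within one record.  A species
    whose count rounds to zero test records stays entirely in train.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_species.setdefault(r.species_id, []).append(i)
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for sid in sorted(by_species):
        idx = by_species[sid]
        n_test = int(round(len(idx) * test_fraction))
        if n_test:
            chosen = rng.choice(len(idx), size=n_test, replace=False)
            test_idx.update(idx[j] for j in chosen)
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test
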