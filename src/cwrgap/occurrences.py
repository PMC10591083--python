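"""Occurrence-record cleaning, gridding and spatial thinning.

Occurrence downloads (Darwin-Core dialect: ``species`` or
``scientificName``, ``decimalLongitude``, ``decimalLatitude``) are
cleaned (invalid / missing coordinates, outside the study region),
assigned to the analysis lattice, deduplicated to one observation per
cell, and thinned so that retained cells are separated by at least one
empty grid cell — a standard guard against spatial autocorrelation in
presence-only modelling.

"Separated by at least one grid cell" is taken as Chebyshev
(8-neighbourhood) distance >= 2: a diagonal neighbour has no intervening
empty cell and therefore conflicts.  A rook (4-neighbourhood) mode is
available for the stricter-on-rows-only reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .grid import Cell, CellSet, GridSpec

__all__ = [
    "OccurrenceRecord",
    "read_occurrences",
    "clean_occurrences",
    "dedupe_cells",
    "thin_cells",
    "is_modellable",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    taxon_name: str
    lon: float
    lat: float
    source_id: str = ""


_LON_COLS = ("decimallongitude", "lon", "longitude")
_LAT_COLS = ("decimallatitude", "lat", "latitude")
_NAME_COLS = ("species", "scientificname", "taxon", "taxon_name")


def read_occurrences(source) -> pd.DataFrame:
    """Read a Darwin-Core-style delimited table into a normalized frame
    with columns ``taxon_name``, ``lon``, ``lat``, ``source_id``.
    Coordinates stay as strings here; validation happens in
    :func:`clean_occurrences`."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]

    def pick(options):
        for name in options:
            if name in df.columns:
                return name
        raise ValueError(f"none of the columns {options} found")

    out = pd.DataFrame(
        {
            "taxon_name": df[pick(_NAME_COLS)],
            "lon": df[pick(_LON_COLS)],
            "lat": df[pick(_LAT_COLS)],
        }
    )
    out["source_id"] = df["gbifid"] if "gbifid" in df.columns else ""
    return out


def clean_occurrences(
    records: pd.DataFrame, region: tuple | None = None
) -> tuple[list[OccurrenceRecord], list[tuple[dict, str]]]:
    """Drop records with missing/invalid coordinates or outside the region.

    ``region`` is a ``(lon_min, lat_min, lon_max, lat_max)`` bounding box
    (or any object with a shapely-style ``contains`` accepting a Point);
    None keeps everything with valid coordinates.  Returns the cleaned
    records and a rejection log of ``(row, reason)`` pairs.
    """
    kept: list[OccurrenceRecord] = []
    rejected: list[tuple[dict, str]] = []
    for row in records.to_dict("records"):
        try:
            lon = float(row["lon"])
            lat = float(row["lat"])
        except (TypeError, ValueError):
            rejected.append((row, "missing or non-numeric coordinates"))
            continue
        if pd.isna(lon) or pd.isna(lat):
            rejected.append((row, "missing or non-numeric coordinates"))
            continue
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            rejected.append((row, "coordinates out of range"))
            continue
        if region is not None:
            if isinstance(region, tuple):
                lon_min, lat_min, lon_max, lat_max = region
                inside = lon_min <= lon <= lon_max and lat_min <= lat <= lat_max
            else:  # polygon with a contains() predicate
                from shapely.geometry import Point

                inside = region.contains(Point(lon, lat))
            if not inside:
                rejected.append((row, "outside study region"))
                continue
        kept.append(
            OccurrenceRecord(
                taxon_name=str(row.get("taxon_name", "")),
                lon=lon,
                lat=lat,
                source_id=str(row.get("source_id", "") or ""),
            )
        )
    return kept, rejected


def dedupe_cells(records: list[OccurrenceRecord], grid: GridSpec) -> CellSet:
    """Reduce multiple occurrences per grid cell to one occupied cell.
    Records outside the grid extent are ignored."""
    cells: CellSet = set()
    for record in records:
        if grid.contains(record.lon, record.lat):
            cells.add(grid.index(record.lon, record.lat))
    return cells


def _conflict(a: Cell, b: Cell, mode: str) -> bool:
    dr = abs(a[0] - b[0])
    dc = abs(a[1] - b[1])
    if mode == "chebyshev":
        return max(dr, dc) < 2
    if mode == "rook":
        return dr + dc < 2
    raise ValueError(f"unknown thinning mode {mode!r}")


def thin_cells(cells: CellSet, mode: str = "chebyshev") -> CellSet:
    """Greedy spatial thinning: scan cells in row-major order and keep a
    cell iff it conflicts with no already-kept cell.

    Under the default Chebyshev mode two cells conflict when their
    Chebyshev distance is < 2 (i.e. they touch, diagonals included).
    The result is deterministic, a subset of the input, maximal (no
    rejected cell could be added back) and idempotent.
    """
    kept: list[Cell] = []
    for cell in sorted(cells):
        if not any(_conflict(cell, other, mode) for other in kept):
            kept.append(cell)
    return set(kept)


def is_modellable(cells: CellSet, min_cells: int = 10) -> bool:
    """Whether a taxon has enough thinned presence cells for modelling."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    return len(cells) >= min_cells
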