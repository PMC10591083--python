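"""The analysis lattice: a regular geographic grid in arc-minutes.

All spatial processing happens on a single equiangular lattice anchored at
an upper-left (lon_min, lat_max) origin, by default at 2.5 arc-minute
resolution (the WorldClim 2.5' convention, ~4x4 km cells at mid
latitudes).  Occupied cells are plain ``set``s of ``(row, col)`` integer
pairs; range sizes are cell counts on this lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GridSpec", "Cell", "CellSet", "DEFAULT_REGION"]

Cell = tuple[int, int]
CellSet = set  # set[Cell]; plain sets keep the set algebra obvious

#: Default study region: Europe and the countries bordering the
#: Mediterranean Sea, as a bounding box (lat 20-72 N, lon 32 W - 62 E).
DEFAULT_REGION = (-32.0, 20.0, 62.0, 72.0)  # lon_min, lat_min, lon_max, lat_max


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid with an upper-left origin.

    Parameters
    ----------
    lon_min, lat_max : float
        Coordinates of the outer corner of cell (0, 0), decimal degrees.
    resolution : float
        Cell size in arc-minutes (2.5 by default).
    n_rows, n_cols : int
        Grid shape; rows run south, columns run east.
    """

    lon_min: float
    lat_max: float
    resolution: float = 2.5
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid shape must be at least 1x1")

    @property
    def res_deg(self) -> float:
        """Cell size in decimal degrees."""
        return self.resolution / 60.0

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.res_deg

    @property
    def lat_min(self) -> float:
        return self.lat_max - self.n_rows * self.res_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_min <= lon <= self.lon_max
            and self.lat_min <= lat <= self.lat_max
        )

    def index(self, lon: float, lat: float) -> Cell:
        """Cell index of a point; cells are half-open [edge, edge + res).

        Points on the extreme east/south boundary clamp to the last
        column/row so the closed extent maps onto valid indices.
        """
        if not self.contains(lon, lat):
            raise ValueError(
                f"point ({lon}, {lat}) outside grid extent "
                f"[{self.lon_min}, {self.lon_max}] x [{self.lat_min}, {self.lat_max}]"
            )
        col = int((lon - self.lon_min) / self.res_deg)
        row = int((self.lat_max - lat) / self.res_deg)
        return (min(row, self.n_rows - 1), min(col, self.n_cols - 1))

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        """(lon, lat) of a cell's centre."""
        row, col = cell
        lon = self.lon_min + (col + 0.5) * self.res_deg
        lat = self.lat_max - (row + 0.5) * self.res_deg
        return (lon, lat)

    def validate_cells(self, cells: CellSet) -> None:
        for row, col in cells:
            if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
                raise ValueError(f"cell {(row, col)} outside grid {self.shape}")

    @classmethod
    def from_bbox(
        cls,
        lon_min: float,
        lat_min: float,
        lon_max: float,
        lat_max: float,
        resolution: float = 2.5,
    ) -> "GridSpec":
        """Smallest grid at ``resolution`` covering the bounding box."""
        import math

        res = resolution / 60.0
        n_cols = max(1, math.ceil((lon_max - lon_min) / res - 1e-9))
        n_rows = max(1, math.ceil((lat_max - lat_min) / res - 1e-9))
        return cls(lon_min, lat_max, resolution, n_rows, n_cols)
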