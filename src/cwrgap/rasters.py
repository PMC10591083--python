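"""Environmental raster layers on the analysis lattice.

Layers are exchanged as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
whitespace-separated rows from north to south — a plain-text format every
GIS reads and writes.  In memory an :class:`EnvStack` holds the named
layers as a single masked 3-D array sharing one :class:`GridSpec` and one
no-data mask.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid import CellSet, GridSpec

__all__ = ["EnvStack", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns (array, grid, nodata).

    No-data cells are NaN in the returned array.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    nodata = header.get("nodata_value", _NODATA)
    data = np.loadtxt(lines[i:].__iter__(), dtype=float)
    data = np.atleast_2d(data)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} != header {(n_rows, n_cols)}")
    data = np.where(data == nodata, np.nan, data)
    cellsize_deg = header["cellsize"]
    grid = GridSpec(
        lon_min=header["xllcorner"],
        lat_max=header["yllcorner"] + n_rows * cellsize_deg,
        resolution=cellsize_deg * 60.0,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return data, grid, nodata


def write_ascii_grid(path, data: np.ndarray, grid: GridSpec, nodata: float = _NODATA):
    """Write a 2-D array (NaN = no data) as an ESRI ASCII grid."""
    path = Path(path)
    out = np.where(np.isnan(data), nodata, data)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.lon_min!r}\n")
        fh.write(f"yllcorner {grid.lat_min!r}\n")
        fh.write(f"cellsize {grid.res_deg!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, out, fmt="%.10g")
    return path


class EnvStack:
    """Named environmental layers sharing one grid and no-data mask."""

    def __init__(self, grid: GridSpec, layers: dict):
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        self.grid = grid
        self.names: list[str] = list(layers)
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        arrays = []
        for name in self.names:
            arr = np.asarray(layers[name], dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid {grid.shape}"
                )
            arrays.append(arr)
        self.data = np.stack(arrays)  # (n_layers, n_rows, n_cols)
        # a cell is valid only where every layer has data
        self.mask = ~np.isnan(self.data).any(axis=0)

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def valid_cells(self) -> CellSet:
        rows, cols = np.nonzero(self.mask)
        return set(zip(rows.tolist(), cols.tolist()))

    def values_at(self, cells) -> np.ndarray:
        """(n_cells, n_layers) matrix of layer values at the given cells."""
        cells = sorted(cells)
        rows = [c[0] for c in cells]
        cols = [c[1] for c in cells]
        return self.data[:, rows, cols].T

    def shifted(self, deltas: dict) -> "EnvStack":
        """A new stack with per-layer additive deltas (a climate shift)."""
        layers = {}
        for i, name in enumerate(self.names):
            layers[name] = self.data[i] + float(deltas.get(name, 0.0))
        return EnvStack(self.grid, layers)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EnvStack)
            and self.grid == other.grid
            and self.names == other.names
            and np.array_equal(self.data, other.data, equal_nan=True)
        )

    @classmethod
    def from_files(cls, paths) -> "EnvStack":
        """Stack ASCII grids; layer names are the file stems."""
        layers = {}
        grid = None
        for p in map(Path, paths):
            data, g, _ = read_ascii_grid(p)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"{p}: grid mismatch with first layer")
            layers[p.stem] = data
        return cls(grid, layers)

    def to_dir(self, directory) -> list:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = []
        for i, name in enumerate(self.names):
            out.append(
                write_ascii_grid(directory / f"{name}.asc", self.data[i], self.grid)
            )
        return out
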