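"""Regular-grid raster container with ESRI ASCII grid I/O.

Cell (row 0, col 0) is the *top-left* cell, matching the ASCII grid
convention; ``origin_x``/``origin_y`` are the lower-left corner of the
grid in planar metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A regular grid of cell values in a planar CRS.

    Attributes
    ----------
    values : (n_rows, n_cols) float array, row 0 at the top
    origin_x, origin_y : lower-left corner, metres
    cell_size : cell edge length, metres
    nodata : sentinel for missing cells
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) arrays of shape (n_rows, n_cols) of cell centres."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        # row 0 is the top row
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup at points (x, y); NaN outside the extent or
        at nodata cells."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        out = np.full(np.broadcast(x, y).shape, np.nan)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        vals = self.values[row[ok], col[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc) text file."""
    path = Path(path)
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin_x!r}\n")
        fh.write(f"yllcorner {raster.origin_y!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc) text file."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return Raster(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", NODATA),
    )
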