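"""Gridded exposure-surface prediction from a fitted LUR model.

Buffer terms are re-extracted at every grid-cell centre with the same
engine used at the monitoring sites, so the surface is a pure function of
location.  Station-measured covariates (NOx, temperature, RH, ...) have no
natural value away from stations; callers supply a raster per covariate
column — an inverse-distance-weighting helper is provided to build such
rasters from station values, as a transparent (and clearly labelled)
modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .buffers import GeoLayer, extract_at_point
from .model import LURModel
from .raster import NODATA, Raster


@dataclass(frozen=True)
class GridSpec:
    """Regular prediction grid: lower-left origin, square cells."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int
    period: str | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of shape (n_rows, n_cols); row 0 at the top."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)


def predict_at_points(model: LURModel, rows: pd.DataFrame) -> np.ndarray:
    """Evaluate the model on design rows (``intercept + Σ βx``,
    back-transformed when fitted on log10)."""
    return model.predict(rows)


def predict_surface(
    model: LURModel,
    layers: Sequence[GeoLayer],
    covariate_rasters: Mapping[str, Raster],
    grid: GridSpec,
) -> Raster:
    """Apply the model across a grid, producing a concentration raster.

    Layer-derived terms (``layer@radius`` / ``layer@dist``) are extracted
    at each cell centre; every other model column must have an entry in
    ``covariate_rasters`` (checked before any computation).  Cells with
    any missing input get the nodata sentinel.
    """
    layer_names = {ly.name for ly in layers}
    layer_by_name = {ly.name: ly for ly in layers}
    needed_layers: list[tuple[str, GeoLayer]] = []
    covariate_cols: list[str] = []
    for col in model.columns:
        stem = col.split("@")[0]
        if "@" in col and stem in layer_names:
            needed_layers.append((col, layer_by_name[stem]))
        else:
            if col not in covariate_rasters:
                raise ValueError(
                    f"model column {col!r} is not derived from a supplied layer "
                    "and has no covariate raster"
                )
            covariate_cols.append(col)

    xs, ys = grid.cell_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    n_cells = flat_x.size
    frame = pd.DataFrame(index=range(n_cells))

    # covariates: vectorized nearest-cell sampling
    for col in covariate_cols:
        frame[col] = covariate_rasters[col].sample(flat_x, flat_y)

    # layer terms: per-cell extraction, one pass per needed layer
    cache: dict[str, dict[str, np.ndarray]] = {}
    for col, layer in needed_layers:
        if layer.name not in cache:
            per_col: dict[str, list[float]] = {}
            for i in range(n_cells):
                vals = extract_at_point(layer, (flat_x[i], flat_y[i]))
                for k, v in vals.items():
                    per_col.setdefault(k, []).append(v)
            cache[layer.name] = {k: np.asarray(v) for k, v in per_col.items()}
        frame[col] = cache[layer.name][col]

    pred = np.full(n_cells, np.nan)
    ok = np.all(np.isfinite(frame[model.columns].to_numpy(dtype=float)), axis=1) \
        if model.columns else np.ones(n_cells, dtype=bool)
    if ok.any():
        pred[ok] = model.predict(frame.loc[ok])
    values = np.where(np.isfinite(pred), pred, NODATA).reshape(grid.n_rows, grid.n_cols)
    return Raster(values=values, origin_x=grid.origin_x, origin_y=grid.origin_y,
                  cell_size=grid.cell_size, nodata=NODATA)


def idw_raster(
    stations_xy: np.ndarray,
    values: np.ndarray,
    grid: GridSpec,
    power: float = 2.0,
) -> Raster:
    """Inverse-distance-weighted raster of station values (all stations,
    default power 2).  A cell coincident with a station takes that
    station's value exactly."""
    pts = np.asarray(stations_xy, dtype=float).reshape(-1, 2)
    vals = np.asarray(values, dtype=float)
    if len(pts) != len(vals) or len(pts) == 0:
        raise ValueError("need one value per station and at least one station")
    xs, ys = grid.cell_centers()
    dx = xs.ravel()[:, None] - pts[None, :, 0]
    dy = ys.ravel()[:, None] - pts[None, :, 1]
    d = np.hypot(dx, dy)
    out = np.empty(d.shape[0])
    exact = d == 0.0
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=1)
    out = (w @ vals) / np.where(denom == 0.0, 1.0, denom)
    if has_exact.any():
        idx = exact[has_exact].argmax(axis=1)
        out[has_exact] = vals[idx]
    return Raster(values=out.reshape(grid.n_rows, grid.n_cols),
                  origin_x=grid.origin_x, origin_y=grid.origin_y,
                  cell_size=grid.cell_size)
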