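"""Circular-buffer and nearest-distance predictor extraction.

Around each monitoring site, every geospatial layer is summarised inside
closed disks of increasing radius: point layers by count, line layers by
clipped length, polygon layers by intersected area, rasters by the mean of
cell values whose centres fall inside the disk.  Point-source layers can
instead contribute the Euclidean distance to the nearest feature.  The
resulting station-period design matrix is the candidate pool for the
regression model.

All coordinates are planar metres; disk membership uses ``distance <= r``
(closed boundary) so values at exact boundaries are deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, mapping, shape
from shapely.ops import unary_union

from .geodata import StationRecord, ValidationError
from .raster import Raster

#: Default buffer-radius ladder (metres).  The dense 25 m step grid is
#: available through :func:`dense_radii`.
DEFAULT_RADII: tuple[float, ...] = (
    25, 50, 100, 250, 500, 750, 1000, 1250, 1500, 1750,
    2000, 2500, 3000, 3500, 4000, 4500, 5000,
)

MIN_RADIUS, MAX_RADIUS = 25.0, 5000.0

SIGN_PRIORS = ("positive", "negative", "unconstrained")

# quad_segs=64 -> 256-sided inscribed polygon; area error <= (2*pi/256)^2/6
# ~ 1e-4 relative, comfortably inside the documented 0.05% bound.
_DISK_QUAD_SEGS = 64


def dense_radii(step: float = 25.0) -> tuple[float, ...]:
    """The full radius grid from 25 m to 5000 m at the given step."""
    return tuple(np.arange(MIN_RADIUS, MAX_RADIUS + step / 2, step))


@dataclass
class GeoLayer:
    """One predictor source: vector geometry or a raster, with its sign
    prior and extraction mode.

    Attributes
    ----------
    name : column-name stem for this layer
    kind : ``points`` / ``lines`` / ``polygons`` / ``raster``
    points : (n, 2) array of x, y (kind=points)
    lines : list of (k, 2) polyline vertex arrays (kind=lines)
    polygons : list of shapely Polygons (kind=polygons)
    raster : :class:`~lurkit.raster.Raster` (kind=raster)
    sign_prior : expected coefficient direction, used by the selection gate
    mode : ``buffer`` (radius ladder) or ``nearest_distance``
    radii : strictly increasing radii in [25, 5000] m (buffer mode)
    """

    name: str
    kind: str
    points: np.ndarray | None = None
    lines: list[np.ndarray] | None = None
    polygons: list[Polygon] | None = None
    raster: Raster | None = None
    sign_prior: str = "unconstrained"
    mode: str = "buffer"
    radii: Sequence[float] = field(default_factory=lambda: DEFAULT_RADII)

    def __post_init__(self) -> None:
        if self.kind not in ("points", "lines", "polygons", "raster"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.sign_prior not in SIGN_PRIORS:
            raise ValueError(f"unknown sign prior {self.sign_prior!r}")
        if self.mode not in ("buffer", "nearest_distance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "nearest_distance" and self.kind != "points":
            raise ValueError("nearest_distance mode requires a point layer")
        if self.points is not None:
            self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.mode == "buffer":
            radii = tuple(float(r) for r in self.radii)
            if any(b <= a for a, b in zip(radii, radii[1:])):
                raise ValueError(f"layer {self.name!r}: radii must be strictly increasing")
            if radii and (radii[0] < MIN_RADIUS or radii[-1] > MAX_RADIUS):
                raise ValueError(
                    f"layer {self.name!r}: radii must lie in "
                    f"[{MIN_RADIUS}, {MAX_RADIUS}] m"
                )
            self.radii = radii

    @property
    def unit(self) -> str:
        if self.mode == "nearest_distance":
            return "m"
        return {"points": "count", "lines": "m", "polygons": "m2",
                "raster": "raster"}[self.kind]


def count_points_in_buffer(
    layer: GeoLayer, center: Sequence[float], radius: float
) -> int:
    """Number of layer points within the closed disk of ``radius`` around
    ``center``."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    pts = layer.points
    if pts is None or len(pts) == 0:
        return 0
    d2 = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
    return int(np.count_nonzero(d2 <= radius * radius))


def _segment_lengths_in_disk(
    p0: np.ndarray, p1: np.ndarray, center: Sequence[float], radius: float
) -> np.ndarray:
    """Clipped length of each segment p0[i]->p1[i] inside the disk.

    Per segment the squared distance to the centre is quadratic in the
    parameter t, so the in-disk interval is found exactly from the roots of
    |p0 + t d - c|^2 = r^2.
    """
    d = p1 - p0
    f = p0 - np.asarray(center, dtype=float)
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", d, f)
    c = np.einsum("ij,ij->i", f, f) - radius * radius

    lengths = np.zeros(len(p0))
    degenerate = a == 0.0  # zero-length segments contribute nothing
    disc = b * b - 4.0 * a * c
    hit = (~degenerate) & (disc > 0.0)
    if np.any(hit):
        sq = np.sqrt(disc[hit])
        t_lo = (-b[hit] - sq) / (2.0 * a[hit])
        t_hi = (-b[hit] + sq) / (2.0 * a[hit])
        overlap = np.minimum(t_hi, 1.0) - np.maximum(t_lo, 0.0)
        lengths[hit] = np.maximum(overlap, 0.0) * np.sqrt(a[hit])
    return lengths


def line_length_in_buffer(
    layer: GeoLayer, center: Sequence[float], radius: float
) -> float:
    """Total polyline length inside the closed disk, by exact
    segment-circle clipping."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if not layer.lines:
        return 0.0
    p0s, p1s = [], []
    for line in layer.lines:
        arr = np.asarray(line, dtype=float)
        if len(arr) < 2:
            continue
        p0s.append(arr[:-1])
        p1s.append(arr[1:])
    if not p0s:
        return 0.0
    return float(
        _segment_lengths_in_disk(
            np.concatenate(p0s), np.concatenate(p1s), center, radius
        ).sum()
    )


def _disk(center: Sequence[float], radius: float) -> Polygon:
    return Point(center[0], center[1]).buffer(radius, quad_segs=_DISK_QUAD_SEGS)


def polygon_area_in_buffer(
    layer: GeoLayer, center: Sequence[float], radius: float
) -> float:
    """Area of (union of layer polygons) ∩ disk, in m².

    The disk is a regular 256-gon; overlapping polygons are unioned first
    so area is never double-counted.  Invalid (self-intersecting) polygons
    raise :class:`ValidationError` naming the polygon index.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    polys = layer.polygons or []
    for i, poly in enumerate(polys):
        if not poly.is_valid:
            raise ValidationError(f"layer {layer.name!r}: polygon {i} is invalid")
    if not polys:
        return 0.0
    merged = getattr(layer, "_merged", None)
    if merged is None:
        merged = unary_union(polys)
        layer._merged = merged  # cache; layers are static across stations
    cx, cy = float(center[0]), float(center[1])
    # cheap axis-aligned pre-clip before the exact disk intersection
    near = shapely.clip_by_rect(merged, cx - radius, cy - radius,
                                cx + radius, cy + radius)
    if near.is_empty:
        return 0.0
    return float(near.intersection(_disk(center, radius)).area)


def raster_mean_in_buffer(
    layer: GeoLayer, center: Sequence[float], radius: float
) -> float:
    """Mean of raster cell values whose cell centres lie in the closed disk.

    Returns NaN (missing) when no cell centre qualifies; a disk entirely
    outside the raster extent additionally emits a warning.
    """
    rast = layer.raster
    if rast is None:
        raise ValueError(f"layer {layer.name!r} has no raster")
    if radius < rast.cell_size / 2:
        raise ValueError(
            f"radius {radius} m is below half the cell size "
            f"({rast.cell_size / 2} m); no cell centre may qualify"
        )
    cx, cy = center
    xmin = rast.origin_x
    xmax = rast.origin_x + rast.n_cols * rast.cell_size
    ymin = rast.origin_y
    ymax = rast.origin_y + rast.n_rows * rast.cell_size
    if cx + radius < xmin or cx - radius > xmax or cy + radius < ymin or cy - radius > ymax:
        warnings.warn(
            f"buffer at ({cx}, {cy}) r={radius} lies outside raster "
            f"{layer.name!r}; returning missing",
            stacklevel=2,
        )
        return float("nan")
    xs, ys = rast.cell_centers()
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius * radius
    vals = rast.values[inside]
    vals = vals[(vals != rast.nodata) & ~np.isnan(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(vals.mean())


def nearest_distance(layer: GeoLayer, center: Sequence[float]) -> float:
    """Euclidean distance from ``center`` to the nearest layer point."""
    pts = layer.points
    if pts is None or len(pts) == 0:
        raise ValueError(f"layer {layer.name!r} is empty; nearest distance undefined")
    d2 = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
    return float(np.sqrt(d2.min()))


def extract_at_point(layer: GeoLayer, center: Sequence[float]) -> dict[str, float]:
    """All columns this layer contributes at one location."""
    if layer.mode == "nearest_distance":
        return {f"{layer.name}@dist": nearest_distance(layer, center)}
    extractor = {
        "points": count_points_in_buffer,
        "lines": line_length_in_buffer,
        "polygons": polygon_area_in_buffer,
        "raster": raster_mean_in_buffer,
    }[layer.kind]
    return {
        f"{layer.name}@{int(r) if float(r).is_integer() else r}": float(
            extractor(layer, center, r)
        )
        for r in layer.radii
    }


@dataclass
class ColumnMeta:
    """Sidecar metadata for one design-matrix column."""

    layer: str | None
    radius: float | None
    unit: str
    sign_prior: str
    kind: str  # "buffer", "distance", "covariate"
    constant: bool = False

    def to_dict(self) -> dict:
        return {
            "layer": self.layer, "radius": self.radius, "unit": self.unit,
            "sign_prior": self.sign_prior, "kind": self.kind,
            "constant": self.constant,
        }


#: Station-period covariates passed through from the period table, with
#: their conventional sign priors for an ozone response (NOx titration,
#: humidity suppression, warmer/higher/sunnier -> more ozone).
COVARIATE_PRIORS: dict[str, str] = {
    "nox": "negative",
    "co": "negative",
    "temperature": "positive",
    "relative_humidity": "negative",
    "uv": "positive",
    "altitude": "positive",
}


class PredictorTable:
    """Design matrix of station-period rows with per-column metadata.

    ``data`` holds key columns ``station_id`` and ``period`` followed by
    predictor columns; ``meta`` maps each predictor column to its
    :class:`ColumnMeta` (unit, sign prior, provenance, constant flag).
    """

    def __init__(self, data: pd.DataFrame, meta: Mapping[str, ColumnMeta]):
        self.data = data.reset_index(drop=True)
        self.meta = dict(meta)

    @property
    def predictor_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in self.meta]

    @property
    def candidate_columns(self) -> list[str]:
        """Predictor columns eligible for selection (non-constant)."""
        return [c for c in self.predictor_columns if not self.meta[c].constant]

    def sign_priors(self) -> dict[str, str]:
        return {c: self.meta[c].sign_prior for c in self.predictor_columns}

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV plus a ``<path>.meta.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = {c: m.to_dict() for c, m in self.meta.items()}
        Path(str(path) + ".meta.json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictorTable":
        path = Path(path)
        data = pd.read_csv(path, dtype={"station_id": str, "period": str})
        raw = json.loads(Path(str(path) + ".meta.json").read_text(encoding="utf-8"))
        meta = {c: ColumnMeta(**m) for c, m in raw.items()}
        return cls(data, meta)


def build_design_matrix(
    stations: Sequence[StationRecord],
    periods: pd.DataFrame,
    layers: Sequence[GeoLayer],
    covariates: Sequence[str] = ("nox", "temperature", "relative_humidity"),
    include_altitude: bool = True,
) -> PredictorTable:
    """Assemble the candidate design matrix.

    One row per (station, period) in ``periods``.  Layer columns are
    extracted once per station (layers are static in time) and repeated
    across that station's periods; covariate columns (``mean_<name>`` in
    ``periods``) and altitude vary as the period table dictates.  Columns
    constant across all rows are flagged in the metadata and excluded from
    the candidate pool.
    """
    by_id = {s.station_id: s for s in stations}
    missing = sorted(set(periods["station_id"]) - set(by_id))
    if missing:
        raise ValueError(f"station id(s) not in station list: {', '.join(missing)}")

    station_ids = list(dict.fromkeys(periods["station_id"]))
    layer_rows: dict[str, dict[str, float]] = {}
    for sid in station_ids:
        st = by_id[sid]
        row: dict[str, float] = {}
        for layer in layers:
            row.update(extract_at_point(layer, (st.x, st.y)))
        layer_rows[sid] = row

    meta: dict[str, ColumnMeta] = {}
    for layer in layers:
        if layer.mode == "nearest_distance":
            meta[f"{layer.name}@dist"] = ColumnMeta(
                layer.name, None, "m", layer.sign_prior, "distance"
            )
        else:
            for r in layer.radii:
                key = f"{layer.name}@{int(r) if float(r).is_integer() else r}"
                meta[key] = ColumnMeta(
                    layer.name, float(r), layer.unit, layer.sign_prior, "buffer"
                )

    out = periods[["station_id", "period"]].copy()
    layer_frame = pd.DataFrame(
        [layer_rows[sid] for sid in out["station_id"]], index=out.index
    )
    out = pd.concat([out, layer_frame], axis=1)

    for cov in covariates:
        src = f"mean_{cov}"
        if src in periods.columns:
            out[cov] = periods[src].to_numpy()
            meta[cov] = ColumnMeta(
                None, None, "", COVARIATE_PRIORS.get(cov, "unconstrained"),
                "covariate",
            )
    if include_altitude:
        out["altitude"] = [by_id[sid].altitude for sid in out["station_id"]]
        meta["altitude"] = ColumnMeta(
            None, None, "m", COVARIATE_PRIORS["altitude"], "covariate"
        )

    for col in meta:
        vals = out[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0 or (finite.max() - finite.min()) == 0.0:
            meta[col].constant = True
    return PredictorTable(out, meta)


# ---------------------------------------------------------------------------
# GeoJSON layer I/O (planar-metre coordinates)

def write_geojson(layer: GeoLayer, path: str | Path) -> None:
    """Serialize a vector layer to GeoJSON (one Feature per geometry)."""
    feats = []
    if layer.kind == "points":
        for x, y in layer.points if layer.points is not None else []:
            feats.append({"type": "Feature", "properties": {},
                          "geometry": {"type": "Point", "coordinates": [x, y]}})
    elif layer.kind == "lines":
        for line in layer.lines or []:
            feats.append({"type": "Feature", "properties": {},
                          "geometry": mapping(LineString(np.asarray(line)))})
    elif layer.kind == "polygons":
        for poly in layer.polygons or []:
            feats.append({"type": "Feature", "properties": {},
                          "geometry": mapping(poly)})
    else:
        raise ValueError("raster layers are written as ASCII grids, not GeoJSON")
    doc = {
        "type": "FeatureCollection",
        "name": layer.name,
        "properties": {
            "sign_prior": layer.sign_prior,
            "mode": layer.mode,
            "radii": list(layer.radii) if layer.mode == "buffer" else None,
            "kind": layer.kind,
        },
        "features": feats,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True), encoding="utf-8")


def read_geojson(path: str | Path, name: str | None = None) -> GeoLayer:
    """Read a vector layer from GeoJSON written by :func:`write_geojson`
    (or any FeatureCollection of a single geometry family)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    props = doc.get("properties", {})
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    kind = props.get("kind")
    if kind is None and geoms:
        kind = {"Point": "points", "MultiPoint": "points",
                "LineString": "lines", "MultiLineString": "lines",
                "Polygon": "polygons", "MultiPolygon": "polygons"}[geoms[0].geom_type]
    kwargs: dict = {}
    if kind == "points":
        pts: list[list[float]] = []
        for g in geoms:
            if g.geom_type == "Point":
                pts.append([g.x, g.y])
            else:
                pts.extend([[p.x, p.y] for p in g.geoms])
        kwargs["points"] = np.asarray(pts, dtype=float).reshape(-1, 2)
    elif kind == "lines":
        lines: list[np.ndarray] = []
        for g in geoms:
            parts = g.geoms if g.geom_type == "MultiLineString" else [g]
            lines.extend(np.asarray(part.coords, dtype=float) for part in parts)
        kwargs["lines"] = lines
    elif kind == "polygons":
        polys: list[Polygon] = []
        for g in geoms:
            parts = g.geoms if g.geom_type == "MultiPolygon" else [g]
            polys.extend(parts)
        kwargs["polygons"] = polys
    else:
        raise ValueError(f"unsupported or empty layer in {path}")
    layer_kwargs = dict(
        name=name or doc.get("name", Path(path).stem),
        kind=kind,
        sign_prior=props.get("sign_prior", "unconstrained"),
        mode=props.get("mode", "buffer"),
        **kwargs,
    )
    if props.get("radii"):
        layer_kwargs["radii"] = props["radii"]
    return GeoLayer(**layer_kwargs)
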