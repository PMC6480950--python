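#!/usr/bin/env python
"""Apply the fitted model across a regular grid to map the ozone surface.

Buffer terms are re-extracted at every cell centre; station-measured
covariates (NOx, temperature, RH, altitude) are rasterized from the
station values by inverse-distance weighting (power 2) — a transparent
modelling choice, since such covariates have no measured value away from
stations.  Writes results/surface.asc (ESRI ASCII grid, ppb).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import lurkit as lk
from lurkit.raster import write_ascii_grid

from importlib.util import spec_from_file_location, module_from_spec

_fit = module_from_spec(spec_from_file_location(
    "fit_model", Path(__file__).parent / "02_fit_model.py"))
_fit.__spec__.loader.exec_module(_fit)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scene", type=Path, default=Path("results/scene"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--cells", type=int, default=25,
                        help="grid cells per side")
    args = parser.parse_args()

    stations, periods, layers, truth = _fit.load_scene_dir(args.scene)
    model = lk.LURModel.load(args.out / "model.json")
    design = lk.build_design_matrix(stations, periods, layers)

    width = max(s.x for s in stations)
    cell = width / args.cells
    grid = lk.GridSpec(0.0, 0.0, cell, args.cells, args.cells)

    xy = np.array([[s.x, s.y] for s in stations])
    by_station = design.data.groupby("station_id", sort=True).mean(numeric_only=True)
    order = [s.station_id for s in stations]
    covs = {}
    for col in model.columns:
        if "@" not in col:
            covs[col] = lk.idw_raster(
                xy, by_station.loc[order, col].to_numpy(float), grid)

    surface = lk.predict_surface(model, layers, covs, grid)
    write_ascii_grid(surface, args.out / "surface.asc")

    vals = surface.values[surface.values != surface.nodata]
    print(f"surface {args.cells}x{args.cells} @ {cell:.0f} m -> "
          f"{args.out / 'surface.asc'}")
    print(f"predicted O3 range: {vals.min():.2f}-{vals.max():.2f} ppb, "
          f"mean {vals.mean():.2f} ppb")


if __name__ == "__main__":
    main()
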