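#!/usr/bin/env python
"""Fit the LUR model to the serialized scene by supervised forward
selection (p < 0.1, VIF < 3, sign priors) and write the fitted model.

Reads results/scene/ as an external consumer would — stations CSV,
GeoJSON layers, ASCII-grid NDVI, covariates CSV — rebuilds the design
matrix through the buffer engine, selects the model, and writes
results/model.json plus a publication-style summary table
results/model_summary.csv (coefficient, p-value, incremental R² per term
in entry order).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import lurkit as lk
from lurkit.buffers import GeoLayer, read_geojson
from lurkit.model import summary_csv
from lurkit.raster import read_ascii_grid

VECTOR_LAYERS = ("temple", "cemetery", "major_road", "local_road",
                 "residential", "industrial", "forest", "crop",
                 "power_plant", "incinerator")


def load_scene_dir(path: Path):
    stations = lk.load_stations(path / "stations.csv")
    periods = pd.read_csv(path / "covariates.csv",
                          dtype={"station_id": str, "period": str})
    layers = [read_geojson(path / f"{name}.geojson", name=name)
              for name in VECTOR_LAYERS]
    ndvi_radii = tuple(r for r in lk.DEFAULT_RADII if r >= 250.0)
    layers.append(GeoLayer("ndvi", "raster",
                           raster=read_ascii_grid(path / "ndvi.asc"),
                           sign_prior="positive", radii=ndvi_radii))
    truth = json.loads((path / "truth.json").read_text())
    return stations, periods, layers, truth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scene", type=Path, default=Path("results/scene"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    stations, periods, layers, truth = load_scene_dir(args.scene)
    design = lk.build_design_matrix(stations, periods, layers)
    response = pd.Series(truth["response"], dtype=float).to_numpy()

    model = lk.forward_select(design, response, lk.SelectionConfig())
    model.save(args.out / "model.json")
    (args.out / "model_summary.csv").write_text(summary_csv(model))

    print(f"selected {len(model.terms)} terms "
          f"(R2={model.r2:.3f}, adj R2={model.adjusted_r2:.3f}, "
          f"RMSE={model.rmse:.3f} ppb, n={model.n_obs})")
    print(f"{'variable':<22} {'coef':>12} {'p':>8} {'incr R2':>9}")
    for t in model.terms:
        print(f"{t.name:<22} {t.coefficient:>12.4g} {t.p_value:>8.3f} "
              f"{t.incremental_r2:>9.4f}")
    true_cols = set(truth["truth"]["coefficients"])
    tp = true_cols & set(model.columns)
    print(f"planted-term recovery: {len(tp)}/{len(true_cols)}; "
          f"false positives: {len(set(model.columns) - true_cols)}")


if __name__ == "__main__":
    main()
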