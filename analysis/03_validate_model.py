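#!/usr/bin/env python
"""Validate the fitted model: site-grouped 10-fold CV (with per-fold
re-selection) and temporal external validation on the last year.

Writes results/validation.json and prints the pooled out-of-fold R²
(squared-Pearson convention, with the 1 - SSE/SST alternative alongside)
and the external R².
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import lurkit as lk

from importlib.util import spec_from_file_location, module_from_spec

_fit = module_from_spec(spec_from_file_location(
    "fit_model", Path(__file__).parent / "02_fit_model.py"))
_fit.__spec__.loader.exec_module(_fit)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scene", type=Path, default=Path("results/scene"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--seed", type=int, default=42)
    args = parser.parse_args()

    stations, periods, layers, truth = _fit.load_scene_dir(args.scene)
    design = lk.build_design_matrix(stations, periods, layers)
    response = pd.Series(truth["response"], dtype=float).to_numpy()

    folds = lk.make_site_folds(stations, args.folds, seed=args.seed)
    cv = lk.cross_validate(design, response, lk.SelectionConfig(), folds)

    holdout = sorted(design.data["period"].unique())[-1]
    ext = lk.external_validate(design, response, lk.SelectionConfig(), holdout)

    report = {"cross_validation": json.loads(cv.to_json()),
              "external": json.loads(ext.to_json()),
              "holdout_period": holdout}
    (args.out / "validation.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))

    print(f"10-fold site-grouped CV: pooled R2 = {cv.cv_r2:.3f} "
          f"(1-SSE/SST = {cv.cv_r2_ss:.3f}), RMSE = {cv.cv_rmse:.3f} ppb")
    print(f"external validation on {holdout}: R2 = {ext.external_r2:.3f} "
          f"(n = {ext.n})")


if __name__ == "__main__":
    main()
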