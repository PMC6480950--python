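"""Site-grouped k-fold cross-validation and temporal external validation.

Folds partition monitoring *sites*, so all periods of a station are held
out together — each site serves as a validation benchmark exactly once.
By default the full forward-selection procedure is re-run on every
training split ("reselect" mode); "refit" mode re-estimates a fixed term
set instead, for comparison.  Pooled CV R² is the squared Pearson
correlation between out-of-fold predictions and observations; the
1 − SSE/SST convention is reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .buffers import PredictorTable
from .geodata import StationRecord
from .model import LURModel, SelectionConfig, fit_ols, forward_select


@dataclass(frozen=True)
class FoldAssignment:
    """Random partition of stations into k folds (sizes differ by ≤ 1)."""

    mapping: dict[str, int]
    k: int
    seed: int

    def stations_in_fold(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.mapping.items() if f == fold)


def make_site_folds(
    stations: Sequence[StationRecord] | Sequence[str], k: int, seed: int
) -> FoldAssignment:
    """Uniform random site-grouped partition, reproducible from ``seed``."""
    ids = sorted(
        s.station_id if isinstance(s, StationRecord) else str(s) for s in stations
    )
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of stations ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    mapping = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return FoldAssignment(mapping=mapping, k=k, seed=seed)


@dataclass
class FoldResult:
    fold: int
    n: int
    r2: float
    rmse: float
    failed: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        return {"fold": self.fold, "n": self.n, "r2": self.r2,
                "rmse": self.rmse, "failed": self.failed,
                "message": self.message}


@dataclass
class ValidationReport:
    """Cross-validation / external-validation summary.

    ``cv_r2`` is the squared Pearson correlation of pooled out-of-fold
    predictions vs observations; ``cv_r2_ss`` is the 1 − SSE/SST
    alternative on the same pooled vectors.
    """

    folds: list[FoldResult]
    cv_r2: float
    cv_rmse: float
    cv_r2_ss: float
    n: int
    convention: str = "pearson_squared_pooled_oof"
    external_r2: float | None = None
    mode: str = "reselect"

    def to_json(self) -> str:
        doc = {
            "folds": [f.to_dict() for f in self.folds],
            "cv_r2": self.cv_r2,
            "cv_rmse": self.cv_rmse,
            "cv_r2_ss": self.cv_r2_ss,
            "n": self.n,
            "convention": self.convention,
            "external_r2": self.external_r2,
            "mode": self.mode,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _pearson_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    if len(obs) < 2 or obs.std() == 0.0 or pred.std() == 0.0:
        return 0.0
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r


def _ss_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    return 1.0 - float(((obs - pred) ** 2).sum()) / sst


def _fit_for_split(
    design: PredictorTable,
    y: np.ndarray,
    train: np.ndarray,
    config: SelectionConfig,
    mode: str,
    fixed_terms: list[str] | None,
) -> LURModel:
    train_table = PredictorTable(design.data.loc[train].copy(), design.meta)
    if mode == "reselect":
        return forward_select(train_table, y[train], config)
    if mode == "refit":
        if not fixed_terms:
            full = forward_select(design, y, config)
            fixed_terms = full.columns
        fit = fit_ols(train_table.data[fixed_terms], y[train])
        from .model import FittedTerm  # local to avoid clutter at module top

        terms = [
            FittedTerm(name=c, coefficient=float(b), p_value=float(p),
                       incremental_r2=0.0,
                       sign_prior=design.meta[c].sign_prior if c in design.meta
                       else "unconstrained")
            for c, b, p in zip(fixed_terms, fit.coefficients, fit.p_values)
        ]
        return LURModel(intercept=fit.intercept, terms=terms, r2=fit.r2,
                        adjusted_r2=fit.adjusted_r2, rmse=fit.rmse,
                        n_obs=fit.n_obs,
                        response_transform=config.response_transform)
    raise ValueError(f"unknown mode {mode!r}")


def cross_validate(
    design: PredictorTable,
    response,
    config: SelectionConfig,
    folds: FoldAssignment,
    mode: str = "reselect",
) -> ValidationReport:
    """Site-grouped k-fold CV with per-fold model development.

    Every fold's held-out stations are predicted by a model that never saw
    them; pooled statistics use out-of-fold predictions only.  A fold whose
    training split cannot be fitted is marked failed and excluded from the
    pooled vectors.
    """
    stations_in_design = set(design.data["station_id"])
    uncovered = stations_in_design - set(folds.mapping)
    if uncovered:
        raise ValueError(f"folds do not cover station(s): {', '.join(sorted(uncovered))}")

    y = np.asarray(response, dtype=float)
    fold_of_row = design.data["station_id"].map(folds.mapping).to_numpy()
    fixed_terms: list[str] | None = None
    if mode == "refit":
        fixed_terms = forward_select(design, y, config).columns

    results: list[FoldResult] = []
    pooled_obs: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for f in range(folds.k):
        test = fold_of_row == f
        train = ~test
        if not test.any():
            continue
        try:
            model = _fit_for_split(design, y, train, config, mode, fixed_terms)
            pred = model.predict(design.data.loc[test])
        except (ValueError, KeyError) as exc:
            results.append(FoldResult(fold=f, n=int(test.sum()), r2=float("nan"),
                                      rmse=float("nan"), failed=True,
                                      message=str(exc)))
            continue
        obs = y[test]
        results.append(FoldResult(
            fold=f, n=int(test.sum()), r2=_pearson_r2(obs, pred),
            rmse=float(np.sqrt(np.mean((obs - pred) ** 2))),
        ))
        pooled_obs.append(obs)
        pooled_pred.append(pred)

    if pooled_obs:
        obs = np.concatenate(pooled_obs)
        pred = np.concatenate(pooled_pred)
        cv_r2 = _pearson_r2(obs, pred)
        cv_rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
        cv_ss = _ss_r2(obs, pred)
        n = len(obs)
    else:
        cv_r2 = cv_rmse = cv_ss = float("nan")
        n = 0
    return ValidationReport(folds=results, cv_r2=cv_r2, cv_rmse=cv_rmse,
                            cv_r2_ss=cv_ss, n=n, mode=mode)


def external_validate(
    design: PredictorTable,
    response,
    config: SelectionConfig,
    holdout_period: str | int,
) -> ValidationReport:
    """Temporal external validation: select and fit on all periods before
    ``holdout_period``, evaluate on the holdout rows only."""
    holdout = str(holdout_period)
    periods = design.data["period"].astype(str)
    test = (periods == holdout).to_numpy()
    train = (periods < holdout).to_numpy()
    if not test.any():
        raise ValueError(f"holdout period {holdout!r} absent from design")
    if not train.any():
        raise ValueError(f"no training periods before {holdout!r}")

    y = np.asarray(response, dtype=float)
    model = _fit_for_split(design, y, train, config, "reselect", None)
    pred = model.predict(design.data.loc[test])
    obs = y[test]
    ext_r2 = _pearson_r2(obs, pred)
    fold = FoldResult(fold=0, n=int(test.sum()), r2=ext_r2,
                      rmse=float(np.sqrt(np.mean((obs - pred) ** 2))))
    return ValidationReport(
        folds=[fold], cv_r2=ext_r2, cv_rmse=fold.rmse,
        cv_r2_ss=_ss_r2(obs, pred), n=int(test.sum()),
        external_r2=ext_r2, mode="external",
    )
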