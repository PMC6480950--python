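"""Sign-constrained supervised forward selection with p-value and VIF gates.

The model-building procedure mirrors established land-use-regression
practice: every candidate predictor carries an a-priori direction of
effect; the model is seeded with the best-explaining direction-consistent
candidate, and candidates are then added one at a time.  A candidate is
admissible only if (i) its own two-sided t-test p-value is below
``p_enter`` (default 0.1), (ii) its coefficient sign matches its prior,
(iii) no previously entered constrained term flips sign, and (iv) every
variance inflation factor in the augmented model stays below ``vif_max``
(default 3).  Among admissible candidates, the one with the largest
adjusted-R² gain enters; entered terms are never removed.  The procedure
stops when no candidate is admissible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .buffers import PredictorTable

SCHEMA_VERSION = 1


class RankDeficientError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: Sequence[str], context: str = ""):
        self.columns = list(columns)
        msg = f"design matrix is rank deficient; collinear column(s): {', '.join(self.columns)}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


@dataclass(frozen=True)
class SelectionConfig:
    """Gates and options for the forward-selection procedure.

    ``p_enter`` and ``vif_max`` are the entry gates; ``min_adj_r2_gain``
    additionally requires each accepted step to improve adjusted R² by
    more than this amount.  ``response_transform`` may be ``"identity"``
    or ``"log10"``.  ``recheck_signs`` re-validates the signs of already
    entered constrained terms at every admission (on by default).
    ``seed`` only labels audit output; the procedure is deterministic.
    """

    p_enter: float = 0.1
    vif_max: float = 3.0
    min_adj_r2_gain: float = 0.0
    response_transform: str = "identity"
    max_terms: int | None = None
    recheck_signs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_enter < 1.0):
            raise ValueError(f"p_enter must be in (0, 1), got {self.p_enter}")
        if self.vif_max <= 1.0:
            raise ValueError(f"vif_max must be > 1, got {self.vif_max}")
        if self.response_transform not in ("identity", "log10"):
            raise ValueError(f"unknown response_transform {self.response_transform!r}")


@dataclass
class FittedTerm:
    """One model term: final coefficient and p-value, plus the R² gain
    recorded when the term entered the selection sequence."""

    name: str
    coefficient: float
    p_value: float
    incremental_r2: float
    sign_prior: str = "unconstrained"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coefficient": self.coefficient,
            "p_value": self.p_value,
            "incremental_r2": self.incremental_r2,
            "sign_prior": self.sign_prior,
        }


@dataclass
class LURModel:
    """A fitted land-use-regression model (terms in entry order)."""

    intercept: float
    terms: list[FittedTerm]
    r2: float
    adjusted_r2: float
    rmse: float
    n_obs: int
    response_transform: str = "identity"

    @property
    def columns(self) -> list[str]:
        return [t.name for t in self.terms]

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Linear prediction ``intercept + X @ beta``, back-transformed if
        the response was fitted on the log10 scale.  Raises ``KeyError``
        naming any model column absent from ``rows``."""
        missing = [c for c in self.columns if c not in rows.columns]
        if missing:
            raise KeyError(f"missing model column(s): {', '.join(missing)}")
        yhat = np.full(len(rows), self.intercept, dtype=float)
        for t in self.terms:
            yhat += t.coefficient * rows[t.name].to_numpy(dtype=float)
        if self.response_transform == "log10":
            yhat = np.power(10.0, yhat)
        return yhat

    def to_json(self) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "intercept": self.intercept,
            "terms": [t.to_dict() for t in self.terms],
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "rmse": self.rmse,
            "n_obs": self.n_obs,
            "response_transform": self.response_transform,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "LURModel":
        doc = json.loads(text)
        return cls(
            intercept=doc["intercept"],
            terms=[FittedTerm(**t) for t in doc["terms"]],
            r2=doc["r2"],
            adjusted_r2=doc["adjusted_r2"],
            rmse=doc["rmse"],
            n_obs=doc["n_obs"],
            response_transform=doc.get("response_transform", "identity"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LURModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass
class OLSFit:
    """Ordinary-least-squares fit of ``response ~ 1 + columns``."""

    columns: list[str]
    intercept: float
    coefficients: np.ndarray       # slope per column
    p_values: np.ndarray           # two-sided t-test per slope
    intercept_p: float
    r2: float
    adjusted_r2: float
    rmse: float
    n_obs: int


def _design_array(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, PredictorTable):
        cols = design.predictor_columns
        return design.data[cols].to_numpy(dtype=float), cols
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    arr = np.asarray(design, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _ols_core(X: np.ndarray, y: np.ndarray, names: list[str]) -> OLSFit:
    """Least squares on the augmented matrix [1 | X]; p-values from the
    classical t-statistics.  Degenerate cases follow documented
    conventions: constant response -> r2 = 0; zero-residual fits give
    p = 0 for nonzero coefficients."""
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n_obs > n_predictors + 1 (n={n}, p={p})")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("design or response contains non-finite values; "
                         "apply complete-case filtering first")
    A = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        # identify columns that do not extend the rank, in order
        bad, kept = [], [np.ones(n)]
        r_prev = 1
        for j in range(p):
            cand = np.column_stack(kept + [X[:, j]])
            r_new = np.linalg.matrix_rank(cand)
            if r_new == r_prev:
                bad.append(names[j])
            else:
                kept.append(X[:, j])
                r_prev = r_new
        raise RankDeficientError(bad or names)

    resid = y - A @ beta
    rss = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if sst == 0.0 else 1.0 - rss / sst
    dof = n - p - 1
    adj = 0.0 if sst == 0.0 else 1.0 - (1.0 - r2) * (n - 1) / dof
    rmse = float(np.sqrt(rss / n))

    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = np.where(
        se > 0.0,
        2.0 * stats.t.sf(np.abs(tvals), dof),
        np.where(beta != 0.0, 0.0, 1.0),
    )
    return OLSFit(
        columns=list(names),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        p_values=pvals[1:].copy(),
        intercept_p=float(pvals[0]),
        r2=r2,
        adjusted_r2=adj,
        rmse=rmse,
        n_obs=n,
    )


def fit_ols(design, response) -> OLSFit:
    """Fit ``response ~ 1 + design`` by ordinary least squares.

    ``design`` may be a :class:`PredictorTable`, a DataFrame of predictor
    columns, or a 2-D array.  Raises :class:`RankDeficientError` listing
    collinear columns when the design has deficient rank.
    """
    X, names = _design_array(design)
    y = np.asarray(response, dtype=float)
    return _ols_core(X, y, names)


def vif(design) -> pd.Series:
    """Variance inflation factor per column: ``1 / (1 - R²_j)`` from
    regressing column j on the remaining columns plus an intercept.
    Perfect collinearity yields ``inf``."""
    X, names = _design_array(design)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    return pd.Series(_vif_values(X), index=names)


def _vif_values(X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        sst = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        if sst == 0.0:
            out[j] = np.inf
            continue
        r2j = 1.0 - float(resid @ resid) / sst
        out[j] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return out


def _univariate_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(r2, slope sign) of y ~ 1 + x, via the sample correlation."""
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0, 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r, float(np.sign(r))


def _sign_ok(coef_sign: float, prior: str) -> bool:
    if prior == "positive":
        return coef_sign > 0
    if prior == "negative":
        return coef_sign < 0
    return True


def univariate_screen(
    design: PredictorTable | pd.DataFrame,
    response,
    priors: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank candidates by univariate R²; mark direction-consistent ones.

    Returns a DataFrame (``column, r2, sign, eligible``) sorted by R²
    descending, ties by column name.  A candidate is eligible iff its
    univariate slope sign matches its prior; unconstrained priors are
    always eligible.
    """
    if isinstance(design, PredictorTable):
        priors = priors or design.sign_priors()
        frame = design.data[design.candidate_columns]
    else:
        frame = design
        priors = priors or {}
    y = np.asarray(response, dtype=float)
    rows = []
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        r2, sign = _univariate_stats(x, y)
        prior = priors.get(col, "unconstrained")
        rows.append((col, r2, sign, _sign_ok(sign, prior)))
    out = pd.DataFrame(rows, columns=["column", "r2", "sign", "eligible"])
    return out.sort_values(
        ["r2", "column"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def forward_select(
    design: PredictorTable | pd.DataFrame,
    response,
    config: SelectionConfig = SelectionConfig(),
    priors: dict[str, str] | None = None,
) -> LURModel:
    """Run the supervised sign-constrained forward selection.

    Rows with a missing response are dropped; candidate columns that are
    constant or contain missing values on the remaining rows are excluded
    from the pool (this keeps every candidate comparison on one common row
    set).  Ties in adjusted-R² gain break by smaller candidate p-value,
    then lexicographic column name, making the procedure fully
    deterministic.
    """
    if isinstance(design, PredictorTable):
        priors = priors or design.sign_priors()
        frame = design.data[design.predictor_columns]
    else:
        frame = design
        priors = dict(priors or {})

    y_raw = np.asarray(response, dtype=float)
    keep = np.isfinite(y_raw)
    y = y_raw[keep]
    if config.response_transform == "log10":
        if np.any(y <= 0):
            raise ValueError("log10 response transform requires positive values")
        y = np.log10(y)
    n = len(y)

    pool: list[str] = []
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)[keep]
        if np.all(np.isfinite(x)) and x.std() > 0.0:
            pool.append(col)
    Xall = frame[pool].to_numpy(dtype=float)[keep]
    col_idx = {c: i for i, c in enumerate(pool)}

    def build(cols: list[str]) -> OLSFit:
        sub = Xall[:, [col_idx[c] for c in cols]]
        return _ols_core(sub, y, cols)

    # step 1: seed with the top direction-consistent univariate candidate
    screen = univariate_screen(frame[pool].iloc[np.flatnonzero(keep)], y, priors)
    eligible = screen[screen["eligible"] & (screen["r2"] > 0)]
    entry_r2: list[float] = []
    if len(eligible) == 0:
        fit0 = _ols_core(np.empty((n, 0)), y, [])
        return _assemble(fit0, [], entry_r2, priors, config)

    selected = [str(eligible.iloc[0]["column"])]
    fit = build(selected)
    entry_r2.append(fit.r2)

    while True:
        if config.max_terms is not None and len(selected) >= config.max_terms:
            break
        if 1.0 - fit.r2 < 1e-12:  # perfect fit; nothing left to explain
            break
        best: tuple | None = None
        for cand in pool:
            if cand in selected:
                continue
            cols = selected + [cand]
            try:
                trial = build(cols)
            except RankDeficientError:
                continue
            cand_p = float(trial.p_values[-1])
            if not (cand_p < config.p_enter):
                continue
            if not _sign_ok(np.sign(trial.coefficients[-1]), priors.get(cand, "unconstrained")):
                continue
            if config.recheck_signs and not all(
                _sign_ok(np.sign(b), priors.get(c, "unconstrained"))
                for c, b in zip(cols[:-1], trial.coefficients[:-1])
            ):
                continue
            if len(cols) >= 2:
                vifs = _vif_values(Xall[:, [col_idx[c] for c in cols]])
                if not np.all(vifs < config.vif_max):
                    continue
            gain = trial.adjusted_r2 - fit.adjusted_r2
            if gain <= config.min_adj_r2_gain:
                continue
            key = (-gain, cand_p, cand)
            if best is None or key < best[0]:
                best = (key, cand, trial)
        if best is None:
            break
        _, cand, trial = best
        selected.append(cand)
        entry_r2.append(trial.r2)
        fit = trial

    return _assemble(fit, selected, entry_r2, priors, config)


def _assemble(
    fit: OLSFit,
    selected: list[str],
    entry_r2: list[float],
    priors: dict[str, str],
    config: SelectionConfig,
) -> LURModel:
    terms = []
    prev = 0.0
    for i, name in enumerate(selected):
        inc = entry_r2[i] - prev
        prev = entry_r2[i]
        terms.append(
            FittedTerm(
                name=name,
                coefficient=float(fit.coefficients[i]),
                p_value=float(fit.p_values[i]),
                incremental_r2=float(inc),
                sign_prior=priors.get(name, "unconstrained"),
            )
        )
    return LURModel(
        intercept=fit.intercept,
        terms=terms,
        r2=fit.r2,
        adjusted_r2=fit.adjusted_r2,
        rmse=fit.rmse,
        n_obs=fit.n_obs,
        response_transform=config.response_transform,
    )


def summarize(model: LURModel) -> pd.DataFrame:
    """Publication-style summary: one row per term in entry order, an
    intercept row first, and footer metrics as attrs.  Round-trips
    byte-stably through CSV for a fixed model."""
    rows = [{"variable": "(intercept)", "coefficient": model.intercept,
             "p_value": np.nan, "incremental_r2": np.nan}]
    for t in model.terms:
        rows.append({"variable": t.name, "coefficient": t.coefficient,
                     "p_value": t.p_value, "incremental_r2": t.incremental_r2})
    out = pd.DataFrame(rows, columns=["variable", "coefficient", "p_value",
                                      "incremental_r2"])
    out.attrs["footer"] = {
        "r2": model.r2, "adjusted_r2": model.adjusted_r2,
        "rmse": model.rmse, "n_obs": model.n_obs,
    }
    return out


def summary_csv(model: LURModel) -> str:
    """Byte-stable CSV rendering of :func:`summarize` plus footer lines."""
    table = summarize(model)
    lines = ["variable,coefficient,p_value,incremental_r2"]
    for _, r in table.iterrows():
        p = "" if np.isnan(r["p_value"]) else repr(float(r["p_value"]))
        inc = "" if np.isnan(r["incremental_r2"]) else repr(float(r["incremental_r2"]))
        lines.append(f"{r['variable']},{float(r['coefficient'])!r},{p},{inc}")
    f = table.attrs["footer"]
    lines.append(f"# r2={f['r2']!r} adjusted_r2={f['adjusted_r2']!r} "
                 f"rmse={f['rmse']!r} n_obs={f['n_obs']}")
    return "\n".join(lines) + "\n"
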