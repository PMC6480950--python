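"""Station and measurement data model, temporal aggregation, unit conversion.

Monitoring networks report daily pollutant and meteorology values per
station.  LUR models are fitted to period (annual or monthly) means, and a
station-period is retained only if enough of its days carry a valid
pollutant value.  Coordinates are planar metres in a single projected CRS
throughout the package; callers working from lon/lat must project first.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class StationClass(str, enum.Enum):
    """Monitoring-station typology (general / traffic / industrial /
    national_park / background / other)."""

    GENERAL = "general"
    TRAFFIC = "traffic"
    INDUSTRIAL = "industrial"
    NATIONAL_PARK = "national_park"
    BACKGROUND = "background"
    OTHER = "other"


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Input rows violate a data invariant (duplicates, out-of-range)."""


@dataclass(frozen=True)
class StationRecord:
    """One monitoring site.

    Attributes
    ----------
    station_id : unique identifier within a study
    x, y : planar coordinates in metres
    altitude : metres above sea level (also usable as a predictor)
    station_class : one of :class:`StationClass`
    """

    station_id: str
    x: float
    y: float
    altitude: float
    station_class: StationClass = StationClass.GENERAL

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"station {self.station_id!r}: coordinates must be finite"
            )
        if not (-500.0 <= self.altitude <= 9000.0):
            raise ValidationError(
                f"station {self.station_id!r}: altitude {self.altitude} "
                "outside [-500, 9000] m"
            )


STATION_COLUMNS = ("station_id", "x", "y", "altitude", "station_class")

#: Daily-measurement value columns; all but temperature/RH may be missing.
MEASUREMENT_COLUMNS = ("o3", "nox", "co", "temperature", "relative_humidity", "uv")


def load_stations(path: str | Path) -> list[StationRecord]:
    """Read stations from a UTF-8 CSV with header.

    Required columns: station_id, x, y, altitude, station_class.
    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` listing duplicated ids.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in STATION_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = [
            StationRecord(
                station_id=row["station_id"],
                x=float(row["x"]),
                y=float(row["y"]),
                altitude=float(row["altitude"]),
                station_class=StationClass(row["station_class"]),
            )
            for row in reader
        ]
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.station_id] = seen.get(rec.station_id, 0) + 1
    dupes = sorted(sid for sid, n in seen.items() if n > 1)
    if dupes:
        raise ValidationError(f"duplicate station_id(s): {', '.join(dupes)}")
    return records


def write_stations(stations: Iterable[StationRecord], path: str | Path) -> None:
    """Write stations to CSV (inverse of :func:`load_stations`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STATION_COLUMNS)
        for s in stations:
            writer.writerow(
                [s.station_id, repr(s.x), repr(s.y), repr(s.altitude),
                 s.station_class.value]
            )


def _period_key(dates: pd.Series, resolution: str) -> pd.Series:
    if resolution == "annual":
        return dates.dt.year.astype(str)
    if resolution == "monthly":
        return dates.dt.strftime("%Y-%m")
    raise ValueError(f"resolution must be 'annual' or 'monthly', got {resolution!r}")


def _days_in_period(period: str) -> int:
    if "-" in period:
        y, m = (int(p) for p in period.split("-"))
        return pd.Period(f"{y}-{m:02d}", freq="M").days_in_month
    y = int(period)
    return 366 if pd.Timestamp(year=y, month=12, day=31).is_leap_year else 365


def aggregate_to_periods(
    daily: pd.DataFrame,
    resolution: str = "annual",
    completeness: float = 0.75,
) -> pd.DataFrame:
    """Aggregate daily measurements to annual or monthly station means.

    Parameters
    ----------
    daily : DataFrame with columns ``station_id``, ``date`` (parseable to
        datetime) and any of :data:`MEASUREMENT_COLUMNS`; missing values
        are NaN.
    resolution : ``"annual"`` or ``"monthly"``.
    completeness : minimum fraction of the period's calendar days with a
        valid (non-missing) o3 value for the row to be retained; the
        conventional regulatory default is 0.75.

    Returns
    -------
    DataFrame with one row per retained (station_id, period):
    ``station_id, period, mean_<var>..., n_valid_days``.  Each variable's
    mean is over the days where that variable is present.  Empty input
    yields an empty frame with the full schema.
    """
    if not (0.0 < completeness <= 1.0):
        raise ValueError(f"completeness must be in (0, 1], got {completeness}")
    value_cols = [c for c in MEASUREMENT_COLUMNS if c in daily.columns]
    out_cols = (["station_id", "period"]
                + [f"mean_{c}" for c in value_cols] + ["n_valid_days"])
    if len(daily) == 0:
        return pd.DataFrame(columns=out_cols)

    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "relative_humidity" in df.columns:
        rh = df["relative_humidity"].dropna()
        bad = rh[(rh < 0) | (rh > 100)]
        if len(bad):
            raise ValidationError("relative_humidity outside [0, 100]")
    df["period"] = _period_key(df["date"], resolution)

    grouped = df.groupby(["station_id", "period"], sort=True)
    agg = grouped[value_cols].mean()
    agg.columns = [f"mean_{c}" for c in value_cols]
    agg["n_valid_days"] = grouped["o3"].count() if "o3" in value_cols else grouped.size()
    agg = agg.reset_index()

    required = agg["period"].map(_days_in_period) * completeness
    agg = agg[agg["n_valid_days"] >= required].reset_index(drop=True)
    agg["n_valid_days"] = agg["n_valid_days"].astype(int)
    return agg[out_cols]


# 25 degC / 1 atm molar volume; reproduces the usual ppb <-> ug/m3 tables.
MOLAR_VOLUME_25C = 24.45
O3_MOLAR_MASS = 48.00


def ppb_to_mass_concentration(
    c: float,
    molar_mass: float = O3_MOLAR_MASS,
    molar_volume: float = MOLAR_VOLUME_25C,
) -> float:
    """Convert a mixing ratio in ppb to a mass concentration in ug/m3.

    ``ug/m3 = ppb * M / Vm`` with molar mass ``M`` (g/mol) and molar volume
    ``Vm`` (L/mol, default 24.45 at 25 degC / 1 atm).
    """
    if molar_volume <= 0:
        raise ValueError(f"molar_volume must be positive, got {molar_volume}")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c * molar_mass / molar_volume


def mass_concentration_to_ppb(
    c: float,
    molar_mass: float = O3_MOLAR_MASS,
    molar_volume: float = MOLAR_VOLUME_25C,
) -> float:
    """Inverse of :func:`ppb_to_mass_concentration`."""
    if molar_volume <= 0:
        raise ValueError(f"molar_volume must be positive, got {molar_volume}")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    return c * molar_volume / molar_mass
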