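"""Domain types and table I/O for multi-city daily mortality panels.

The analysis operates on two tables:

* a **city-day series** — one row per city and calendar day, carrying the
  daily mean temperature (degrees C, later augmented with a city-specific
  percentile) and daily death counts, overall and by outcome stratum
  (sex, age group, mode of transport);
* a **death-record table** — one row per individual death, carrying the
  demographic predictors and the cause category used by the cause-of-death
  redistribution stage.

Both are plain CSV with a header row.  Dates are ISO-8601; day-of-week is
derived from the proleptic Gregorian calendar with Monday first, because the
case-crossover strata are keyed on day-of-week.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Outcome strata.  Counts in stratum columns must sum to at most the overall
# column (exactly when the stratification is exhaustive and nothing is
# unknown).
SEX_LEVELS = ("male", "female")
AGE_GROUPS = ("0-9", "10-19", "20-34", "35-64", "65+")
MODE_LEVELS = ("motor_vehicle", "motorcycle", "bicycle", "pedestrian")

ROAD_CAUSES = MODE_LEVELS
CAUSE_LEVELS = ROAD_CAUSES + ("non_road_traffic", "ill_defined")

#: five-year age bands used as predictors in the redistribution model
AGE_BANDS_5YR = tuple(
    f"{lo}-{lo + 4}" for lo in range(0, 85, 5)
) + ("85+",)


def age_band_to_group(band: str) -> str:
    """Map a five-year age band (``"20-24"``) to its analysis age group."""
    if band not in AGE_BANDS_5YR:
        raise ValueError(f"unknown age band {band!r}")
    lo = 85 if band == "85+" else int(band.split("-")[0])
    if lo <= 9:
        return "0-9"
    if lo <= 19:
        return "10-19"
    if lo <= 34:
        return "20-34"
    if lo <= 64:
        return "35-64"
    return "65+"


def _stratum_columns() -> list[str]:
    cols = [f"deaths_{s}" for s in SEX_LEVELS]
    cols += [f"deaths_age_{g}".replace("-", "_").replace("+", "plus") for g in AGE_GROUPS]
    cols += [f"deaths_{m}" for m in MODE_LEVELS]
    return cols


SEX_COLUMNS = tuple(f"deaths_{s}" for s in SEX_LEVELS)
AGE_COLUMNS = tuple(
    f"deaths_age_{g}".replace("-", "_").replace("+", "plus") for g in AGE_GROUPS
)
MODE_COLUMNS = tuple(f"deaths_{m}" for m in MODE_LEVELS)
STRATUM_COLUMNS = tuple(_stratum_columns())

AGE_GROUP_TO_COLUMN = dict(zip(AGE_GROUPS, AGE_COLUMNS))

RECORD_COLUMNS = ("city_id", "date", "country", "year", "age_group", "sex", "cause")


@dataclass
class CityDaySeries:
    """Daily record stream for one city.

    ``data`` is indexed by a strictly increasing, duplicate-free
    ``DatetimeIndex`` and carries ``temp_c``, optionally ``temp_pctl``
    (assigned by the exposure stage), the overall ``deaths`` count and any
    subset of the stratum count columns.
    """

    city_id: str
    data: pd.DataFrame = field(repr=False)
    #: relax the stratum-sum bound for summary series (e.g. across-imputation
    #: medians, where cellwise medians are not additive)
    check_stratum_sums: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError(f"city {self.city_id}: index must be a DatetimeIndex")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(
                f"duplicate (city, date) key: ({self.city_id}, {dup.date()})"
            )
        if not idx.is_monotonic_increasing:
            raise ValueError(f"city {self.city_id}: dates must be increasing")
        count_cols = [c for c in self.data.columns if c.startswith("deaths")]
        for col in count_cols:
            vals = self.data[col].to_numpy()
            if np.any(vals < 0):
                raise ValueError(f"city {self.city_id}: negative counts in {col}")
        if "temp_pctl" in self.data.columns:
            p = self.data["temp_pctl"].dropna()
            if len(p) and (p.min() < 0 or p.max() > 100):
                raise ValueError(f"city {self.city_id}: temp_pctl outside [0, 100]")
        if "deaths" in self.data.columns and self.check_stratum_sums:
            overall = self.data["deaths"].to_numpy()
            for group in (SEX_COLUMNS, AGE_COLUMNS, MODE_COLUMNS):
                present = [c for c in group if c in self.data.columns]
                if len(present) == len(group):
                    total = self.data[list(present)].to_numpy().sum(axis=1)
                    if np.any(total > overall):
                        raise ValueError(
                            f"city {self.city_id}: stratum counts exceed overall"
                        )

    @property
    def n_days(self) -> int:
        return len(self.data)


@dataclass
class CityAttributes:
    """One row per city of scalar effect modifiers.

    Typical modifiers: mean street-segment length (km), mean peak-hour
    travel time (minutes), mean temperature (degrees C), temperature SD.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table["city_id"].duplicated().any():
            raise ValueError("duplicate city_id in attribute table")
        num = self.table.drop(columns="city_id")
        if not np.isfinite(num.to_numpy(dtype=float)).all():
            raise ValueError("non-finite modifier values")

    def modifier(self, name: str) -> pd.Series:
        return self.table.set_index("city_id")[name]


@dataclass
class ValidationReport:
    cities: list[str]
    date_ranges: dict[str, tuple[pd.Timestamp, pd.Timestamp]]
    discrepancies: pd.DataFrame

    @property
    def ok(self) -> bool:
        return self.discrepancies.empty


Panel = dict[str, CityDaySeries]


def panel_to_frame(panel: Panel) -> pd.DataFrame:
    """Stack a panel into one long table with ``city_id`` and ``date`` columns."""
    frames = []
    for city_id, s in panel.items():
        f = s.data.reset_index(names="date")
        f.insert(0, "city_id", city_id)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def frame_to_panel(frame: pd.DataFrame) -> Panel:
    panel: Panel = {}
    for city_id, g in frame.groupby("city_id", sort=True):
        data = g.drop(columns="city_id").set_index("date").sort_index()
        panel[str(city_id)] = CityDaySeries(str(city_id), data)
    return panel


def read_city_series(path) -> Panel:
    """Read a city-day series CSV into a panel of validated series.

    Raises on duplicate (city, date) keys, negative counts and dates that do
    not parse (the error names the offending row).
    """
    raw = pd.read_csv(path, dtype={"city_id": str})
    required = {"city_id", "date", "temp_c"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    dates = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        bad = int(np.flatnonzero(dates.isna())[0])
        raise ValueError(f"non-parsable date {raw['date'].iloc[bad]!r} at row {bad}")
    raw = raw.assign(date=dates)
    count_cols = [c for c in raw.columns if c.startswith("deaths")]
    raw[count_cols] = raw[count_cols].astype("int64")
    return frame_to_panel(raw)


def write_city_series(panel: Panel, path) -> None:
    frame = panel_to_frame(panel)
    frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False)


def read_death_records(path) -> pd.DataFrame:
    rec = pd.read_csv(path, dtype={"city_id": str, "age_group": str})
    missing = set(RECORD_COLUMNS) - set(rec.columns)
    if missing:
        raise ValueError(f"missing record columns: {sorted(missing)}")
    rec["date"] = pd.to_datetime(rec["date"], format="ISO8601")
    bad = ~rec["cause"].isin(CAUSE_LEVELS)
    if bad.any():
        raise ValueError(f"unknown cause values: {sorted(rec.loc[bad, 'cause'].unique())}")
    return rec


def write_death_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def validate_panel(panel: Panel, records: pd.DataFrame) -> ValidationReport:
    """Cross-check per-day record tallies against series counts.

    For every (city, date, mode) cell present in both inputs, the number of
    records with that well-defined cause is compared with the series count.
    Mismatches are listed, not fatal: with ill-defined causes present the
    record-side tallies are expected to fall short until imputation.
    """
    cities = sorted(panel)
    date_ranges = {
        c: (panel[c].data.index[0], panel[c].data.index[-1]) for c in cities
    }
    rows = []
    road = records[records["cause"].isin(ROAD_CAUSES)]
    tally = (
        road.groupby(["city_id", "date", "cause"], observed=True)
        .size()
        .unstack("cause", fill_value=0)
    )
    for city in cities:
        data = panel[city].data
        present = [m for m in MODE_LEVELS if f"deaths_{m}" in data.columns]
        for mode in present:
            series_counts = data[f"deaths_{mode}"]
            if (city, mode) and mode in tally.columns and city in tally.index.get_level_values(0):
                rec_counts = tally.xs(city, level="city_id")[mode]
            else:
                rec_counts = pd.Series(0, index=data.index)
            rec_counts = rec_counts.reindex(data.index, fill_value=0)
            diff = series_counts - rec_counts
            for date in diff.index[diff != 0]:
                rows.append(
                    {
                        "city_id": city,
                        "date": date,
                        "column": f"deaths_{mode}",
                        "series_count": int(series_counts.loc[date]),
                        "record_count": int(rec_counts.loc[date]),
                    }
                )
    disc = pd.DataFrame(
        rows, columns=["city_id", "date", "column", "series_count", "record_count"]
    )
    return ValidationReport(cities, date_ranges, disc)
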