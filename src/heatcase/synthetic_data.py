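"""Synthetic multi-city panels with known exposure-response truth.

The generator emulates the statistical structure the case-crossover DLNM
analysis assumes, at the scale of a Latin-American city panel: heterogeneous
seasonal temperature climates, sparse daily road-death counts (on the order
of a third of a death per city-day), weekly and monthly rhythm in the
baseline rate, a cumulative lagged effect of hot days on mortality, a cause
mix over travel modes, and a stated fraction of death records carrying an
ill-defined cause code.  Every stage is deterministic given (seed, config),
with independent substreams per stage so regenerating one stage never
perturbs another.

Ground truth is a piecewise-linear cumulative log-RR curve in percentile
space (flat at zero below its reference percentile) distributed over lags
0..2 by fixed non-negative weights; downstream recovery tests compare fitted
curves against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (
    AGE_BANDS_5YR,
    AGE_COLUMNS,
    AGE_GROUPS,
    AGE_GROUP_TO_COLUMN,
    CityAttributes,
    CityDaySeries,
    MODE_LEVELS,
    Panel,
    SEX_LEVELS,
    age_band_to_group,
)

_STAGE_CLIMATE = 0
_STAGE_DEATHS = 1
_STAGE_RECORDS = 2
_STAGE_ATTRS = 3


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class TrueExposureResponse:
    """Known cumulative exposure-response curve on the percentile scale.

    ``anchors`` are (percentile, RR) points; the cumulative log-RR is
    piecewise linear between the reference percentile (log-RR = 0) and the
    anchors, flat at zero below the reference, and extends the final segment
    linearly above the last anchor.  ``lag_weights`` spread the cumulative
    effect over lags 0..len-1 and must sum to one.
    """

    anchors: tuple[tuple[float, float], ...] = ((95.0, 1.16), (99.0, 1.18))
    reference_pctl: float = 1.0
    lag_weights: tuple[float, ...] = (0.6, 0.3, 0.1)

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag weights must be non-negative and sum to 1")
        ps = [p for p, _ in self.anchors]
        if ps != sorted(ps) or (ps and ps[0] <= self.reference_pctl):
            raise ValueError("anchor percentiles must increase above the reference")

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1

    def curve(self, pctl) -> np.ndarray:
        """Cumulative log-RR at percentile(s) ``pctl`` relative to the reference."""
        pctl = np.asarray(pctl, dtype=float)
        xs = np.array([self.reference_pctl] + [p for p, _ in self.anchors])
        ys = np.array([0.0] + [np.log(r) for _, r in self.anchors])
        out = np.interp(pctl, xs, ys)
        # linear extrapolation above the last anchor
        if len(xs) >= 2:
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            above = pctl > xs[-1]
            out = np.where(above, ys[-1] + slope * (pctl - xs[-1]), out)
        return np.where(pctl < self.reference_pctl, 0.0, out)

    def lagged_log_rr(self, pctl_series: np.ndarray) -> np.ndarray:
        """Per-day log rate contribution from the lag-weighted curve.

        Leading days without full history reuse the first day's exposure for
        the missing lags (these days are dropped by the fitting stage).
        """
        c = self.curve(np.asarray(pctl_series, dtype=float))
        n = len(c)
        out = np.zeros(n)
        for lag, w in enumerate(self.lag_weights):
            lagged = np.concatenate([np.repeat(c[0], lag), c[: n - lag]])
            out += w * lagged
        return out

    def rr_at(self, pctl: float) -> float:
        return float(np.exp(self.curve(pctl)))


def null_truth() -> TrueExposureResponse:
    return TrueExposureResponse(anchors=((99.0, 1.0),))


# Cause-mix defaults emulate the panel's per-100-day averages by mode
# (motor vehicle 7.50, motorcycle 5.09, bicycle 0.90, pedestrian 13.87),
# normalized so the four modes exhaust the overall count; likewise sex
# (26.81 / 6.93) and analysis age groups.
_MODE_PROBS = {"motor_vehicle": 7.50, "motorcycle": 5.09,
               "bicycle": 0.90, "pedestrian": 13.87}
_SEX_PROBS = {"male": 26.81, "female": 6.93}
_AGE_PROBS = {"0-9": 1.11, "10-19": 3.27, "20-34": 11.56,
              "35-64": 13.58, "65+": 4.22}


def _normalized(d: dict[str, float]) -> dict[str, float]:
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic panel.

    Defaults target the scale of the emulated panel: a mean daily
    temperature near 21 degrees C with ~4 degrees spread across cities,
    0.3375 road deaths per city-day (33.75 per 100 days) and an 11%
    ill-defined share among cause-of-death records.
    """

    n_cities: int = 40
    n_days: int = 1095
    seed: int = 0
    start_date: str = "2016-01-01"
    # climate
    climate_mean_c: float = 21.2
    climate_mean_sd_c: float = 4.0
    amplitude_range_c: tuple[float, float] = (2.0, 8.0)
    noise_sd_range_c: tuple[float, float] = (1.0, 3.0)
    # outcome process
    baseline_deaths_per_day: float = 0.3375
    dow_multipliers: tuple[float, ...] = (0.95, 0.9, 0.9, 0.95, 1.1, 1.2, 1.1)
    month_multipliers: tuple[float, ...] = (
        1.05, 1.0, 1.0, 0.95, 0.95, 0.95, 1.0, 1.0, 1.0, 1.0, 1.05, 1.1,
    )
    overdispersion: float = 1.0  # variance/mean; 1 = Poisson
    # record attributes
    mode_probs: dict[str, float] = field(default_factory=lambda: _normalized(_MODE_PROBS))
    sex_probs: dict[str, float] = field(default_factory=lambda: _normalized(_SEX_PROBS))
    age_probs: dict[str, float] = field(default_factory=lambda: _normalized(_AGE_PROBS))
    ill_defined_fraction: float = 0.11
    nonroad_per_road: float = 2.0  # non-road external-cause records per road death
    n_countries: int = 3
    # city-level effect modification: log-RR curve scaled by
    # (1 + slope * standardized modifier)
    modifier_slopes: dict[str, float] = field(default_factory=dict)
    # optional per-mode truth curves (see gen_deaths)
    mode_truths: dict[str, TrueExposureResponse] | None = None

    def __post_init__(self) -> None:
        if self.n_cities <= 0 or self.n_days <= 0:
            raise ValueError("n_cities and n_days must be positive")
        if not (0.0 <= self.ill_defined_fraction < 1.0):
            raise ValueError("ill_defined_fraction must be in [0, 1)")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if self.baseline_deaths_per_day <= 0:
            raise ValueError("baseline rate must be positive")
        for probs in (self.mode_probs, self.sex_probs, self.age_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("attribute probabilities must sum to 1")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _city_ids(config: GeneratorConfig) -> list[str]:
    return [f"city_{i:03d}" for i in range(config.n_cities)]


def city_climates(config: GeneratorConfig) -> pd.DataFrame:
    """Per-city climate parameters, drawn once from the climate substream."""
    rng = _rng(config.seed, _STAGE_CLIMATE)
    n = config.n_cities
    return pd.DataFrame(
        {
            "city_id": _city_ids(config),
            "annual_mean_c": rng.normal(config.climate_mean_c, config.climate_mean_sd_c, n),
            "amplitude_c": rng.uniform(*config.amplitude_range_c, n),
            "phase": rng.uniform(0.0, 2.0 * np.pi, n),
            "noise_sd_c": rng.uniform(*config.noise_sd_range_c, n),
        }
    )


def gen_city_temperatures(config: GeneratorConfig) -> Panel:
    """Sinusoidal seasonal temperature series with Gaussian day-to-day noise."""
    climates = city_climates(config)
    # separate substream from the one city_climates consumes
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STAGE_CLIMATE, 1))
    )
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    panel: Panel = {}
    for row in climates.itertuples(index=False):
        seasonal = row.annual_mean_c + row.amplitude_c * np.sin(
            2.0 * np.pi * doy / 365.25 + row.phase
        )
        temps = seasonal + rng.normal(0.0, row.noise_sd_c, config.n_days)
        data = pd.DataFrame({"temp_c": temps}, index=dates)
        data.index.name = "date"
        panel[row.city_id] = CityDaySeries(row.city_id, data)
    return panel


def gen_city_attributes(config: GeneratorConfig) -> CityAttributes:
    """Scalar city modifiers: street-segment length, peak travel time, climate."""
    rng = _rng(config.seed, _STAGE_ATTRS)
    climates = city_climates(config)
    n = config.n_cities
    table = pd.DataFrame(
        {
            "city_id": _city_ids(config),
            "street_segment_km": rng.lognormal(np.log(0.10), 0.3, n),
            "peak_travel_min": rng.normal(35.0, 10.0, n).clip(min=10.0),
            "mean_temp_c": climates["annual_mean_c"].to_numpy(),
            "temp_sd_c": np.sqrt(
                climates["amplitude_c"].to_numpy() ** 2 / 2.0
                + climates["noise_sd_c"].to_numpy() ** 2
            ),
        }
    )
    return CityAttributes(table)


def _standardized_modifiers(config: GeneratorConfig,
                            attrs: CityAttributes) -> pd.DataFrame:
    z = attrs.table.set_index("city_id")[list(config.modifier_slopes)]
    return (z - z.mean()) / z.std(ddof=1)


def gen_deaths(
    panel: Panel,
    truth: TrueExposureResponse,
    config: GeneratorConfig,
    attrs: CityAttributes | None = None,
) -> Panel:
    """Draw daily death counts under the known exposure-response truth.

    The log daily mean adds the baseline rate, month and day-of-week
    multipliers, and the lag-weighted cumulative curve evaluated along the
    city's percentile series.  Counts are Poisson, or negative binomial when
    ``config.overdispersion`` exceeds one.  Subgroup columns (sex, age,
    mode) partition each day's count multinomially so strata sum exactly to
    the overall count.

    When ``config.mode_truths`` is set, each mode's count is instead drawn
    as an independent Poisson stream under its own curve (baseline scaled by
    the mode share) and the overall count is their sum — used to plant
    mode-specific effects.
    """
    rng = _rng(config.seed, _STAGE_DEATHS)
    if config.modifier_slopes:
        if attrs is None:
            attrs = gen_city_attributes(config)
        zstd = _standardized_modifiers(config, attrs)
    out: Panel = {}
    for city_id, series in panel.items():
        if "temp_pctl" not in series.data.columns:
            raise ValueError(
                f"city {city_id}: temp_pctl missing — run the exposure stage "
                "(to_percentiles) before generating deaths"
            )
        data = series.data.copy()
        dates = data.index
        dow_mult = np.asarray(config.dow_multipliers)[dates.dayofweek]
        month_mult = np.asarray(config.month_multipliers)[dates.month - 1]
        scale = 1.0
        if config.modifier_slopes:
            scale += sum(
                s * zstd.loc[city_id, name]
                for name, s in config.modifier_slopes.items()
            )
        pctl = data["temp_pctl"].to_numpy(dtype=float)
        base = config.baseline_deaths_per_day * month_mult * dow_mult

        if config.mode_truths is not None:
            mode_counts = {}
            for mode in MODE_LEVELS:
                t_mode = config.mode_truths.get(mode, truth)
                mu = (base * config.mode_probs[mode]
                      * np.exp(scale * t_mode.lagged_log_rr(pctl)))
                mode_counts[mode] = _draw_counts(rng, mu, config.overdispersion)
            counts = sum(mode_counts.values())
            for mode in MODE_LEVELS:
                data[f"deaths_{mode}"] = mode_counts[mode]
        else:
            mu = base * np.exp(scale * truth.lagged_log_rr(pctl))
            counts = _draw_counts(rng, mu, config.overdispersion)
            probs = [config.mode_probs[m] for m in MODE_LEVELS]
            draws = rng.multinomial(counts, probs)
            for j, mode in enumerate(MODE_LEVELS):
                data[f"deaths_{mode}"] = draws[:, j]
        data["deaths"] = counts
        for levels, probs_map, cols in (
            (SEX_LEVELS, config.sex_probs, [f"deaths_{s}" for s in SEX_LEVELS]),
            (AGE_GROUPS, config.age_probs, list(AGE_COLUMNS)),
        ):
            draws = rng.multinomial(counts, [probs_map[l] for l in levels])
            for j, col in enumerate(cols):
                data[col] = draws[:, j]
        out[city_id] = CityDaySeries(city_id, data)
    return out


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, od: float) -> np.ndarray:
    if od <= 1.0:
        return rng.poisson(mu)
    # NB parameterized so that variance = od * mu
    r = mu / (od - 1.0)
    p = 1.0 / od
    return rng.negative_binomial(np.maximum(r, 1e-12), p)


def city_country(city_id: str, config: GeneratorConfig) -> str:
    idx = int(city_id.rsplit("_", 1)[1])
    return f"country_{idx % config.n_countries}"


def gen_death_records(panel: Panel, config: GeneratorConfig) -> pd.DataFrame:
    """Expand daily counts into one record per death, plus non-road records.

    Per city-day, the mode / sex / age-group tallies already drawn into the
    series are expanded to individual records (the three attribute lists are
    shuffled independently and zipped, so record tallies reproduce every
    series column exactly).  Non-road external-cause deaths arrive as an
    independent Poisson stream.  A fraction ``ill_defined_fraction`` of all
    records has its cause masked to ``ill_defined``; the true cause is kept
    in a ``true_cause`` column for recovery testing only.
    """
    rng = _rng(config.seed, _STAGE_RECORDS)
    frames = []
    sex_levels = list(SEX_LEVELS)
    for city_id, series in panel.items():
        data = series.data
        n_days = len(data)
        counts = data["deaths"].to_numpy(dtype=int)
        nonroad_rate = config.nonroad_per_road * config.baseline_deaths_per_day
        nonroad = rng.poisson(nonroad_rate, n_days)
        total = int(counts.sum() + nonroad.sum())
        if total == 0:
            continue
        day_idx = np.repeat(np.arange(n_days), counts)
        modes = _expand_tallies(
            data, [f"deaths_{m}" for m in MODE_LEVELS], list(MODE_LEVELS), counts, rng
        )
        sexes = _expand_tallies(
            data, [f"deaths_{s}" for s in SEX_LEVELS], sex_levels, counts, rng
        )
        ages = _expand_tallies(
            data, list(AGE_COLUMNS), list(AGE_GROUPS), counts, rng
        )
        nr_day_idx = np.repeat(np.arange(n_days), nonroad)
        nr_sex = rng.choice(sex_levels, size=len(nr_day_idx),
                            p=[config.sex_probs[s] for s in sex_levels])
        nr_age = rng.choice(list(AGE_GROUPS), size=len(nr_day_idx),
                            p=[config.age_probs[a] for a in AGE_GROUPS])
        frame = pd.DataFrame(
            {
                "city_id": city_id,
                "date": data.index.to_numpy()[np.concatenate([day_idx, nr_day_idx])],
                "age_group": _to_five_year_bands(
                    np.concatenate([ages, nr_age]), rng
                ),
                "sex": np.concatenate([sexes, nr_sex]),
                "cause": np.concatenate(
                    [modes, np.repeat("non_road_traffic", len(nr_day_idx))]
                ),
            }
        )
        frames.append(frame)
    if not frames:
        records = pd.DataFrame(
            columns=["city_id", "date", "age_group", "sex", "cause"]
        )
    else:
        records = pd.concat(frames, ignore_index=True)
    records["country"] = [city_country(c, config) for c in records["city_id"]]
    records["year"] = pd.to_datetime(records["date"]).dt.year
    records["true_cause"] = records["cause"]
    mask = rng.random(len(records)) < config.ill_defined_fraction
    records.loc[mask, "cause"] = "ill_defined"
    cols = ["city_id", "date", "country", "year", "age_group", "sex",
            "cause", "true_cause"]
    return records[cols]


def _expand_tallies(data: pd.DataFrame, cols: list[str], levels: list[str],
                    overall: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-day expansion of tally columns to a shuffled per-death label list."""
    tallies = data[cols].to_numpy(dtype=int)
    out = []
    for day, n in enumerate(overall):
        if n == 0:
            continue
        labels = np.repeat(levels, tallies[day])
        rng.shuffle(labels)
        out.append(labels)
    return np.concatenate(out) if out else np.array([], dtype=object)


def _to_five_year_bands(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a five-year band uniformly within each analysis age group."""
    bands_by_group: dict[str, list[str]] = {g: [] for g in AGE_GROUPS}
    for band in AGE_BANDS_5YR:
        bands_by_group[age_band_to_group(band)].append(band)
    out = np.empty(len(groups), dtype=object)
    for g, bands in bands_by_group.items():
        idx = np.flatnonzero(groups == g)
        if len(idx):
            out[idx] = rng.choice(bands, size=len(idx))
    return out


def simulate_panel(
    config: GeneratorConfig,
    truth: TrueExposureResponse | None = None,
) -> tuple[Panel, pd.DataFrame, CityAttributes, TrueExposureResponse]:
    """Full generation pipeline: temperatures, percentiles, deaths, records."""
    from .exposure import panel_to_percentiles

    truth = truth or TrueExposureResponse()
    panel = panel_to_percentiles(gen_city_temperatures(config))
    attrs = gen_city_attributes(config)
    panel = gen_deaths(panel, truth, config, attrs=attrs)
    records = gen_death_records(panel, config)
    return panel, records, attrs, truth
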