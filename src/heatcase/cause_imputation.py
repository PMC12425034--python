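"""Multinomial redistribution of ill-defined causes of death.

A share of external-cause death records carries ill-defined ICD-10 codes
that cannot be assigned to a road-traffic category directly.  A multinomial
logit fitted on the well-defined records — outcome: the four road-user
categories or non-road-traffic; predictors: five-year age band, sex, year
and country — yields per-record category probabilities, from which ``m``
independent categorical draws produce ``m`` completed datasets.  Each
completed dataset aggregates to a daily road-death time series per city;
downstream model fits run once per imputation and are pooled with Rubin's
rules (see :mod:`heatcase.inference`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import (
    AGE_COLUMNS,
    AGE_GROUPS,
    CityDaySeries,
    MODE_LEVELS,
    Panel,
    ROAD_CAUSES,
    SEX_LEVELS,
    age_band_to_group,
)

OUTCOME_CATEGORIES = tuple(ROAD_CAUSES) + ("non_road_traffic",)
CATEGORICAL_PREDICTORS = ("age_group", "sex", "country")


@dataclass
class RedistributionModel:
    """Fitted multinomial logit over death categories.

    Stores the fitted parameter table and the factor levels seen at fit
    time; prediction on a record with an unseen level is an error rather
    than a silent extrapolation.
    """

    params: np.ndarray  # (n_features, n_categories - 1)
    exog_columns: list[str]
    levels: dict[str, list[str]]
    year_center: float
    categories: tuple[str, ...] = OUTCOME_CATEGORIES

    def _design(self, records: pd.DataFrame) -> np.ndarray:
        for pred in CATEGORICAL_PREDICTORS:
            seen = set(self.levels[pred])
            unseen = set(records[pred].unique()) - seen
            if unseen:
                raise ValueError(
                    f"unseen {pred} level(s) at prediction time: {sorted(unseen)}"
                )
        X = pd.DataFrame(index=records.index)
        X["const"] = 1.0
        X["year_c"] = records["year"].astype(float) - self.year_center
        for pred in CATEGORICAL_PREDICTORS:
            for level in self.levels[pred][1:]:  # first level is reference
                X[f"{pred}[{level}]"] = (records[pred] == level).astype(float)
        return X[self.exog_columns].to_numpy()

    def predict_probabilities(self, records: pd.DataFrame) -> pd.DataFrame:
        """Per-record probabilities over the outcome categories (rows sum to 1)."""
        X = self._design(records)
        eta = np.hstack([np.zeros((len(X), 1)), X @ self.params])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        probs = e / e.sum(axis=1, keepdims=True)
        return pd.DataFrame(probs, index=records.index, columns=list(self.categories))


def fit_redistribution(records: pd.DataFrame) -> RedistributionModel:
    """Maximum-likelihood multinomial logit on the well-defined records.

    Predictors: age band and sex and country as categoricals (first level as
    reference), year as a centred continuous covariate.  Ill-defined rows
    are excluded from fitting and only ever receive predictions.
    """
    well = records[records["cause"] != "ill_defined"]
    counts = well["cause"].value_counts()
    for cat in OUTCOME_CATEGORIES:
        if counts.get(cat, 0) == 0:
            raise ValueError(f"no well-defined records in outcome category {cat!r}")
    levels = {
        pred: sorted(well[pred].astype(str).unique())
        for pred in CATEGORICAL_PREDICTORS
    }
    year_center = float(well["year"].mean())
    model = RedistributionModel(
        params=np.empty(0),
        exog_columns=[],
        levels=levels,
        year_center=year_center,
    )
    X = pd.DataFrame(index=well.index)
    X["const"] = 1.0
    if well["year"].nunique() > 1:
        X["year_c"] = well["year"].astype(float) - year_center
    for pred in CATEGORICAL_PREDICTORS:
        for level in levels[pred][1:]:
            X[f"{pred}[{level}]"] = (well[pred] == level).astype(float)
    endog = pd.Categorical(
        well["cause"], categories=list(OUTCOME_CATEGORIES)
    ).codes
    mn = sm.MNLogit(endog, X.to_numpy())
    try:
        res = mn.fit(method="lbfgs", maxiter=500, disp=False)
    except Exception as exc:  # pragma: no cover - statsmodels raise paths vary
        raise ValueError(f"multinomial fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if not np.isfinite(params).all() or np.abs(params).max() > 30:
        culprit = _separation_culprit(well)
        raise ValueError(
            "apparent perfect separation in the redistribution model"
            + (f" (predictor {culprit})" if culprit else "")
        )
    model.params = params
    model.exog_columns = list(X.columns)
    return model


def _separation_culprit(well: pd.DataFrame) -> str | None:
    for pred in CATEGORICAL_PREDICTORS:
        tab = pd.crosstab(well[pred], well["cause"])
        if (tab.to_numpy() == 0).any() and tab.shape[0] > 1:
            return pred
    return None


@dataclass
class ImputationSet:
    """``m`` completed datasets from categorical redistribution draws.

    Well-defined rows are identical across imputations; only the
    ill-defined rows carry per-imputation category assignments.
    """

    records: pd.DataFrame = field(repr=False)
    ill_index: np.ndarray
    assignments: np.ndarray  # (n_ill, m) of category indices
    m: int
    seed: int
    categories: tuple[str, ...] = OUTCOME_CATEGORIES

    def completed_records(self, i: int) -> pd.DataFrame:
        if not (0 <= i < self.m):
            raise IndexError(f"imputation index {i} out of range 0..{self.m - 1}")
        out = self.records.copy()
        cats = np.asarray(self.categories, dtype=object)
        out.loc[self.ill_index, "cause"] = cats[self.assignments[:, i]]
        return out

    def to_panel(self, i: int, template: Panel) -> Panel:
        return aggregate_records(self.completed_records(i), template)


def impute(
    records: pd.DataFrame,
    model: RedistributionModel,
    m: int = 100,
    seed: int = 0,
) -> ImputationSet:
    """Draw ``m`` independent completions of the ill-defined records.

    One RNG substream per imputation index is derived from the master seed,
    so extending ``m`` never changes earlier imputations.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    ill = records.index[records["cause"] == "ill_defined"].to_numpy()
    if len(ill) == 0:
        assignments = np.empty((0, m), dtype=np.int64)
        return ImputationSet(records, ill, assignments, m, seed)
    probs = model.predict_probabilities(records.loc[ill]).to_numpy()
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    assignments = np.empty((len(ill), m), dtype=np.int64)
    for i in range(m):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        u = rng.random(len(ill))
        assignments[:, i] = (u[:, None] > cum).sum(axis=1)
    return ImputationSet(records, ill, assignments, m, seed)


def aggregate_records(records: pd.DataFrame, template: Panel) -> Panel:
    """Aggregate completed records to daily road-death counts per city.

    The overall count is the sum of the four road modes; non-road records
    are dropped.  Sex and age-group columns count road deaths only.  The
    template supplies the full date index (zero-death days included) and
    temperature columns.
    """
    road = records[records["cause"].isin(MODE_LEVELS)].copy()
    road["age_analysis"] = [age_band_to_group(b) for b in road["age_group"]]
    out: Panel = {}
    for city_id, series in template.items():
        idx = series.data.index
        sub = road[road["city_id"] == city_id]
        keep = [c for c in ("temp_c", "temp_pctl") if c in series.data.columns]
        data = series.data[keep].copy()
        by_mode = (
            sub.groupby(["date", "cause"], observed=True).size().unstack(fill_value=0)
        )
        for mode in MODE_LEVELS:
            col = by_mode[mode] if mode in by_mode.columns else pd.Series(0, index=by_mode.index)
            data[f"deaths_{mode}"] = col.reindex(idx, fill_value=0).astype("int64")
        data["deaths"] = data[[f"deaths_{m}" for m in MODE_LEVELS]].sum(axis=1)
        by_sex = sub.groupby(["date", "sex"], observed=True).size().unstack(fill_value=0)
        for sex in SEX_LEVELS:
            col = by_sex[sex] if sex in by_sex.columns else pd.Series(0, index=by_sex.index)
            data[f"deaths_{sex}"] = col.reindex(idx, fill_value=0).astype("int64")
        by_age = (
            sub.groupby(["date", "age_analysis"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
        for group, col_name in zip(AGE_GROUPS, AGE_COLUMNS):
            col = by_age[group] if group in by_age.columns else pd.Series(0, index=by_age.index)
            data[col_name] = col.reindex(idx, fill_value=0).astype("int64")
        out[city_id] = CityDaySeries(city_id, data)
    return out


def median_series(imps: ImputationSet, template: Panel) -> Panel:
    """Across-imputation lower-median count per city-day-stratum.

    The lower of the two central order statistics is used for even ``m`` so
    counts stay integral (the Poisson stages require integer counts).
    """
    panels = [imps.to_panel(i, template) for i in range(imps.m)]
    out: Panel = {}
    for city_id in template:
        frames = [p[city_id].data for p in panels]
        count_cols = [c for c in frames[0].columns if c.startswith("deaths")]
        base = frames[0].drop(columns=count_cols).copy()
        stacked = np.stack([f[count_cols].to_numpy() for f in frames])  # (m, n, c)
        stacked.sort(axis=0)
        lower_median = stacked[(imps.m - 1) // 2]
        for j, col in enumerate(count_cols):
            base[col] = lower_median[:, j].astype("int64")
        # cellwise medians are not additive, so stratum medians may exceed
        # the overall median on a given day
        out[city_id] = CityDaySeries(city_id, base, check_stratum_sums=False)
    return out
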