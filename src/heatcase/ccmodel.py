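"""Time-stratified case-crossover fitting.

Each city-day belongs to exactly one stratum keyed by (city, year, month,
day-of-week); a case day is thereby compared only with the 3 or 4 other
same-weekday days of the same city-month, which removes seasonality, long
term trends and any city-level confounder by design.  Estimation maximizes
the conditional Poisson likelihood: conditioning on each stratum's total
count eliminates the stratum intercepts exactly and is equivalent to a
multinomial likelihood over the days within the stratum.  Overdispersion is
handled quasi-likelihood style, scaling the covariance by the Pearson
dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Panel
from .crossbasis import CrossBasisSpec, build_crossbasis


@dataclass(frozen=True)
class StratumKey:
    city_id: str
    year: int
    month: int
    dow: int  # Monday = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.city_id}:{self.year}-{self.month:02d}:dow{self.dow}"


@dataclass
class StrataReport:
    keys: pd.DataFrame  # one row per observation: city_id, year, month, dow, stratum
    sizes: pd.Series  # observations per stratum
    empty: list[int]  # stratum codes with zero total deaths (given y)


def make_strata(dates: pd.Series, city_ids: pd.Series) -> pd.Series:
    """Integer stratum codes for (city, year, month, Monday-first weekday)."""
    dates = pd.to_datetime(dates)
    key = pd.DataFrame(
        {
            "city_id": np.asarray(city_ids),
            "year": dates.dt.year.to_numpy(),
            "month": dates.dt.month.to_numpy(),
            "dow": dates.dt.dayofweek.to_numpy(),
        }
    )
    codes, _ = pd.factorize(
        pd.MultiIndex.from_frame(key), sort=True
    )
    return pd.Series(codes, index=dates.index, name="stratum")


def strata_report(dates: pd.Series, city_ids: pd.Series,
                  y: np.ndarray | None = None) -> StrataReport:
    strata = make_strata(dates, city_ids)
    dates = pd.to_datetime(dates)
    keys = pd.DataFrame(
        {
            "city_id": np.asarray(city_ids),
            "year": dates.dt.year.to_numpy(),
            "month": dates.dt.month.to_numpy(),
            "dow": dates.dt.dayofweek.to_numpy(),
            "stratum": strata.to_numpy(),
        }
    )
    sizes = keys.groupby("stratum").size()
    empty: list[int] = []
    if y is not None:
        totals = np.bincount(strata.to_numpy(), weights=np.asarray(y, dtype=float))
        empty = list(np.flatnonzero(totals == 0))
    return StrataReport(keys, sizes, empty)


@dataclass
class FitResult:
    coef: np.ndarray
    vcov: np.ndarray  # dispersion-scaled
    dispersion: float
    deviance: float  # unscaled conditional Poisson deviance
    n_strata: int
    n_obs: int
    loglik: float  # conditional log-likelihood (multinomial kernel)
    vcov_unscaled: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.coef)


@dataclass
class LRTestResult:
    statistic: float
    df: int
    pvalue: float


def _group_matrix(strata: np.ndarray, values: np.ndarray, n_strata: int) -> np.ndarray:
    out = np.zeros((n_strata, values.shape[1]))
    np.add.at(out, strata, values)
    return out


def fit_ccpoisson(
    y: np.ndarray,
    X: np.ndarray,
    strata: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> FitResult:
    """Maximize the conditional Poisson likelihood with strata absorbed.

    Within stratum ``s`` with total ``N_s``, the conditional likelihood is
    multinomial with day probabilities ``exp(x_i b) / sum_j exp(x_j b)``;
    Newton-Raphson on this concave objective converges in a handful of
    steps.  Strata with zero total count contribute nothing and are dropped;
    the Pearson dispersion uses ``n - p - (#strata)`` residual degrees of
    freedom, mirroring a Poisson fit with stratum intercepts.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    strata = np.asarray(strata)
    if y.ndim != 1 or X.shape[0] != len(y) or len(strata) != len(y):
        raise ValueError("y, X and strata must have matching first dimension")
    codes, _ = pd.factorize(strata, sort=True)
    totals = np.bincount(codes, weights=y)
    keep = totals[codes] > 0
    if not keep.any():
        raise ValueError("all strata have zero total count")
    y, X, codes = y[keep], X[keep], codes[keep]
    codes, _ = pd.factorize(codes, sort=True)
    S = codes.max() + 1
    N = np.bincount(codes, weights=y)
    n, p = X.shape

    # centre within strata once for the constancy check
    counts = np.bincount(codes).astype(float)
    means = _group_matrix(codes, X, S) / counts[:, None]
    Xc = X - means[codes]
    if np.allclose(Xc, 0.0, atol=1e-12):
        raise ValueError("no within-stratum contrast in the design")

    beta = np.zeros(p)
    ll_sat = float(np.sum(y[y > 0] * np.log(y[y > 0] / N[codes][y > 0])))

    def state(b):
        eta = X @ b
        # per-stratum max for numerical stability
        smax = np.full(S, -np.inf)
        np.maximum.at(smax, codes, eta)
        e = np.exp(eta - smax[codes])
        denom = np.bincount(codes, weights=e)
        prob = e / denom[codes]
        mu = N[codes] * prob
        pos = y > 0
        ll = float(np.sum(y[pos] * np.log(prob[pos])))
        return prob, mu, ll

    prob, mu, ll = state(beta)
    dev = 2.0 * (ll_sat - ll)
    for _ in range(max_iter):
        grad = X.T @ (y - mu)
        A = (X * mu[:, None]).T @ X
        M = _group_matrix(codes, X * prob[:, None], S)
        H = A - (M * N[:, None]).T @ M
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving keeps the multinomial log-likelihood ascending
        for _ in range(30):
            cand = beta + step
            prob_c, mu_c, ll_c = state(cand)
            if ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta, prob, mu, ll_new = cand, prob_c, mu_c, ll_c
        dev_new = 2.0 * (ll_sat - ll_new)
        if abs(dev_new - dev) <= tol * (abs(dev) + 1e-12):
            dev, ll = dev_new, ll_new
            break
        dev, ll = dev_new, ll_new
    else:
        gnorm = float(np.linalg.norm(X.T @ (y - mu)))
        raise RuntimeError(
            f"conditional Poisson fit did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.3e})"
        )

    A = (X * mu[:, None]).T @ X
    M = _group_matrix(codes, X * prob[:, None], S)
    H = A - (M * N[:, None]).T @ M
    vcov_unscaled = np.linalg.pinv(H)
    resid_df = max(n - p - S, 1)
    pearson = float(np.sum((y - mu) ** 2 / mu, where=mu > 0))
    phi = pearson / resid_df
    vcov = vcov_unscaled * phi
    return FitResult(
        coef=beta,
        vcov=vcov,
        dispersion=phi,
        deviance=dev,
        n_strata=int(S),
        n_obs=int(n),
        loglik=ll,
        vcov_unscaled=vcov_unscaled,
    )


def add_modifier_interaction(X: np.ndarray, z: np.ndarray,
                             city_ids: np.ndarray | None = None) -> np.ndarray:
    """Append ``z * X`` interaction columns for a city-level scalar modifier.

    ``z`` must be constant within each city; its main effect is absorbed by
    the city-nested strata and is therefore not added.
    """
    z = np.asarray(z, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(z) != X.shape[0]:
        raise ValueError("modifier length must match design rows")
    if city_ids is not None:
        tab = pd.DataFrame({"city": np.asarray(city_ids), "z": z})
        nun = tab.groupby("city")["z"].nunique()
        bad = nun[nun > 1]
        if len(bad):
            raise ValueError(
                f"modifier varies within city/cities: {list(bad.index)}"
            )
    return np.hstack([X, z[:, None] * X])


def lr_test(full: FitResult, reduced: FitResult) -> LRTestResult:
    """Chi-square likelihood-ratio test between nested conditional fits.

    Uses the unscaled Poisson deviance difference (chi-square reference), the
    convention behind reported chi-square statistics; see ``f_test_scaled``
    for the dispersion-adjusted variant.
    """
    if full.n_params <= reduced.n_params:
        if full.n_params == reduced.n_params:
            stat = max(reduced.deviance - full.deviance, 0.0)
            return LRTestResult(stat, 0, 1.0)
        raise ValueError("`full` must have more parameters than `reduced`")
    if full.n_obs != reduced.n_obs or full.n_strata != reduced.n_strata:
        raise ValueError("fits must share observations and strata (nested designs)")
    df = full.n_params - reduced.n_params
    stat = reduced.deviance - full.deviance
    if stat < -1e-6:
        raise ValueError("reduced model fits better; designs are not nested")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return LRTestResult(stat, df, p)


def f_test_scaled(full: FitResult, reduced: FitResult) -> LRTestResult:
    """Dispersion-scaled F variant of the nested-model test."""
    base = lr_test(full, reduced)
    df2 = max(full.n_obs - full.n_params - full.n_strata, 1)
    fstat = (base.statistic / base.df) / full.dispersion if base.df else 0.0
    p = float(stats.f.sf(fstat, base.df, df2)) if base.df else 1.0
    return LRTestResult(fstat, base.df, p)


@dataclass
class PanelDesign:
    """Stacked, lag-complete design for a pooled panel fit."""

    y: np.ndarray
    X: np.ndarray
    strata: np.ndarray
    city_ids: np.ndarray
    dates: pd.DatetimeIndex
    exposure: np.ndarray  # percentile (or degrees C) at lag 0
    spec: CrossBasisSpec


def build_panel_design(
    panel: Panel,
    spec: CrossBasisSpec,
    outcome: str = "deaths",
) -> PanelDesign:
    """Cross-basis + strata for every city, dropping incomplete-lag days.

    Days without full lag history are removed before strata construction so
    stratum sizes reflect usable days only.
    """
    ys, Xs, cities, dates, expo = [], [], [], [], []
    col = "temp_pctl" if spec.exposure_scale == "percentile" else "temp_c"
    if spec.exposure_scale == "celsius" and spec.boundary is None:
        allt = np.concatenate(
            [s.data["temp_c"].to_numpy(dtype=float) for s in panel.values()]
        )
        spec = spec.with_boundary(float(np.nanmin(allt)), float(np.nanmax(allt)))
    for city_id, series in panel.items():
        if col not in series.data.columns:
            raise ValueError(
                f"city {city_id}: column {col!r} missing; run the exposure "
                "stage before model fitting"
            )
        if outcome not in series.data.columns:
            raise ValueError(f"city {city_id}: outcome column {outcome!r} missing")
        e = series.data[col].to_numpy(dtype=float)
        cb = build_crossbasis(e, spec)
        m = cb.complete
        ys.append(series.data[outcome].to_numpy(dtype=float)[m])
        Xs.append(cb.matrix[m])
        cities.append(np.repeat(city_id, m.sum()))
        dates.append(series.data.index[m])
        expo.append(e[m])
        spec = cb.spec  # keeps any data-derived boundary
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    city_ids = np.concatenate(cities)
    date_idx = pd.DatetimeIndex(np.concatenate([d.values for d in dates]))
    strata = make_strata(pd.Series(date_idx), pd.Series(city_ids)).to_numpy()
    return PanelDesign(y, X, strata, city_ids, date_idx, np.concatenate(expo), spec)
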