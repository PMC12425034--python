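"""Pooling and summarization of fitted exposure-response surfaces.

Given conditional-Poisson fits on the cross-basis design — one per imputed
dataset — this module pools coefficients with Rubin's rules, locates the
minimum-mortality temperature percentile (MMTP), builds MMTP-centred
relative-risk curves with 95% confidence bands, computes the excess death
fraction (EDF) attributable to extreme heat with a simulation-based
empirical interval, and evaluates effect-modification marginal curves at
chosen modifier values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccmodel import FitResult, PanelDesign, build_panel_design, fit_ccpoisson
from .core_io import Panel
from .crossbasis import CrossBasisSpec, contrast_vector, cumulative_contrast

MMTP_GRID = np.arange(1.0, 100.0)  # integer percentiles 1..99
Z95 = 1.959963984540054


@dataclass
class PooledFit:
    """Rubin-pooled coefficients and total covariance across imputations."""

    coef: np.ndarray
    within: np.ndarray  # mean of per-imputation vcovs
    between: np.ndarray  # sample covariance of coefficients
    total: np.ndarray  # within + (1 + 1/m) * between
    m: int

    @classmethod
    def from_single(cls, fit: FitResult) -> "PooledFit":
        z = np.zeros_like(fit.vcov)
        return cls(fit.coef.copy(), fit.vcov.copy(), z, fit.vcov.copy(), 1)


def pool_rubin(fits: list[FitResult]) -> PooledFit:
    """Pool coefficient and covariance estimates with Rubin's rules.

    coef = mean over imputations; total covariance = mean within-imputation
    covariance + (1 + 1/m) times the between-imputation sample covariance.
    """
    if not fits:
        raise ValueError("no fits to pool")
    p = fits[0].coef.shape[0]
    for f in fits:
        if f.coef.shape[0] != p or f.vcov.shape != (p, p):
            raise ValueError("fits have mismatched design dimensions")
    m = len(fits)
    coefs = np.stack([f.coef for f in fits])
    coef = coefs.mean(axis=0)
    within = np.mean([f.vcov for f in fits], axis=0)
    if m > 1:
        dev = coefs - coef
        between = dev.T @ dev / (m - 1)
    else:
        between = np.zeros((p, p))
    total = within + (1.0 + 1.0 / m) * between
    return PooledFit(coef, within, between, total, m)


def find_mmtp(pooled: PooledFit, spec: CrossBasisSpec,
              grid: np.ndarray = MMTP_GRID) -> float:
    """Percentile of minimum cumulative log-RR on the 1..99 grid.

    The argmin is invariant to the reference used in the contrast; ties
    resolve to the smallest percentile.
    """
    ref = float(grid[0])
    vals = np.array(
        [cumulative_contrast(spec, pooled.coef, None, float(p), ref)[0] for p in grid]
    )
    return float(grid[int(np.argmin(vals))])


@dataclass
class RRCurve:
    """MMTP-centred relative-risk curve with pointwise 95% CI."""

    table: pd.DataFrame  # columns: pctl, rr, lo, hi, log_rr, se
    mmtp: float

    def at(self, pctl: float) -> pd.Series:
        row = self.table[np.isclose(self.table["pctl"], pctl)]
        if row.empty:
            raise KeyError(f"percentile {pctl} not on the curve grid")
        return row.iloc[0]

    def rr(self, pctl: float) -> float:
        return float(self.at(pctl)["rr"])


def rr_curve(
    pooled: PooledFit,
    spec: CrossBasisSpec,
    center: float,
    grid: np.ndarray = MMTP_GRID,
) -> RRCurve:
    """Cumulative RR at each grid percentile relative to ``center``.

    RR equals exactly one (CI degenerate at one) at the centering
    percentile.
    """
    rows = []
    for p in grid:
        log_rr, se = cumulative_contrast(
            spec, pooled.coef, pooled.total, float(p), center
        )
        rows.append(
            {
                "pctl": float(p),
                "rr": float(np.exp(log_rr)),
                "lo": float(np.exp(log_rr - Z95 * se)),
                "hi": float(np.exp(log_rr + Z95 * se)),
                "log_rr": log_rr,
                "se": se,
            }
        )
    return RRCurve(pd.DataFrame(rows), float(center))


@dataclass
class EDFResult:
    """Excess death fraction for days at or above a percentile threshold."""

    edf: float
    lower: float
    upper: float
    threshold: float
    n_sim: int
    seed: int


def _daily_log_rr(design: PanelDesign, coef: np.ndarray, ref: float) -> np.ndarray:
    """Cumulative log-RR of each day's own lagged exposure history vs ``ref``.

    Backward perspective: day ``t``'s risk reflects its exposures at lags
    0..max_lag, which is exactly the day's cross-basis row contrasted with
    the reference held across all lags.
    """
    spec = design.spec
    ref_row = np.tile(spec.exposure_basis(np.array([ref]))[0], spec.d_l)
    return (design.X - ref_row) @ coef


def edf(
    pooled: PooledFit,
    design: PanelDesign,
    mmtp: float,
    threshold: float = 95.0,
    n_sim: int = 1000,
    seed: int = 0,
) -> EDFResult:
    """Fraction of deaths attributable to exposure at or above the threshold.

    Attributable deaths on day ``t`` are ``n_t * (1 - exp(-eta_t))`` with
    ``eta_t`` the day's cumulative log-RR versus the MMTP; the EDF sums this
    over threshold-exceeding days and divides by all deaths.  The empirical
    interval re-evaluates the EDF under ``n_sim`` multivariate-normal draws
    of the coefficients from the pooled (mean, total covariance).
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must be inside (0, 100)")
    y = design.y
    total = y.sum()
    if total == 0:
        raise ValueError("no deaths in the panel")
    hot = design.exposure >= threshold

    def edf_for(coef: np.ndarray) -> float:
        eta = _daily_log_rr(design, coef, mmtp)
        an = y * (1.0 - np.exp(-eta))
        return float(an[hot].sum() / total)

    point = edf_for(pooled.coef)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(pooled.coef, pooled.total, size=n_sim,
                                    method="cholesky" if _is_pd(pooled.total) else "svd")
    sims = np.array([edf_for(b) for b in draws])
    lo, hi = np.quantile(sims, [0.025, 0.975])
    return EDFResult(point, float(lo), float(hi), threshold, n_sim, seed)


def _is_pd(a: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(a)
        return True
    except np.linalg.LinAlgError:
        return False


def marginal_curves(
    pooled: PooledFit,
    spec: CrossBasisSpec,
    center: float,
    z_values: tuple[float, float],
    grid: np.ndarray = MMTP_GRID,
) -> tuple[RRCurve, RRCurve]:
    """MMTP-centred curves at two modifier values from an interaction fit.

    The pooled coefficient vector must stack the main cross-basis block and
    the modifier-interaction block; the curve at modifier value ``z`` uses
    ``beta_main + z * beta_int`` with delta-method covariance
    ``C T C'`` for ``C = [I, zI]``.
    """
    k = spec.n_columns
    if pooled.coef.shape[0] != 2 * k:
        raise ValueError(
            "fit lacks an interaction block: expected coefficient length "
            f"{2 * k}, got {pooled.coef.shape[0]}"
        )
    curves = []
    eye = np.eye(k)
    for z in z_values:
        C = np.hstack([eye, z * eye])
        sub = PooledFit(
            coef=C @ pooled.coef,
            within=C @ pooled.within @ C.T,
            between=C @ pooled.between @ C.T,
            total=C @ pooled.total @ C.T,
            m=pooled.m,
        )
        curves.append(rr_curve(sub, spec, center, grid=grid))
    return curves[0], curves[1]


def modifier_percentile_values(values: np.ndarray,
                               q: tuple[float, float] = (10.0, 90.0)) -> tuple[float, float]:
    lo, hi = np.percentile(np.asarray(values, dtype=float), q)
    return float(lo), float(hi)


@dataclass
class MainAnalysis:
    """Convenience bundle for a single-dataset main-effects analysis."""

    design: PanelDesign
    fit: FitResult
    pooled: PooledFit
    mmtp: float
    curve: RRCurve


def run_main_analysis(
    panel: Panel,
    spec: CrossBasisSpec | None = None,
    outcome: str = "deaths",
    center: float | None = None,
) -> MainAnalysis:
    """Percentile panel -> cross-basis -> conditional fit -> centred curve.

    ``center`` overrides the MMTP search, used for subgroup and stratified
    analyses which are centred at the overall-analysis MMTP.
    """
    spec = spec or CrossBasisSpec()
    design = build_panel_design(panel, spec, outcome=outcome)
    fit = fit_ccpoisson(design.y, design.X, design.strata)
    pooled = PooledFit.from_single(fit)
    mmtp = find_mmtp(pooled, design.spec) if center is None else float(center)
    curve = rr_curve(pooled, design.spec, mmtp)
    return MainAnalysis(design, fit, pooled, mmtp, curve)
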