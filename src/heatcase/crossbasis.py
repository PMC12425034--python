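"""Exposure x lag cross-basis for distributed-lag non-linear models.

The exposure-response dimension is a natural cubic spline (linear beyond the
boundary knots, zero second derivative at the boundaries) with internal knots
placed by default at the 10th, 75th and 90th temperature percentiles and
boundary knots at 0 and 100 on the percentile scale.  The lag dimension uses
one indicator column per lag 0..max_lag (unconstrained lag strata), so the
default basis has 4 x 3 = 12 columns; the cumulative (over lags) log relative
risk between two exposure levels is a linear contrast of the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_KNOTS = (10.0, 75.0, 90.0)

#: alternative knot placements commonly used in heat-mortality work,
#: exposed for sensitivity analyses (percentile scale)
SENSITIVITY_KNOT_SETS = (
    (50.0,),
    (33.3, 66.7),
    (25.0, 75.0),
    (10.0, 90.0),
    (25.0, 50.0, 75.0),
    (10.0, 50.0, 90.0),
)


def ns_basis(
    x: np.ndarray,
    internal_knots,
    boundary_knots=(0.0, 100.0),
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    With ``k`` internal knots the basis has ``k + 1`` columns; linear
    functions of ``x`` lie exactly in its span, and the fitted function is
    linear beyond the boundary knots.  Uses the truncated-power
    representation with the natural constraints applied in closed form,
    which spans the same space as any B-spline formulation.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("exposure values must be finite")
    lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
    knots = np.asarray([lo, *sorted(float(k) for k in internal_knots), hi])
    if len(np.unique(knots)) != len(knots):
        raise ValueError(f"knots must be strictly increasing: {knots}")
    if np.any((knots[1:-1] <= lo) | (knots[1:-1] >= hi)):
        raise ValueError("internal knots must lie strictly inside the boundary")
    K = len(knots)

    def d(j: int) -> np.ndarray:
        num = np.maximum(x - knots[j], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[j])

    cols = [x]
    dK1 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK1)
    return np.column_stack(cols)


@dataclass(frozen=True)
class CrossBasisSpec:
    """Parameterization of the bi-dimensional exposure x lag basis."""

    exposure_scale: str = "percentile"  # or "celsius"
    knots: tuple[float, ...] = DEFAULT_KNOTS
    boundary: tuple[float, float] | None = (0.0, 100.0)
    max_lag: int = 2
    lag_basis: str = "indicator"

    def __post_init__(self) -> None:
        if self.exposure_scale not in ("percentile", "celsius"):
            raise ValueError(f"unknown exposure scale {self.exposure_scale!r}")
        if self.lag_basis != "indicator":
            raise ValueError(f"unsupported lag basis {self.lag_basis!r}")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.boundary is None and self.exposure_scale == "percentile":
            object.__setattr__(self, "boundary", (0.0, 100.0))

    @property
    def d_x(self) -> int:
        return len(self.knots) + 1

    @property
    def d_l(self) -> int:
        return self.max_lag + 1

    @property
    def n_columns(self) -> int:
        return self.d_x * self.d_l

    def exposure_basis(self, x: np.ndarray) -> np.ndarray:
        if self.boundary is None:
            raise ValueError("boundary knots unset; build a cross-basis first "
                             "or supply boundary explicitly")
        return ns_basis(x, self.knots, self.boundary)

    def with_boundary(self, lo: float, hi: float) -> "CrossBasisSpec":
        return CrossBasisSpec(self.exposure_scale, self.knots, (lo, hi),
                              self.max_lag, self.lag_basis)

    def to_yaml(self, path) -> None:
        payload = {
            "exposure_scale": self.exposure_scale,
            "knots": list(self.knots),
            "boundary": list(self.boundary) if self.boundary else None,
            "max_lag": self.max_lag,
            "lag_basis": self.lag_basis,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "CrossBasisSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            exposure_scale=payload["exposure_scale"],
            knots=tuple(payload["knots"]),
            boundary=tuple(payload["boundary"]) if payload.get("boundary") else None,
            max_lag=int(payload["max_lag"]),
            lag_basis=payload.get("lag_basis", "indicator"),
        )


@dataclass
class CrossBasis:
    """Cross-basis design for one exposure series.

    ``matrix`` has one row per day and ``d_x * d_l`` columns ordered by lag
    block: columns ``[l * d_x, (l + 1) * d_x)`` hold the exposure basis
    evaluated at the exposure ``l`` days earlier.  The first ``max_lag`` rows
    have incomplete lag history (``complete`` is False there) and must be
    excluded from fitting.
    """

    matrix: np.ndarray
    complete: np.ndarray
    spec: CrossBasisSpec
    labels: list[tuple[int, int]] = field(default_factory=list)  # (basis j, lag l)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [
                (j, l) for l in range(self.spec.d_l) for j in range(self.spec.d_x)
            ]


def build_crossbasis(exposure: np.ndarray, spec: CrossBasisSpec) -> CrossBasis:
    """Evaluate the cross-basis along one city's exposure series.

    Column block ``l`` at day ``t`` equals the exposure basis at day
    ``t - l``; lags never cross series boundaries, so stack per-city
    cross-bases rather than concatenating exposures.
    """
    exposure = np.asarray(exposure, dtype=float)
    n = len(exposure)
    if n < spec.max_lag + 1:
        raise ValueError(
            f"series of length {n} shorter than max_lag+1 = {spec.max_lag + 1}"
        )
    if spec.boundary is None:
        spec = spec.with_boundary(float(exposure.min()), float(exposure.max()))
    blocks = []
    for lag in range(spec.d_l):
        lagged = np.concatenate([np.repeat(exposure[0], lag), exposure[: n - lag]])
        blocks.append(spec.exposure_basis(lagged))
    complete = np.arange(n) >= spec.max_lag
    return CrossBasis(np.hstack(blocks), complete, spec)


def cumulative_contrast(
    spec: CrossBasisSpec,
    coef: np.ndarray,
    vcov: np.ndarray | None,
    at: float,
    ref: float,
) -> tuple[float, float]:
    """Cumulative (summed over lags) log-RR of ``at`` versus ``ref``.

    Returns ``(log_rr, se)``; ``se`` is ``nan`` when ``vcov`` is None.
    """
    coef = np.asarray(coef, dtype=float)
    if coef.shape[0] != spec.n_columns:
        raise ValueError(
            f"coefficient length {coef.shape[0]} != cross-basis dimension "
            f"{spec.n_columns}"
        )
    c = contrast_vector(spec, at, ref)
    log_rr = float(c @ coef)
    if vcov is None:
        return log_rr, float("nan")
    vcov = np.asarray(vcov, dtype=float)
    if vcov.shape != (spec.n_columns, spec.n_columns):
        raise ValueError("vcov shape does not match cross-basis dimension")
    se = float(np.sqrt(c @ vcov @ c))
    return log_rr, se


def contrast_vector(spec: CrossBasisSpec, at: float, ref: float) -> np.ndarray:
    """Contrast picking out the cumulative exposure effect ``at`` minus ``ref``."""
    delta = (
        spec.exposure_basis(np.array([at]))[0]
        - spec.exposure_basis(np.array([ref]))[0]
    )
    return np.tile(delta, spec.d_l)
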