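"""Temperature standardization and city climate clustering.

Pooling cities with very different climates requires complete overlap of the
exposure ranges; absolute daily mean temperatures are therefore converted to
city-specific percentiles (0-100) over all available days.  For stratified
analyses, cities are grouped by the shape of their temperature distribution:
five empirical quantiles (1st, 10th, 75th, 90th, 99th) are standardized
across cities and fed to agglomerative clustering with Ward linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from .core_io import CityDaySeries, Panel

PROFILE_PERCENTILES = (1.0, 10.0, 75.0, 90.0, 99.0)


@dataclass
class PercentileMap:
    """Monotone map from degrees C to a city's empirical percentile scale."""

    city_id: str
    sample: np.ndarray  # sorted

    def __call__(self, temp_c: np.ndarray) -> np.ndarray:
        temp_c = np.asarray(temp_c, dtype=float)
        n = len(self.sample)
        # midpoint rank: average of counts strictly below and at-or-below
        below = np.searchsorted(self.sample, temp_c, side="left")
        at_or_below = np.searchsorted(self.sample, temp_c, side="right")
        r = (below + at_or_below) / 2.0 + 0.5
        return 100.0 * (r - 0.5) / n


def percentile_map(series: CityDaySeries) -> PercentileMap:
    temps = series.data["temp_c"].to_numpy(dtype=float)
    temps = temps[np.isfinite(temps)]
    if len(temps) == 0:
        raise ValueError(f"city {series.city_id}: no finite temperatures")
    return PercentileMap(series.city_id, np.sort(temps))


def to_percentiles(series: CityDaySeries) -> CityDaySeries:
    """Assign ``temp_pctl`` = 100 * (midpoint rank - 0.5) / n within the city.

    Midpoint ranks handle ties symmetrically (a constant series maps to 50)
    and keep the output strictly inside (0, 100), so every day stays inside
    the spline's boundary knots.  Idempotent: ranks depend only on temp_c.
    """
    temps = series.data["temp_c"].to_numpy(dtype=float)
    if not np.isfinite(temps).any():
        raise ValueError(f"city {series.city_id}: all temperatures missing")
    r = rankdata(temps, method="average")
    pctl = 100.0 * (r - 0.5) / len(temps)
    data = series.data.copy()
    data["temp_pctl"] = pctl
    return CityDaySeries(series.city_id, data)


def panel_to_percentiles(panel: Panel) -> Panel:
    return {c: to_percentiles(s) for c, s in panel.items()}


def profile_city(series: CityDaySeries) -> np.ndarray:
    """Five-point temperature profile (degrees C) at the 1/10/75/90/99th percentiles."""
    temps = series.data["temp_c"].to_numpy(dtype=float)
    temps = temps[np.isfinite(temps)]
    if len(temps) < 100:
        warnings.warn(
            f"city {series.city_id}: only {len(temps)} days; extreme quantiles "
            "of the profile are unstable",
            stacklevel=2,
        )
    return np.percentile(temps, PROFILE_PERCENTILES, method="linear")


@dataclass
class ClusterAssignment:
    """City-to-cluster labels plus per-cluster profile means and the linkage."""

    assignment: pd.Series  # index city_id, values 1..k
    profiles: pd.DataFrame  # per-city raw profiles (degrees C)
    linkage_matrix: np.ndarray
    k: int

    def cities_in(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])

    @property
    def cluster_profiles(self) -> pd.DataFrame:
        return self.profiles.groupby(self.assignment).mean()


def cluster_cities(profiles: dict[str, np.ndarray], k: int = 6) -> ClusterAssignment:
    """Ward clustering of cities on standardized five-percentile profiles.

    Each of the five coordinates is z-scored across cities (sample SD) so no
    single percentile dominates the Euclidean geometry; the Ward tree is cut
    at ``k`` clusters.  Constant coordinates are left uncentred-unscaled
    (degenerate geometry: ties resolve by city order in the linkage).
    """
    cities = list(profiles)
    if k > len(cities):
        raise ValueError(f"k={k} exceeds number of cities ({len(cities)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray([profiles[c] for c in cities], dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles must be finite")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if len(cities) > 1 else np.ones(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    link = linkage(Z, method="ward")
    labels = fcluster(link, t=k, criterion="maxclust")
    assignment = pd.Series(labels, index=pd.Index(cities, name="city_id"))
    prof = pd.DataFrame(
        X, index=assignment.index, columns=[f"p{int(p)}" for p in PROFILE_PERCENTILES]
    )
    return ClusterAssignment(assignment, prof, link, k)


def cluster_panel(panel: Panel, k: int = 6) -> ClusterAssignment:
    return cluster_cities({c: profile_city(s) for c, s in panel.items()}, k=k)
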