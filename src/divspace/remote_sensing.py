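"""NDVI time-series proxies: productivity and land-use intensity.

Per-plot irregular NDVI series (multi-year satellite acquisitions) are
reduced to two scalars.  Productivity is the mean interannual NDVI: a
penalized cyclic cubic regression spline of NDVI on Julian day (basis
dimension 5) plus a categorical year effect is fitted with Gaussian
errors, and the prediction is averaged over days 1-365 with the year
effect averaged over observed years.  Land-use intensity is the mean
absolute residual of a low-flexibility smooth (basis dimension 3) fitted
to growing-season observations only: mowing, grazing and manuring leave
abrupt deflections from the seasonal signal that such a smooth cannot
follow, so the residual magnitude tracks management frequency.

Smoothing penalties are chosen by generalized cross-validation on a
log-spaced grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.gam.smooth_basis import BSplines, CyclicCubicSplines

__all__ = [
    "NDVISeries",
    "TooFewObservationsError",
    "filter_series",
    "mean_interannual_ndvi",
    "land_use_intensity",
]

logger = logging.getLogger(__name__)

DEFAULT_SEASON = (121, 273)  # Julian-day growing-season window


class TooFewObservationsError(ValueError):
    """Raised when a plot has too few usable NDVI records."""

    def __init__(self, plot_id, message: str):
        self.plot_id = plot_id
        super().__init__(f"plot {plot_id!r}: {message}")


@dataclass
class NDVISeries:
    """Irregular NDVI records for one plot.

    ``data`` columns: date (datetime64), ndvi (float), quality
    ('clear'/'bad'); ``season`` is the plot's growing-season window as
    inclusive (start, end) Julian days.
    """

    plot_id: object
    data: pd.DataFrame
    season: tuple[int, int] = DEFAULT_SEASON

    def __post_init__(self) -> None:
        df = self.data.copy()
        df["date"] = pd.to_datetime(df["date"])
        self.data = df.sort_values("date", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


def filter_series(raw: NDVISeries) -> NDVISeries:
    """Retain only clear-flagged records with NDVI in [-1, 1]."""
    df = raw.data
    keep = (df["quality"] == "clear") & df["ndvi"].between(-1.0, 1.0)
    out = df.loc[keep].reset_index(drop=True)
    logger.info("plot %s: retained %d of %d NDVI records", raw.plot_id, len(out), len(df))
    return replace(raw, data=out)


# ---------------------------------------------------------------------------
# penalized least squares with GCV penalty selection
# ---------------------------------------------------------------------------

def _gcv_fit(
    x_unpen: np.ndarray, x_spline: np.ndarray, penalty: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-type fit penalizing only the spline block; alpha chosen by GCV.

    Minimizes mean squared error + alpha * beta_s' S beta_s, scanning alpha
    over {0} and a log grid; returns (coefficients, fitted values).
    """
    X = np.column_stack([x_unpen, x_spline])
    n, p = X.shape
    k = x_unpen.shape[1]
    S = np.zeros((p, p))
    S[k:, k:] = penalty
    xtx = X.T @ X / n
    xty = X.T @ y / n
    best = None
    for alpha in [0.0, *np.logspace(-8, 4, 25)]:
        try:
            A = np.linalg.solve(xtx + alpha * S, np.column_stack([xty, X.T / n]))
        except np.linalg.LinAlgError:
            continue
        beta = A[:, 0]
        fitted = X @ beta
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.einsum("ij,ji->", X, A[:, 1:]))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, beta, fitted)
    if best is None:
        raise np.linalg.LinAlgError("penalized fit failed at every penalty weight")
    return best[1], best[2]


def _day_of_year(dates: pd.Series) -> np.ndarray:
    doy = pd.to_datetime(dates).dt.dayofyear.to_numpy(dtype=float)
    return np.minimum(doy, 365.0)  # fold leap day


def mean_interannual_ndvi(
    series: NDVISeries,
    min_records: int = 20,
    min_years: int = 2,
    min_obs_per_year: int = 3,
    basis_df: int = 5,
) -> float:
    """Day-averaged prediction of the seasonal NDVI model (productivity proxy).

    NDVI is modeled as a penalized cyclic cubic spline of Julian day plus a
    categorical year effect; years with fewer than ``min_obs_per_year``
    records are dropped from the year factor.  The returned value averages
    the predicted curve over Julian days 1-365 with the year effect
    averaged equally over observed years.
    """
    df = series.data
    years = pd.to_datetime(df["date"]).dt.year
    counts = years.value_counts()
    keep_years = counts[counts >= min_obs_per_year].index
    df = df.loc[years.isin(keep_years)]
    years = pd.to_datetime(df["date"]).dt.year.to_numpy()
    if len(df) < min_records or len(np.unique(years)) < min_years:
        raise TooFewObservationsError(
            series.plot_id,
            f"{len(df)} records in {len(np.unique(years))} usable years "
            f"(need >= {min_records} in >= {min_years})",
        )
    doy = _day_of_year(df["date"])
    y = df["ndvi"].to_numpy(dtype=float)

    smoother = CyclicCubicSplines(doy[:, None], df=[basis_df])
    levels = np.sort(np.unique(years))
    dummies = (years[:, None] == levels[None, 1:]).astype(float)
    x_unpen = np.column_stack([np.ones(len(y)), dummies])
    beta, _ = _gcv_fit(x_unpen, smoother.basis, smoother.penalty_matrices[0], y)

    days = np.arange(1, 366, dtype=float)
    spline_new = smoother.transform(days[:, None])
    year_cols = np.full((len(days), len(levels) - 1), 1.0 / len(levels))
    x_new = np.column_stack([np.ones(len(days)), year_cols, spline_new])
    return float(np.mean(x_new @ beta))


def land_use_intensity(
    series: NDVISeries,
    min_records: int = 10,
    basis_df: int = 3,
) -> float:
    """Mean absolute growing-season residual (land-use intensity proxy).

    Records inside the plot's growing-season window are fitted with a
    penalized low-rank smooth of NDVI on Julian day (basis dimension
    ``basis_df``); the mean absolute residual is returned.
    """
    df = series.data
    doy = _day_of_year(df["date"])
    start, end = series.season
    mask = (doy >= start) & (doy <= end)
    df = df.loc[mask]
    doy = doy[mask]
    if len(df) < min_records:
        raise TooFewObservationsError(
            series.plot_id,
            f"{len(df)} growing-season records (need >= {min_records})",
        )
    y = df["ndvi"].to_numpy(dtype=float)
    if np.ptp(doy) <= 0:
        return float(np.mean(np.abs(y - y.mean())))
    smoother = BSplines(doy[:, None], df=[basis_df], degree=[2])
    x_unpen = np.ones((len(y), 1))
    _, fitted = _gcv_fit(x_unpen, smoother.basis, smoother.penalty_matrices[0], y)
    return float(np.mean(np.abs(y - fitted)))
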