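"""Productivity-biodiversity response fitting and curve-shape classification.

For every point of biodiversity space, bootstrap-replicate diversity
values are regressed on NDVI with a low-flexibility penalized smooth
(basis dimension 3) of log-diversity, Gaussian errors.  Goodness of fit is
the explained variance after back-transforming fitted values to the
diversity scale.  The predicted curve over the observed NDVI range is
classified into one of five shapes: ns (R^2 below threshold), concave-
(unimodal, interior maximum), concave+ (interior minimum with a
substantial rise at both edges), increasing, or decreasing.  The extra
edge-rise requirement on concave+ guards against inflexible smooths
mislabeling exponential-like increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.gam.smooth_basis import BSplines

from .remote_sensing import _gcv_fit

__all__ = ["CurveFit", "fit_response", "classify_curve", "summarize_space", "plot_response"]

PREDICTION_GRID_SIZE = 200


@dataclass
class CurveFit:
    """One fitted productivity-diversity response."""

    grid: np.ndarray  # NDVI prediction grid (observed range, 200 points)
    curve: np.ndarray  # predicted diversity (back-transformed)
    r2: float  # explained variance on the diversity scale
    coords: dict = field(default_factory=dict)  # e.g. {"a": 1, "delta": 1, "q": 2}
    shape: str | None = None


def fit_response(
    ndvi: Sequence[float],
    diversity: Sequence[float],
    basis_df: int = 3,
    coords: dict | None = None,
) -> CurveFit:
    """Penalized smooth of log-diversity on NDVI with back-transformed R^2.

    Diversity values must be strictly positive (they are effective
    numbers); they are log-transformed before fitting and the explained
    variance is computed after exponentiating the fitted values back.
    """
    x = np.asarray(ndvi, dtype=float)
    d = np.asarray(diversity, dtype=float)
    if (d <= 0).any():
        raise ValueError("diversity values must be strictly positive")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct NDVI values")
    y = np.log(d)
    smoother = BSplines(x[:, None], df=[basis_df], degree=[2])
    beta, fitted_log = _gcv_fit(
        np.ones((len(y), 1)), smoother.basis, smoother.penalty_matrices[0], y
    )
    fitted = np.exp(fitted_log)
    ss_res = float(np.sum((d - fitted) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    grid = np.linspace(x.min(), x.max(), PREDICTION_GRID_SIZE)
    x_new = np.column_stack([np.ones(len(grid)), smoother.transform(grid[:, None])])
    curve = np.exp(x_new @ beta)
    return CurveFit(grid=grid, curve=curve, r2=r2, coords=dict(coords or {}))


def classify_curve(
    fit: CurveFit,
    r2_threshold: float = 0.15,
    edge_rise_fraction: float = 0.25,
) -> str:
    """Assign one of {ns, concave-, concave+, increasing, decreasing}.

    Rules, applied in order on the predicted curve: (1) R^2 below the
    threshold is 'ns'; (2) an interior maximum (minimum at an edge) is
    'concave-'; (3) an interior minimum with predictions at BOTH edges
    exceeding min + edge_rise_fraction * (max - min) is 'concave+';
    otherwise (4) the curve is 'increasing' when its maximum sits at the
    right edge and 'decreasing' when it sits at the left edge.  Exact-tie
    extrema at an edge count as edge.
    """
    curve = np.asarray(fit.curve, dtype=float)
    n = len(curve)
    i_max = int(np.argmax(curve))
    i_min = int(np.argmin(curve))
    cmax, cmin = curve[i_max], curve[i_min]
    interior_max = curve[0] < cmax and curve[-1] < cmax
    interior_min = curve[0] > cmin and curve[-1] > cmin

    shape: str
    if fit.r2 < r2_threshold:
        shape = "ns"
    elif interior_max and not interior_min:
        shape = "concave-"
    else:
        rng = cmax - cmin
        if (
            interior_min
            and rng > 0
            and curve[0] > cmin + edge_rise_fraction * rng
            and curve[-1] > cmin + edge_rise_fraction * rng
        ):
            shape = "concave+"
        elif curve[-1] >= curve[0]:
            shape = "increasing"
        else:
            shape = "decreasing"
    fit.shape = shape
    return shape


def summarize_space(fits: Sequence[CurveFit]) -> pd.DataFrame:
    """Tidy (a, delta, q, shape, r2) table across biodiversity space."""
    rows = []
    for fit in fits:
        row = dict(fit.coords)
        row["shape"] = fit.shape if fit.shape is not None else classify_curve(fit)
        row["r2"] = fit.r2
        rows.append(row)
    return pd.DataFrame(rows)


_SHAPE_COLORS = {
    "increasing": "tab:blue",
    "concave-": "gold",
    "concave+": "purple",
    "decreasing": "tab:orange",
    "ns": "gray",
}


def plot_response(
    ndvi: Sequence[float],
    diversity: Sequence[float],
    fit: CurveFit,
    bins: Sequence | None = None,
    ax=None,
):
    """Boxplots of diversity per NDVI bin with the colored fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(ndvi, dtype=float)
    d = np.asarray(diversity, dtype=float)
    if bins is not None:
        df = pd.DataFrame({"bin": bins, "D": d, "ndvi": x})
        groups = [g["D"].to_numpy() for _, g in df.groupby("bin")]
        centers = [g["ndvi"].mean() for _, g in df.groupby("bin")]
        width = 0.6 * np.min(np.diff(sorted(centers))) if len(centers) > 1 else 0.01
        ax.boxplot(groups, positions=centers, widths=width, manage_ticks=False)
    else:
        ax.plot(x, d, ".", alpha=0.3, color="0.5")
    shape = fit.shape or "ns"
    ax.plot(fit.grid, fit.curve, color=_SHAPE_COLORS.get(shape, "black"), lw=2,
            label=f"{shape} (R$^2$={fit.r2:.2f})")
    ax.set_xlabel("NDVI")
    ax.set_ylabel("diversity (effective number)")
    ax.legend()
    return ax
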