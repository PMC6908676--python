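"""Community-table preparation: coverage conversion, quality filtering,
ecosystem assignment, NDVI binning, and spatially constrained bootstraps.

Plot-level vegetation surveys record species abundance in ordinal coverage
classes; these are converted to percentage midpoints (totals may exceed
100% because vegetation is vertically layered).  Plots are filtered on
four quality criteria (sampling completeness & richness, geo-positioning
precision, plausible total coverage, trait coverage), labeled by ecosystem
type from the habitat affinities of their dominant coverage, binned along
the NDVI/productivity gradient, and resampled with a minimum pairwise
distance constraint so bootstrap replicates are not spatially clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "FilterThresholds",
    "DEFAULT_COVERAGE_MIDPOINTS",
    "DEFAULT_BIN_EDGES",
    "convert_coverage",
    "quality_filter",
    "assign_ecosystem",
    "bin_plots",
    "quantile_bin_edges",
    "land_use_tertiles",
    "bootstrap_bins",
]

#: Braun-Blanquet-style midpoints for the six coverage classes (percent).
DEFAULT_COVERAGE_MIDPOINTS: dict[int, float] = {
    1: 0.5,
    2: 3.0,
    3: 15.0,
    4: 37.5,
    5: 62.5,
    6: 87.5,
}

#: 18 regular NDVI bins from -0.04 to 0.32 in steps of 0.02.
DEFAULT_BIN_EDGES: np.ndarray = np.round(np.arange(-0.04, 0.32 + 1e-9, 0.02), 10)


@dataclass
class CommunityTable:
    """Long-format coverage records plus per-plot metadata.

    ``cover`` columns: plot_id, species_id, coverage (percent).
    ``plots`` is indexed by plot_id with columns x, y (projected meters),
    geo_precision (m), complete (bool); a ``total_coverage`` column is
    maintained as the per-plot coverage sum.
    """

    cover: pd.DataFrame
    plots: pd.DataFrame

    def __post_init__(self) -> None:
        totals = self.cover.groupby("plot_id")["coverage"].sum()
        plots = self.plots.copy()
        plots["total_coverage"] = totals.reindex(plots.index).fillna(0.0)
        plots["n_species"] = (
            self.cover[self.cover["coverage"] > 0]
            .groupby("plot_id")["species_id"]
            .nunique()
            .reindex(plots.index)
            .fillna(0)
            .astype(int)
        )
        self.plots = plots

    def subset(self, plot_ids: Sequence) -> "CommunityTable":
        keep = self.plots.index.isin(plot_ids)
        return CommunityTable(
            cover=self.cover[self.cover["plot_id"].isin(plot_ids)].reset_index(drop=True),
            plots=self.plots.loc[keep].drop(columns=["total_coverage", "n_species"]),
        )


def convert_coverage(
    classes: pd.DataFrame,
    plots: pd.DataFrame,
    conversion: Mapping[int, float] | None = None,
) -> CommunityTable:
    """Translate ordinal coverage classes into coverage percentages.

    ``classes`` columns: plot_id, species_id, coverage_class.  Unknown
    class codes raise; totals above 100% are retained (layered vegetation).
    """
    conv = dict(DEFAULT_COVERAGE_MIDPOINTS if conversion is None else conversion)
    codes = classes["coverage_class"]
    unknown = set(codes.unique()) - set(conv)
    if unknown:
        raise ValueError(f"unknown coverage class code(s): {sorted(unknown)!r}")
    cover = classes[["plot_id", "species_id"]].copy()
    cover["coverage"] = codes.map(conv).astype(float)
    return CommunityTable(cover=cover, plots=plots)


@dataclass(frozen=True)
class FilterThresholds:
    """Quality-filter thresholds (defaults follow the four survey criteria)."""

    min_species: int = 10
    max_geo_precision: float = 10.0  # meters
    min_total_coverage: float = 30.0  # percent, strict >
    max_total_coverage: float = 250.0  # percent, strict <
    min_trait_coverage: float = 0.8  # fraction of total coverage


def quality_filter(
    communities: CommunityTable,
    traits: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[CommunityTable, list[dict]]:
    """Retain plots passing all four quality criteria, in order.

    Criteria: (1) completely sampled with at least ``min_species`` species;
    (2) geo-positioning standard error at most ``max_geo_precision`` m;
    (3) total coverage strictly between the coverage bounds; (4) species
    with complete trait data contribute at least ``min_trait_coverage`` of
    the total coverage.  The audit log records, per dropped plot, the first
    criterion failed; retained plots are logged as passing.
    """
    th = thresholds
    complete_traits = set(traits.dropna().index)
    audit: list[dict] = []
    keep: list = []
    cover_by_plot = dict(iter(communities.cover.groupby("plot_id")))
    for plot_id, row in communities.plots.iterrows():
        entry = {"plot_id": plot_id}
        sub = cover_by_plot.get(plot_id)
        total = float(row["total_coverage"])
        if not bool(row.get("complete", True)) or row["n_species"] < th.min_species:
            entry.update(passed=False, failed="sampling")
        elif row["geo_precision"] > th.max_geo_precision:
            entry.update(passed=False, failed="geo_precision")
        elif not (th.min_total_coverage < total < th.max_total_coverage):
            entry.update(passed=False, failed="total_coverage")
        else:
            with_traits = sub.loc[
                sub["species_id"].isin(complete_traits), "coverage"
            ].sum()
            frac = with_traits / total if total > 0 else 0.0
            entry["trait_coverage"] = float(frac)
            if frac < th.min_trait_coverage:
                entry.update(passed=False, failed="trait_coverage")
            else:
                entry.update(passed=True)
                keep.append(plot_id)
        audit.append(entry)
    return communities.subset(keep), audit


def assign_ecosystem(
    communities: CommunityTable,
    habitat_flags: pd.DataFrame,
    dominance_threshold: float = 0.5,
    exclusion_threshold: float = 0.25,
) -> pd.Series:
    """Label each plot forest / grassland / other from habitat affinities.

    ``habitat_flags`` is indexed by species with boolean columns
    forest_typical and grassland_typical.  A plot is forest when
    forest-typical species contribute at least ``dominance_threshold`` of
    its coverage while grassland-typical species stay below
    ``exclusion_threshold`` (and symmetrically for grassland); everything
    else is "other".
    """
    missing = set(communities.cover["species_id"]) - set(habitat_flags.index)
    if missing:
        raise ValueError(f"species without habitat flags: {sorted(missing)[:5]!r}")
    cov = communities.cover.merge(
        habitat_flags[["forest_typical", "grassland_typical"]],
        left_on="species_id",
        right_index=True,
    )
    grouped = cov.groupby("plot_id").apply(
        lambda g: pd.Series(
            {
                "forest": g.loc[g["forest_typical"], "coverage"].sum() / g["coverage"].sum(),
                "grassland": g.loc[g["grassland_typical"], "coverage"].sum()
                / g["coverage"].sum(),
            }
        ),
        include_groups=False,
    )
    labels = pd.Series("other", index=communities.plots.index, name="ecosystem")
    f = grouped["forest"].reindex(labels.index).fillna(0.0)
    g = grouped["grassland"].reindex(labels.index).fillna(0.0)
    labels[(f >= dominance_threshold) & (g < exclusion_threshold)] = "forest"
    labels[(g >= dominance_threshold) & (f < exclusion_threshold)] = "grassland"
    return labels


def bin_plots(
    ndvi: pd.Series, edges: np.ndarray | Sequence[float] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Assign plots to NDVI bins with half-open [lower, upper) intervals.

    The last bin is closed on the right; plots outside the edge range get
    bin -1 and out_of_range=True.
    """
    edges = np.asarray(edges, dtype=float)
    if not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    vals = ndvi.to_numpy(dtype=float)
    idx = np.searchsorted(edges, vals, side="right") - 1
    idx[vals == edges[-1]] = len(edges) - 2  # close the last bin
    out_of_range = (idx < 0) | (idx > len(edges) - 2)
    idx[out_of_range] = -1
    return pd.DataFrame(
        {"ndvi": vals, "bin": idx, "out_of_range": out_of_range}, index=ndvi.index
    )


def quantile_bin_edges(ndvi: pd.Series, step: float = 0.05) -> np.ndarray:
    """Alternative binning: edges at regular quantiles (default 5% percentiles)."""
    qs = np.arange(0.0, 1.0 + 1e-9, step)
    return np.unique(np.quantile(ndvi.to_numpy(dtype=float), qs))


def land_use_tertiles(intensities: pd.Series) -> pd.Series:
    """Split land-use intensities into low / medium / high tertiles.

    Ties at a boundary go to the lower class (boundary membership uses <=).
    """
    if len(intensities) < 3:
        raise ValueError("need at least 3 plots to form tertiles")
    vals = intensities.to_numpy(dtype=float)
    t1, t2 = np.quantile(vals, [1 / 3, 2 / 3])
    labels = np.where(vals <= t1, "low", np.where(vals <= t2, "medium", "high"))
    return pd.Series(labels, index=intensities.index, name="land_use")


def bootstrap_bins(
    assignments: pd.DataFrame,
    coords: pd.DataFrame,
    n_reps: int = 100,
    sample_size: int = 40,
    min_dist: float = 5000.0,
    seed: int | np.random.Generator | None = None,
    retry_budget: int = 1000,
) -> tuple[dict[int, list[list]], list[int]]:
    """Spatially constrained bootstrap samples of plots per NDVI bin.

    For each occupied bin, draws ``n_reps`` subsets of ``sample_size``
    plots in which every pair is at least ``min_dist`` meters apart,
    using shuffled greedy accept/reject with ``retry_budget`` attempts per
    replicate.  Bins where any replicate cannot be filled are dropped and
    returned in the second element.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples: dict[int, list[list]] = {}
    dropped: list[int] = []
    xy = coords[["x", "y"]]
    for bin_id, sub in assignments[~assignments["out_of_range"]].groupby("bin"):
        ids = list(sub.index)
        pts = xy.loc[ids].to_numpy(dtype=float)
        reps: list[list] = []
        feasible = True
        for _ in range(n_reps):
            chosen_idx: list[int] = []
            for _attempt in range(retry_budget):
                order = rng.permutation(len(ids))
                chosen_idx = []
                chosen_pts = np.empty((0, 2))
                for i in order:
                    if len(chosen_idx) == sample_size:
                        break
                    p = pts[i]
                    if chosen_pts.shape[0] == 0 or (
                        np.hypot(*(chosen_pts - p).T) >= min_dist
                    ).all():
                        chosen_idx.append(i)
                        chosen_pts = np.vstack([chosen_pts, p])
                if len(chosen_idx) == sample_size:
                    break
            if len(chosen_idx) < sample_size:
                feasible = False
                break
            reps.append([ids[i] for i in chosen_idx])
        if feasible:
            samples[int(bin_id)] = reps
        else:
            dropped.append(int(bin_id))
    return samples, dropped
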