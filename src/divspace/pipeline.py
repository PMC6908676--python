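"""End-to-end orchestration: scenario -> binned bootstraps -> diversity ->
fitted and classified productivity-biodiversity relationships.

This is the composition layer the acceptance checks and the CLI drive; it
wires the individual modules together exactly the way the analysis runs on
real inputs, except that plot productivity comes from the generator's
ground truth (the NDVI proxy estimators are validated separately against
series with known structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_prep import (
    DEFAULT_BIN_EDGES,
    CommunityTable,
    bin_plots,
    bootstrap_bins,
    convert_coverage,
)
from .diversity import ParameterGrid, diversity_grid
from .relationships import CurveFit, classify_curve, fit_response, summarize_space
from .synthetic_data import ScenarioConfig, ScenarioData, generate_scenario
from .trees import build_functional_tree, expand_genus_tree

__all__ = [
    "ScenarioResult",
    "pooled_bootstrap_communities",
    "run_scenario",
    "null_comparison",
]

#: Reduced grid covering the corners of biodiversity space; full analyses
#: pass ParameterGrid() instead.
REDUCED_GRID = ParameterGrid(
    a_values=(0.0, 1.0), delta_values=(1.0, math.inf), q_values=(0.0, 2.0)
)


@dataclass
class ScenarioResult:
    data: ScenarioData
    diversity: pd.DataFrame  # tidy (a, delta, q, community, D) + bin, ndvi
    fits: list[CurveFit]
    summary: pd.DataFrame  # (a, delta, q, shape, r2)


def pooled_bootstrap_communities(
    communities: CommunityTable,
    ndvi: pd.Series,
    bin_edges=DEFAULT_BIN_EDGES,
    n_boot: int = 100,
    sample_size: int = 40,
    min_dist: float = 5000.0,
    seed=None,
) -> tuple[list[pd.Series], list[tuple[int, int]], list[float]]:
    """Coverage-summed pooled communities for every (bin, bootstrap rep).

    Plots are binned on NDVI, resampled with the pairwise-distance
    constraint, and each replicate's coverages are summed per species into
    one pooled abundance vector.  Returns (abundance vectors, (bin, rep)
    ids, mean NDVI per pooled community).
    """
    assignments = bin_plots(ndvi.loc[communities.plots.index], bin_edges)
    samples, _dropped = bootstrap_bins(
        assignments,
        communities.plots,
        n_reps=n_boot,
        sample_size=sample_size,
        min_dist=min_dist,
        seed=seed,
    )
    cover = communities.cover
    by_plot = {pid: g for pid, g in cover.groupby("plot_id")}
    pooled: list[pd.Series] = []
    ids: list[tuple[int, int]] = []
    ndvi_means: list[float] = []
    for bin_id in sorted(samples):
        for rep, plot_ids in enumerate(samples[bin_id]):
            frames = [by_plot[pid] for pid in plot_ids if pid in by_plot]
            merged = pd.concat(frames).groupby("species_id")["coverage"].sum()
            pooled.append(merged / merged.sum())
            ids.append((bin_id, rep))
            ndvi_means.append(float(ndvi.loc[plot_ids].mean()))
    return pooled, ids, ndvi_means


def run_scenario(
    config: ScenarioConfig,
    grid: ParameterGrid = REDUCED_GRID,
    n_tree_reps: int = 1,
    n_boot: int = 100,
    sample_size: int = 40,
    bin_edges=DEFAULT_BIN_EDGES,
) -> ScenarioResult:
    """Run the full analysis on one synthetic scenario.

    Generates the inputs, builds the functional tree from traits and
    ``n_tree_reps`` Yule-expanded phylogeny replicates, pools
    spatially-constrained bootstrap samples per productivity bin,
    evaluates diversity over the grid, and fits/classifies each
    (a, delta, q) response.
    """
    data = generate_scenario(config, with_ndvi=False)
    rng = np.random.default_rng(config.seed + 7)
    ftree = build_functional_tree(data.traits)
    ptrees = [
        expand_genus_tree(data.genus_tree, data.species_to_genus, int(s))
        for s in rng.integers(0, 2**31 - 1, size=n_tree_reps)
    ]
    communities = convert_coverage(data.cover_classes, data.plots)
    pooled, ids, ndvi_means = pooled_bootstrap_communities(
        communities,
        data.truth.productivity,
        bin_edges=bin_edges,
        n_boot=n_boot,
        sample_size=sample_size,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    div = diversity_grid(pooled, ftree, ptrees, grid, community_ids=list(range(len(pooled))))
    meta = pd.DataFrame(
        {
            "community": range(len(pooled)),
            "bin": [b for b, _ in ids],
            "rep": [r for _, r in ids],
            "ndvi": ndvi_means,
        }
    )
    div = div.merge(meta, on="community")
    fits = []
    for (a, delta, q), sub in div.groupby(["a", "delta", "q"]):
        fit = fit_response(sub["ndvi"], sub["D"], coords={"a": a, "delta": delta, "q": q})
        classify_curve(fit)
        fits.append(fit)
    return ScenarioResult(
        data=data, diversity=div, fits=fits, summary=summarize_space(fits)
    )


def null_comparison(
    result: ScenarioResult,
    grid: ParameterGrid = REDUCED_GRID,
    n_sets: int = 200,
    set_size: int = 40,
    top_k_bins: int = 5,
    n_swaps: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Density bias of observed high-productivity diversity against nulls.

    Randomizes the site x species matrix with the checkerboard swap chain,
    permutes the observed per-site abundance multisets onto the new
    species lists, draws null community sets with equal per-bin
    representation, evaluates their diversity on the same grid and trees,
    and returns the per-(a, delta, q) density bias averaged over the
    ``top_k_bins`` highest-productivity bins.
    """
    from .null_models import (
        default_n_swaps,
        high_productivity_bias,
        reassign_abundances,
        sample_null_sets,
        swap_chain,
    )

    rng = np.random.default_rng(seed)
    data = result.data
    communities = convert_coverage(data.cover_classes, data.plots)
    wide = (
        communities.cover.pivot_table(
            index="plot_id", columns="species_id", values="coverage", fill_value=0.0
        )
    )
    presence = (wide.to_numpy() > 0).astype(np.int8)
    shuffled = swap_chain(
        presence,
        n_swaps if n_swaps is not None else default_n_swaps(presence),
        seed=int(rng.integers(2**31)),
    )
    null_cov = reassign_abundances(
        pd.DataFrame(shuffled, index=wide.index, columns=wide.columns),
        wide,
        seed=int(rng.integers(2**31)),
    )
    ndvi = data.truth.productivity
    assignments = bin_plots(ndvi.loc[wide.index])
    site_bins = assignments.loc[~assignments["out_of_range"], "bin"]
    sets = sample_null_sets(site_bins, n_sets=n_sets, set_size=set_size,
                            seed=int(rng.integers(2**31)))
    pooled = []
    for s in sets:
        merged = null_cov.loc[s].sum(axis=0)
        merged = merged[merged > 0]
        pooled.append(merged / merged.sum())
    ftree = build_functional_tree(data.traits)
    ptrees = [expand_genus_tree(data.genus_tree, data.species_to_genus,
                                int(rng.integers(2**31)))]
    null_div = diversity_grid(pooled, ftree, ptrees, grid,
                              community_ids=list(range(len(pooled))))
    observed = result.diversity[["a", "delta", "q", "bin", "D"]]
    return high_productivity_bias(observed, null_div, top_k_bins=top_k_bins)
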