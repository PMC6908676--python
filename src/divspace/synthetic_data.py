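"""Synthetic inputs with known ground truth for the whole pipeline.

Real inputs to this analysis are plot-level vegetation surveys, a species
trait table, a genus-level ultrametric phylogeny and per-plot NDVI time
series.  This module generates statistically analogous stand-ins with
controllable structure so every downstream stage can be tested against a
known answer:

* a Yule (pure-birth) genus phylogeny, depth-normalized to 1;
* strictly positive log-normal traits, optionally with phylogenetic
  signal (Brownian motion of log-traits along the tree);
* communities assembled along a latent productivity gradient.  Species
  receive niche windows on the gradient whose density follows the
  configured richness shape; per-plot species sets are drawn from the
  local candidate pool, biased toward trait-dispersed or trait-clustered
  subsets to dial trait/phylogenetic diversity response shapes
  independently; abundances follow a geometric dominance series and are
  discretized into the six ordinal coverage classes;
* irregular multi-year NDVI series: plot mean + seasonal sinusoid + year
  offsets + growing-season land-use deflections + noise, with a
  configurable fraction of bad-quality acquisitions.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .community_prep import DEFAULT_COVERAGE_MIDPOINTS
from .remote_sensing import NDVISeries
from .trees import expand_genus_tree, node_depths, tree_to_distance

__all__ = [
    "TraitSpec",
    "ShapeSpec",
    "NDVISpec",
    "ScenarioConfig",
    "GroundTruth",
    "SHAPES",
    "COVERAGE_CLASS_BOUNDS",
    "coverage_to_class",
    "shape_mean_function",
    "gen_genus_phylogeny",
    "gen_traits",
    "gen_communities",
    "gen_ndvi_series",
    "ScenarioData",
    "generate_scenario",
    "config_from_dict",
    "write_scenario",
]

SHAPES = ("increasing", "decreasing", "concave-", "flat")

#: Upper bounds (percent) of the six coverage classes; class k covers
#: (bound[k-1], bound[k]].
COVERAGE_CLASS_BOUNDS = (0.0, 1.0, 5.0, 25.0, 50.0, 75.0, 100.0)


def coverage_to_class(percent: float) -> int:
    """Ordinal coverage class (1-6) for a coverage percentage."""
    if percent <= 0:
        raise ValueError("coverage must be positive to receive a class")
    idx = int(np.searchsorted(COVERAGE_CLASS_BOUNDS, min(percent, 100.0), side="left"))
    return min(max(idx, 1), 6)


@dataclass(frozen=True)
class TraitSpec:
    """Log-normal trait parameters: log-scale location/scale and signal switch."""

    location: float = 1.0
    scale: float = 0.6
    phylo_signal: bool = False

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError(f"trait scale must be >= 0, got {self.scale}")


@dataclass(frozen=True)
class ShapeSpec:
    """Target response shapes along the productivity gradient."""

    richness: str = "concave-"
    trait_diversity: str = "increasing"
    phylo_diversity: str = "flat"
    richness_amplitude: float = 10.0  # species, peak-to-base
    richness_base: float = 12.0  # species at the low end
    dispersion_amplitude: float = 6.0  # selection-bias strength for trait/phylo shaping

    def __post_init__(self) -> None:
        for name in ("richness", "trait_diversity", "phylo_diversity"):
            val = getattr(self, name)
            if not isinstance(val, str) or val not in SHAPES:
                raise ValueError(
                    f"shape_spec.{name} must be one of {SHAPES}, got {val!r}"
                )


@dataclass(frozen=True)
class NDVISpec:
    """NDVI time-series generator parameters."""

    ndvi_range: tuple[float, float] = (-0.03, 0.31)  # latent plot mean levels
    seasonal_amplitude: float = 0.06
    year_offset_sd: float = 0.01
    residual_sd: float = 0.02
    disturbance_magnitude: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.01, "medium": 0.05, "high": 0.12}
    )
    disturbance_prob: float = 0.2  # per growing-season acquisition
    bad_quality_fraction: float = 0.2
    year_start: int = 1999
    year_end: int = 2017
    revisit_days: int = 16
    gap_fraction: float = 0.2
    season: tuple[int, int] = (121, 273)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one synthetic study."""

    n_genera: int = 80
    species_per_genus_mean: float = 2.5  # shifted-Poisson mean (>= 1)
    n_plots: int = 900
    n_bins_target: int = 18
    trait_spec: Mapping[str, TraitSpec] = field(
        default_factory=lambda: {
            "SLA": TraitSpec(location=2.8, scale=0.5),
            "HGT": TraitSpec(location=3.0, scale=1.0),
            "SM": TraitSpec(location=0.0, scale=1.4),
        }
    )
    shape_spec: ShapeSpec = ShapeSpec()
    dominance_evenness: float = 0.8  # geometric-series ratio; 1 = perfectly even
    niche_width: float = 0.35  # half-width of species niche windows (gradient units)
    #: fraction of local candidates sampled per plot; None auto-calibrates so
    #: the expected per-plot richness matches the configured mean function
    occupancy: float | None = None
    total_coverage_range: tuple[float, float] = (60.0, 120.0)
    plot_spacing: float = 6000.0  # meters; > 5 km so bootstraps are feasible
    ndvi_spec: NDVISpec = NDVISpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1 or self.n_plots < 0 or self.n_bins_target < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.dominance_evenness <= 1):
            raise ValueError("dominance_evenness must lie in (0, 1]")
        if self.occupancy is not None and not (0 < self.occupancy <= 1):
            raise ValueError("occupancy must lie in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually embedded, for recovery checks."""

    shapes: dict[str, str]
    productivity: pd.Series  # per-plot latent NDVI mean level
    land_use: pd.Series  # per-plot class in {low, medium, high}
    habitat_flags: pd.DataFrame  # species x boolean flag columns
    niche_optima: pd.Series  # species position on the normalized gradient


# ---------------------------------------------------------------------------
# response-shape mean functions
# ---------------------------------------------------------------------------

def shape_mean_function(shape: str, t: np.ndarray | float, base: float, amplitude: float):
    """Noiseless expected response at normalized gradient position t in [0,1].

    Defines the embedded shapes: increasing/decreasing are linear ramps,
    concave- is a parabola peaking at t = 0.5, flat is constant.
    """
    t = np.asarray(t, dtype=float)
    if shape == "flat":
        return base + np.zeros_like(t)
    if shape == "increasing":
        return base + amplitude * t
    if shape == "decreasing":
        return base + amplitude * (1.0 - t)
    if shape == "concave-":
        return base + amplitude * (1.0 - (2.0 * t - 1.0) ** 2)
    raise ValueError(f"unknown shape {shape!r}")


def _dispersion_bias(shape: str, t: float, beta0: float) -> float:
    """Selection-bias coefficient beta(t): positive = trait-dispersed sampling."""
    if shape == "flat":
        return 0.0
    if shape == "increasing":
        return beta0 * (2.0 * t - 1.0)
    if shape == "decreasing":
        return -beta0 * (2.0 * t - 1.0)
    if shape == "concave-":
        return beta0 * (2.0 * (1.0 - (2.0 * t - 1.0) ** 2) - 1.0)
    raise ValueError(f"unknown shape {shape!r}")


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def gen_genus_phylogeny(
    n_genera: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> dendropy.Tree:
    """Simulate a Yule (pure-birth) genus tree, depth-normalized to 1.

    Starting from the root split (two lineages at time 0), a uniformly
    chosen lineage splits after an Exp(rate * k) waiting time until
    ``n_genera`` lineages exist; tips then extend by one final waiting
    time.  Tips are labeled g001, g002, ... in simulation order.
    """
    if n_genera < 2:
        raise ValueError(f"need at least 2 genera, got {n_genera}")
    if not (birth_rate > 0):
        raise ValueError(f"birth rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tree = dendropy.Tree()
    root = tree.seed_node
    active: list[dendropy.Node] = []
    birth: dict[dendropy.Node, float] = {}
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_genera:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    width = len(str(n_genera))
    tns = tree.taxon_namespace
    for i, node in enumerate(active):
        node.edge.length = t - birth[node]
        node.taxon = tns.new_taxon(label=f"g{i + 1:0{width}d}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    return tree


def species_per_genus(
    n_genera: int, mean: float, seed: int | np.random.Generator | None = None
) -> dict[str, int]:
    """Shifted-Poisson species counts per genus (every genus keeps >= 1)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    width = len(str(n_genera))
    counts = 1 + rng.poisson(max(mean - 1.0, 0.0), size=n_genera)
    return {f"g{i + 1:0{width}d}": int(c) for i, c in enumerate(counts)}


def species_names(genus_counts: Mapping[str, int]) -> dict[str, str]:
    """Species-id -> genus-id map, species labeled <genus>_s1, <genus>_s2, ..."""
    return {
        f"{genus}_s{j + 1}": genus
        for genus in sorted(genus_counts)
        for j in range(genus_counts[genus])
    }


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def gen_traits(
    species_list: Sequence[str],
    phylogeny: dendropy.Tree | None,
    trait_spec: Mapping[str, TraitSpec],
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Strictly positive trait values, log-normal across species.

    With ``phylo_signal`` on, log-traits evolve by Brownian motion along
    the (species-level, depth-1) phylogeny so the tip marginal standard
    deviation equals the configured scale; otherwise log-traits are i.i.d.
    normal.  Values are exponentiated, so a zero scale collapses every
    species to exp(location).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    species = list(species_list)
    columns: dict[str, np.ndarray] = {}
    tip_values: dict[str, dict[str, float]] | None = None
    for name in sorted(trait_spec):
        spec = trait_spec[name]
        if spec.scale < 0:
            raise ValueError(f"trait {name!r}: scale must be >= 0")
        if spec.phylo_signal:
            if phylogeny is None:
                raise ValueError(f"trait {name!r} requests phylogenetic signal but no tree given")
            values = _brownian_tips(phylogeny, rng)
            missing = [sp for sp in species if sp not in values]
            if missing:
                raise ValueError(f"species {missing[0]!r} absent from the phylogeny")
            logs = spec.location + spec.scale * np.array([values[sp] for sp in species])
        else:
            logs = spec.location + spec.scale * rng.standard_normal(len(species))
        columns[name] = np.exp(logs)
    return pd.DataFrame(columns, index=pd.Index(species, name="species_id"))


def _brownian_tips(tree: dendropy.Tree, rng: np.random.Generator) -> dict[str, float]:
    """Standard Brownian motion along the tree; tip variance equals tree depth."""
    values: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[node] = 0.0
            continue
        edge = node.edge.length or 0.0
        values[node] = values[parent] + math.sqrt(max(edge, 0.0)) * rng.standard_normal()
    return {leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def gen_communities(
    config: ScenarioConfig,
    traits: pd.DataFrame,
    phylogeny: dendropy.Tree,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Assemble plot communities along a latent productivity gradient.

    Returns (cover_classes, plots, ground_truth): long-format class-coded
    records (plot_id, species_id, coverage_class), per-plot metadata
    (coordinates, geo precision, completeness), and the embedded truth.

    Mechanism: species receive niche windows on the normalized gradient
    whose center density follows the configured richness shape, so the
    local candidate-pool size (and with it both per-plot and pooled
    richness) inherits that shape.  Within the candidate pool, species are
    sampled sequentially with weights exp(beta_f * trait spread + beta_p *
    phylogenetic spread), where the beta coefficients vary along the
    gradient according to the trait/phylogenetic diversity shapes.
    Abundances follow a geometric series with the configured evenness and
    are discretized into coverage classes.
    """
    rng = np.random.default_rng(config.seed)
    shapes = config.shape_spec
    species = list(traits.index)
    n_sp = len(species)
    if n_sp < 2:
        raise ValueError("need at least 2 species")

    # niche optima with density proportional to the richness mean function,
    # extended past [0, 1] by one window so edges are not depleted
    w = config.niche_width
    m_base, m_amp = shapes.richness_base, shapes.richness_amplitude
    m_max = float(
        np.max(shape_mean_function(shapes.richness, np.linspace(0, 1, 201), m_base, m_amp))
    )
    optima = np.empty(n_sp)
    filled = 0
    while filled < n_sp:
        prop = rng.uniform(-w, 1.0 + w, size=2 * n_sp)
        m = shape_mean_function(shapes.richness, np.clip(prop, 0, 1), m_base, m_amp)
        accept = rng.uniform(0, m_max, size=prop.size) < m
        take = prop[accept][: n_sp - filled]
        optima[filled : filled + take.size] = take
        filled += take.size
    optima = optima[rng.permutation(n_sp)]

    # occupancy calibration: the expected candidate count at t is
    # N(t) ~ S * 2w * m(t) / Z, so a constant sampling fraction Z / (2 w S)
    # makes the expected per-plot richness equal the mean function m(t)
    tgrid = np.linspace(-w, 1.0 + w, 513)
    z_norm = float(
        np.trapezoid(
            shape_mean_function(shapes.richness, np.clip(tgrid, 0, 1), m_base, m_amp),
            tgrid,
        )
    )
    occupancy = config.occupancy
    if occupancy is None:
        occupancy = min(0.95, z_norm / (2.0 * w * n_sp))

    # species scores for dispersion-biased sampling
    logged = np.log(traits.to_numpy(dtype=float))
    std = logged.std(axis=0, ddof=1)
    zt = (logged - logged.mean(axis=0)) / np.where(std > 0, std, 1.0)
    pdist_df = tree_to_distance(phylogeny)
    pdist_df = pdist_df.loc[species, species]
    pd_arr = pdist_df.to_numpy()
    trait_scale = float(np.mean(np.linalg.norm(zt[:, None, :] - zt[None, :, :], axis=-1)))
    phylo_scale = float(pd_arr.mean()) or 1.0

    # plots: stratified latent productivity, >5-km grid coordinates
    n_plots = config.n_plots
    lo, hi = config.ndvi_spec.ndvi_range
    bins = config.n_bins_target
    t_plot = np.array(
        [rng.uniform(b / bins, (b + 1) / bins) for b in np.arange(n_plots) % bins]
    )
    t_plot = t_plot[rng.permutation(n_plots)]
    side = max(int(math.ceil(math.sqrt(max(n_plots, 1)))), 1)
    idx = np.arange(n_plots)
    coords_x = (idx % side) * config.plot_spacing + rng.uniform(-200, 200, n_plots)
    coords_y = (idx // side) * config.plot_spacing + rng.uniform(-200, 200, n_plots)

    records: list[tuple[str, str, int]] = []
    plot_ids = [f"p{i + 1:04d}" for i in range(n_plots)]
    for p, t in enumerate(t_plot):
        cand = np.nonzero(np.abs(t - optima) <= w)[0]
        if cand.size == 0:
            continue
        n_take = int(rng.binomial(cand.size, occupancy))
        n_take = max(min(n_take, cand.size), min(2, cand.size))
        beta_f = _dispersion_bias(shapes.trait_diversity, t, shapes.dispersion_amplitude)
        beta_p = _dispersion_bias(shapes.phylo_diversity, t, shapes.dispersion_amplitude)
        chosen = [int(cand[rng.integers(cand.size)])]
        pool = [i for i in cand if i != chosen[0]]
        while len(chosen) < n_take and pool:
            pool_arr = np.asarray(pool)
            centroid = zt[chosen].mean(axis=0)
            d_trait = np.linalg.norm(zt[pool_arr] - centroid, axis=1) / (trait_scale or 1.0)
            d_phylo = pd_arr[np.ix_(pool_arr, chosen)].mean(axis=1) / phylo_scale
            logw = beta_f * d_trait + beta_p * d_phylo
            wts = np.exp(logw - logw.max())
            wts /= wts.sum()
            pick = int(rng.choice(len(pool), p=wts))
            chosen.append(pool.pop(pick))
        # geometric dominance series; dominance order biased so abundant
        # species are trait/phylogenetically extreme (dispersed, beta > 0)
        # or central (clustered, beta < 0), which carries the diversity
        # signal into abundance-weighted orders q > 0
        k = len(chosen)
        chosen_arr = np.asarray(chosen)
        centroid = zt[chosen_arr].mean(axis=0)
        ext_trait = np.linalg.norm(zt[chosen_arr] - centroid, axis=1) / (trait_scale or 1.0)
        ext_phylo = pd_arr[np.ix_(chosen_arr, chosen_arr)].mean(axis=1) / phylo_scale
        score = beta_f * ext_trait + beta_p * ext_phylo + rng.gumbel(size=k)
        ranks = np.empty(k, dtype=float)
        ranks[np.argsort(-score)] = np.arange(k)
        p_rel = config.dominance_evenness ** ranks
        p_rel /= p_rel.sum()
        total = rng.uniform(*config.total_coverage_range)
        for sp_idx, frac in zip(chosen, p_rel):
            records.append(
                (plot_ids[p], species[sp_idx], coverage_to_class(frac * total))
            )

    cover_classes = pd.DataFrame(
        records, columns=["plot_id", "species_id", "coverage_class"]
    )
    plots = pd.DataFrame(
        {
            "x": coords_x,
            "y": coords_y,
            "geo_precision": 5.0,
            "complete": True,
        },
        index=pd.Index(plot_ids, name="plot_id"),
    )

    habitat = pd.DataFrame(
        {
            "forest_typical": optima > 0.55,
            "grassland_typical": optima < 0.45,
        },
        index=pd.Index(species, name="species_id"),
    )
    habitat["forest_occasional"] = ~habitat["forest_typical"] & (optima > 0.3)
    habitat["grassland_occasional"] = ~habitat["grassland_typical"] & (optima < 0.7)
    # every species carries at least one flag
    none = ~habitat.any(axis=1)
    habitat.loc[none, ["forest_occasional", "grassland_occasional"]] = True

    truth = GroundTruth(
        shapes={
            "richness": shapes.richness,
            "trait_diversity": shapes.trait_diversity,
            "phylo_diversity": shapes.phylo_diversity,
        },
        productivity=pd.Series(lo + t_plot * (hi - lo), index=plots.index, name="ndvi"),
        land_use=pd.Series(
            rng.choice(["low", "medium", "high"], size=n_plots),
            index=plots.index,
            name="land_use",
        ),
        habitat_flags=habitat,
        niche_optima=pd.Series(optima, index=habitat.index, name="niche_optimum"),
    )
    return cover_classes, plots, truth


# ---------------------------------------------------------------------------
# NDVI time series
# ---------------------------------------------------------------------------

def gen_ndvi_series(
    plot_means: pd.Series,
    ndvi_spec: NDVISpec,
    land_use_classes: pd.Series | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[object, NDVISeries]:
    """Irregular multi-year NDVI series for each plot.

    value = plot mean + seasonal sinusoid (peaking mid growing season)
    + per-year offset + land-use disturbance (negative deflections on a
    random subset of growing-season acquisitions, magnitude set by the
    plot's land-use class) + Gaussian noise.  Acquisitions follow a
    16-day revisit cycle with day-level jitter and random gaps; a
    configurable fraction of records is flagged bad quality.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    means = plot_means.astype(float)
    if ((means <= -1) | (means >= 1)).any():
        raise ValueError("plot mean NDVI levels must lie within (-1, 1)")
    spec = ndvi_spec
    start, end = spec.season
    peak = 0.5 * (start + end)
    out: dict[object, NDVISeries] = {}
    for plot_id, mean in means.items():
        dates: list[pd.Timestamp] = []
        for year in range(spec.year_start, spec.year_end + 1):
            days = np.arange(1, 366, spec.revisit_days, dtype=float)
            days = days + rng.uniform(-3, 3, size=days.size)
            days = days[(days >= 1) & (days <= 365)]
            keep = rng.uniform(size=days.size) >= spec.gap_fraction
            for d in days[keep]:
                dates.append(pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(days=float(d) - 1))
        dates_arr = pd.DatetimeIndex(sorted(dates))
        doy = np.minimum(dates_arr.dayofyear.to_numpy(dtype=float), 365.0)
        years = dates_arr.year.to_numpy()
        year_levels = np.arange(spec.year_start, spec.year_end + 1)
        offsets = dict(zip(year_levels, rng.normal(0.0, spec.year_offset_sd, year_levels.size)))
        seasonal = spec.seasonal_amplitude * np.cos(2 * np.pi * (doy - peak) / 365.0)
        values = mean + seasonal + np.array([offsets[y] for y in years])
        if land_use_classes is not None and plot_id in land_use_classes.index:
            mag = spec.disturbance_magnitude.get(str(land_use_classes.loc[plot_id]), 0.0)
            if mag > 0:
                in_season = (doy >= start) & (doy <= end)
                hit = in_season & (rng.uniform(size=doy.size) < spec.disturbance_prob)
                values = values - hit * mag * rng.uniform(0.5, 1.5, size=doy.size)
        if spec.residual_sd > 0:
            values = values + rng.normal(0.0, spec.residual_sd, size=doy.size)
        quality = np.where(
            rng.uniform(size=doy.size) < spec.bad_quality_fraction, "bad", "clear"
        )
        out[plot_id] = NDVISeries(
            plot_id=plot_id,
            data=pd.DataFrame({"date": dates_arr, "ndvi": values, "quality": quality}),
            season=spec.season,
        )
    return out


# ---------------------------------------------------------------------------
# scenario serialization
# ---------------------------------------------------------------------------

def _config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["trait_spec"] = {k: dataclasses.asdict(v) for k, v in config.trait_spec.items()}
    return d


def config_from_dict(d: Mapping) -> ScenarioConfig:
    d = dict(d)
    if "trait_spec" in d:
        d["trait_spec"] = {k: TraitSpec(**v) for k, v in d["trait_spec"].items()}
    if "shape_spec" in d:
        d["shape_spec"] = ShapeSpec(**d["shape_spec"])
    if "ndvi_spec" in d:
        nd = dict(d["ndvi_spec"])
        for key in ("ndvi_range", "season"):
            if key in nd:
                nd[key] = tuple(nd[key])
        d["ndvi_spec"] = NDVISpec(**nd)
    for key in ("total_coverage_range",):
        if key in d:
            d[key] = tuple(d[key])
    return ScenarioConfig(**d)


@dataclass
class ScenarioData:
    """In-memory bundle of one generated scenario."""

    config: ScenarioConfig
    genus_tree: dendropy.Tree
    species_tree: dendropy.Tree
    species_to_genus: dict[str, str]
    traits: pd.DataFrame
    cover_classes: pd.DataFrame
    plots: pd.DataFrame
    truth: GroundTruth
    ndvi_series: dict[object, NDVISeries] | None = None


def generate_scenario(config: ScenarioConfig, with_ndvi: bool = True) -> ScenarioData:
    """Generate every input the pipeline consumes from one config + seed."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=5)
    genus_tree = gen_genus_phylogeny(config.n_genera, seed=int(seeds[0]))
    counts = species_per_genus(config.n_genera, config.species_per_genus_mean, int(seeds[1]))
    sp2gen = species_names(counts)
    species_tree = expand_genus_tree(genus_tree, sp2gen, seed=int(seeds[2]))
    traits = gen_traits(sorted(sp2gen), species_tree, config.trait_spec, int(seeds[3]))
    cover, plots, truth = gen_communities(config, traits, species_tree)
    series = None
    if with_ndvi:
        series = gen_ndvi_series(
            truth.productivity, config.ndvi_spec, truth.land_use, int(seeds[4])
        )
    return ScenarioData(
        config=config,
        genus_tree=genus_tree,
        species_tree=species_tree,
        species_to_genus=sp2gen,
        traits=traits,
        cover_classes=cover,
        plots=plots,
        truth=truth,
        ndvi_series=series,
    )


def write_scenario(outdir: str | Path, config: ScenarioConfig) -> dict[str, Path]:
    """Generate a full scenario and write it as plain-text files.

    Writes communities.csv (long, class-coded), plots.csv, traits.csv,
    genus_tree.nwk, species_tree.nwk, ndvi.csv, habitat_flags.csv,
    ground_truth.json and config.yaml; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_scenario(config, with_ndvi=True)
    genus_tree, species_tree = data.genus_tree, data.species_tree
    traits, cover, plots, truth = data.traits, data.cover_classes, data.plots, data.truth
    series = data.ndvi_series

    paths = {name: outdir / fname for name, fname in {
        "communities": "communities.csv",
        "plots": "plots.csv",
        "traits": "traits.csv",
        "genus_tree": "genus_tree.nwk",
        "species_tree": "species_tree.nwk",
        "ndvi": "ndvi.csv",
        "habitat_flags": "habitat_flags.csv",
        "ground_truth": "ground_truth.json",
        "config": "config.yaml",
    }.items()}
    cover.to_csv(paths["communities"], index=False)
    plots.to_csv(paths["plots"])
    traits.to_csv(paths["traits"])
    genus_tree.write(path=str(paths["genus_tree"]), schema="newick")
    species_tree.write(path=str(paths["species_tree"]), schema="newick")
    ndvi_rows = [
        {
            "plot_id": pid,
            "date": row.date.date().isoformat(),
            "ndvi": row.ndvi,
            "quality": row.quality,
        }
        for pid, s in series.items()
        for row in s.data.itertuples()
    ]
    pd.DataFrame(ndvi_rows).to_csv(paths["ndvi"], index=False)
    truth.habitat_flags.to_csv(paths["habitat_flags"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "shapes": truth.shapes,
                "productivity": truth.productivity.to_dict(),
                "land_use": truth.land_use.to_dict(),
                "season": list(config.ndvi_spec.season),
            },
            fh,
            indent=1,
        )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
    return paths
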