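"""Generators: Yule phylogenies, traits, communities, NDVI series, round trips."""

import dataclasses
import math

import dendropy
import numpy as np
import pandas as pd
import pytest
import yaml

import divspace as dv
from divspace.synthetic_data import (
    COVERAGE_CLASS_BOUNDS,
    coverage_to_class,
    shape_mean_function,
)
from divspace.trees import node_depths


def count_cherries(tree: dendropy.Tree) -> int:
    return sum(
        1
        for n in tree.preorder_internal_node_iter()
        if all(c.is_leaf() for c in n.child_nodes())
    )


def oracle_yule_cherries(n_tips: int, n_sims: int, rng) -> np.ndarray:
    """Independent ERM simulator: repeatedly split a uniformly chosen leaf."""
    out = np.empty(n_sims)
    for s in range(n_sims):
        children: dict[int, list[int]] = {}
        leaves = [0]
        next_id = 1
        while len(leaves) < n_tips:
            i = int(rng.integers(len(leaves)))
            node = leaves[i]
            kids = [next_id, next_id + 1]
            next_id += 2
            children[node] = kids
            leaves[i] = kids[0]
            leaves.append(kids[1])
        leafset = set(leaves)
        out[s] = sum(1 for kids in children.values() if set(kids) <= leafset)
    return out


class TestGenGenusPhylogeny:
    def test_two_genera_forced_topology(self):
        tree = dv.gen_genus_phylogeny(2, seed=0)
        depths = node_depths(tree)
        tips = [depths[l] for l in tree.leaf_node_iter()]
        assert tips == pytest.approx([1.0, 1.0])
        assert len(tree.seed_node.child_nodes()) == 2

    def test_seeded_determinism(self):
        t1 = dv.gen_genus_phylogeny(50, seed=9)
        t2 = dv.gen_genus_phylogeny(50, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_cherry_count_matches_independent_yule_simulation(self):
        rng = np.random.default_rng(2024)
        oracle = oracle_yule_cherries(100, 10_000, rng)
        ours = np.array(
            [count_cherries(dv.gen_genus_phylogeny(100, seed=s)) for s in range(300)]
        )
        se = math.sqrt(oracle.var() / len(oracle) + ours.var() / len(ours))
        assert abs(ours.mean() - oracle.mean()) < 3 * se

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            dv.gen_genus_phylogeny(1, seed=0)
        with pytest.raises(ValueError):
            dv.gen_genus_phylogeny(5, birth_rate=0.0, seed=0)


class TestGenTraits:
    def test_degenerate_scale_collapses_to_location(self, small_species_tree):
        tree, sp2g = small_species_tree
        traits = dv.gen_traits(
            sorted(sp2g), tree, {"SLA": dv.TraitSpec(2.0, 0.0)}, seed=1
        )
        np.testing.assert_allclose(traits["SLA"], math.exp(2.0))

    def test_byte_identical_under_fixed_seed(self, small_species_tree):
        tree, sp2g = small_species_tree
        spec = {"SLA": dv.TraitSpec(2.0, 0.5, True), "HGT": dv.TraitSpec(1.0, 0.8)}
        t1 = dv.gen_traits(sorted(sp2g), tree, spec, seed=4)
        t2 = dv.gen_traits(sorted(sp2g), tree, spec, seed=4)
        assert t1.to_csv() == t2.to_csv()

    def test_phylogenetic_signal_exceeds_tip_shuffled_control(self, small_species_tree):
        tree, sp2g = small_species_tree
        species = sorted(sp2g)
        d = dv.tree_to_distance(tree).loc[species, species].to_numpy()
        tril = np.tril_indices(len(species), k=-1)
        rng = np.random.default_rng(77)
        wins = 0
        for seed in range(100):
            traits = dv.gen_traits(
                species, tree, {"SLA": dv.TraitSpec(1.0, 0.8, True)}, seed=seed
            )
            x = np.log(traits["SLA"].to_numpy())
            def stat(v):
                diff = np.abs(v[:, None] - v[None, :])[tril]
                return np.corrcoef(diff, d[tril])[0, 1]
            if stat(x) > stat(rng.permutation(x)):
                wins += 1
        assert wins >= 95

    def test_negative_scale_raises(self, small_species_tree):
        tree, sp2g = small_species_tree
        with pytest.raises(ValueError):
            dv.gen_traits(sorted(sp2g), tree, {"SLA": dv.TraitSpec(1.0, -0.1)}, seed=0)


def small_config(**kw):
    # 6 bins at the default per-bin plot density (50 plots per bin) and the
    # default species-pool size, so amplitudes keep their species units
    defaults = dict(n_plots=300, n_bins_target=6, seed=0)
    defaults.update(kw)
    return dv.ScenarioConfig(**defaults)


def per_bin_richness(cfg, traits, tree):
    cover, plots, truth = dv.gen_communities(cfg, traits, tree)
    rich = cover.groupby("plot_id")["species_id"].nunique()
    t = (truth.productivity - truth.productivity.min()) / (
        truth.productivity.max() - truth.productivity.min()
    )
    bins = np.minimum((t * cfg.n_bins_target).astype(int), cfg.n_bins_target - 1)
    return rich.groupby(bins.reindex(rich.index)).mean()


@pytest.fixture(scope="module")
def shared_pool():
    cfg = small_config()
    data = dv.generate_scenario(cfg, with_ndvi=False)
    return data.traits, data.species_tree


class TestGenCommunities:
    def test_flat_shapes_give_statistically_flat_richness(self, shared_pool):
        traits, tree = shared_pool
        flat = dv.ShapeSpec("flat", "flat", "flat")
        means = []
        for seed in range(60):
            cfg = small_config(shape_spec=flat, seed=seed)
            means.append(per_bin_richness(cfg, traits, tree))
        m = pd.concat(means, axis=1)
        bin_means = m.mean(axis=1)
        se = m.std(axis=1) / math.sqrt(m.shape[1])
        z = (bin_means - bin_means.mean()) / se
        assert float((z**2).mean()) < 4.0  # bins indistinguishable from flat

    def test_concave_richness_has_interior_maximum(self, shared_pool):
        traits, tree = shared_pool
        hits = 0
        for seed in range(100):
            cfg = small_config(seed=seed)  # default shape: concave- richness
            prof = per_bin_richness(cfg, traits, tree)
            if 0 < int(np.argmax(prof.to_numpy())) < len(prof) - 1:
                hits += 1
        assert hits >= 95

    def test_zero_plots_empty_no_error(self, shared_pool):
        traits, tree = shared_pool
        cover, plots, truth = dv.gen_communities(
            small_config(n_plots=0), traits, tree
        )
        assert len(cover) == 0 and len(plots) == 0

    def test_contradictory_shape_spec_rejected(self):
        with pytest.raises(ValueError):
            dv.ShapeSpec(richness=("increasing", "decreasing"))
        with pytest.raises(ValueError):
            dv.ShapeSpec(richness="sideways")

    def test_every_species_has_a_habitat_flag(self, shared_pool):
        traits, tree = shared_pool
        _, _, truth = dv.gen_communities(small_config(seed=3), traits, tree)
        assert truth.habitat_flags.any(axis=1).all()

    def test_seeded_determinism(self, shared_pool):
        traits, tree = shared_pool
        c1, _, _ = dv.gen_communities(small_config(seed=5), traits, tree)
        c2, _, _ = dv.gen_communities(small_config(seed=5), traits, tree)
        pd.testing.assert_frame_equal(c1, c2)


class TestShapeMeanFunction:
    def test_defining_inequalities(self):
        t = np.linspace(0, 1, 101)
        inc = shape_mean_function("increasing", t, 10, 5)
        assert (np.diff(inc) > 0).all()
        dec = shape_mean_function("decreasing", t, 10, 5)
        assert (np.diff(dec) < 0).all()
        con = shape_mean_function("concave-", t, 10, 5)
        peak = int(np.argmax(con))
        assert 0 < peak < len(t) - 1 and con[peak] == pytest.approx(15.0)
        assert (shape_mean_function("flat", t, 10, 5) == 10).all()


class TestCoverageClasses:
    def test_midpoints_round_trip_within_bounds(self):
        for code, midpoint in dv.DEFAULT_COVERAGE_MIDPOINTS.items():
            assert coverage_to_class(midpoint) == code
            assert COVERAGE_CLASS_BOUNDS[code - 1] < midpoint <= COVERAGE_CLASS_BOUNDS[code]

    def test_clipping_and_errors(self):
        assert coverage_to_class(120.0) == 6
        with pytest.raises(ValueError):
            coverage_to_class(0.0)


class TestGenNdviSeries:
    def test_degenerate_spec_constant(self):
        spec = dv.NDVISpec(seasonal_amplitude=0, year_offset_sd=0, residual_sd=0,
                           bad_quality_fraction=0)
        out = dv.gen_ndvi_series(pd.Series({"p1": 0.2}), spec, None, seed=0)
        np.testing.assert_allclose(out["p1"].data["ndvi"], 0.2)

    def test_disturbance_residuals_rank_with_magnitude(self):
        # noiseless, flat-season series: the residual from the plot mean is
        # exactly the injected land-use deflection
        mags = {f"c{i:02d}": m for i, m in enumerate(np.linspace(0.005, 0.15, 20))}
        spec = dv.NDVISpec(seasonal_amplitude=0, year_offset_sd=0, residual_sd=0,
                           bad_quality_fraction=0, disturbance_magnitude=mags)
        plots = pd.Series(0.2, index=[f"p{i:02d}" for i in range(20)])
        classes = pd.Series(list(mags), index=plots.index)
        out = dv.gen_ndvi_series(plots, spec, classes, seed=1)
        realized = []
        for pid in plots.index:
            df = out[pid].data
            doy = np.minimum(pd.to_datetime(df["date"]).dt.dayofyear, 365)
            season = (doy >= spec.season[0]) & (doy <= spec.season[1])
            realized.append(np.abs(df.loc[season, "ndvi"] - 0.2).mean())
        from scipy.stats import spearmanr

        rho = spearmanr(realized, [mags[c] for c in classes]).statistic
        assert rho >= 0.9

    def test_bad_quality_fraction(self):
        spec = dv.NDVISpec(bad_quality_fraction=0.3)
        out = dv.gen_ndvi_series(pd.Series({"p1": 0.1}), spec, None, seed=2)
        frac = (out["p1"].data["quality"] == "bad").mean()
        n = len(out["p1"].data)
        assert abs(frac - 0.3) < 3 * math.sqrt(0.3 * 0.7 / n)

    def test_out_of_range_mean_rejected(self):
        with pytest.raises(ValueError):
            dv.gen_ndvi_series(pd.Series({"p1": 1.5}), dv.NDVISpec(), None, seed=0)


class TestScenarioIO:
    def test_write_scenario_round_trip(self, tmp_path):
        cfg = small_config(n_plots=20)
        paths = dv.write_scenario(tmp_path, cfg)
        assert all(p.exists() for p in paths.values())
        loaded = dv.config_from_dict(yaml.safe_load(paths["config"].read_text()))
        assert loaded == cfg
        comm = pd.read_csv(paths["communities"])
        assert set(comm.columns) == {"plot_id", "species_id", "coverage_class"}
        assert comm["coverage_class"].between(1, 6).all()
        tree = dendropy.Tree.get(path=str(paths["species_tree"]), schema="newick")
        assert set(comm["species_id"]) <= {l.taxon.label for l in tree.leaf_node_iter()}
        ndvi = pd.read_csv(paths["ndvi"])
        assert set(ndvi["quality"]) <= {"clear", "bad"}
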