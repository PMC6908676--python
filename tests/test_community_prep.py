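"""Coverage conversion, quality filtering, ecosystem typing, binning, bootstraps."""

import numpy as np
import pandas as pd
import pytest

import divspace as dv


def plots_frame(ids, **overrides):
    base = {
        "x": np.arange(len(ids)) * 6000.0,
        "y": 0.0,
        "geo_precision": 5.0,
        "complete": True,
    }
    base.update(overrides)
    return pd.DataFrame(base, index=pd.Index(ids, name="plot_id"))


def long_cover(plot_id, coverages, prefix="s"):
    return pd.DataFrame(
        {
            "plot_id": plot_id,
            "species_id": [f"{prefix}{i}" for i in range(len(coverages))],
            "coverage": coverages,
        }
    )


class TestConvertCoverage:
    def test_default_map_and_totals(self):
        classes = pd.DataFrame(
            {"plot_id": ["p1"] * 3, "species_id": ["s1", "s2", "s3"],
             "coverage_class": [3, 4, 5]}
        )
        table = dv.convert_coverage(classes, plots_frame(["p1"]))
        assert table.plots.loc["p1", "total_coverage"] == pytest.approx(15 + 37.5 + 62.5)

    def test_unknown_code_raises(self):
        classes = pd.DataFrame(
            {"plot_id": ["p1"], "species_id": ["s1"], "coverage_class": [9]}
        )
        with pytest.raises(ValueError, match="9"):
            dv.convert_coverage(classes, plots_frame(["p1"]))

    def test_identity_map_round_trip(self):
        classes = pd.DataFrame(
            {"plot_id": ["p1"] * 2, "species_id": ["s1", "s2"], "coverage_class": [7, 8]}
        )
        table = dv.convert_coverage(classes, plots_frame(["p1"]), {7: 7.0, 8: 8.0})
        assert sorted(table.cover["coverage"]) == [7.0, 8.0]


def eight_plot_fixture():
    """Six plots each violating exactly one quality criterion, two clean."""
    ids = [f"p{i}" for i in range(1, 9)]
    plots = plots_frame(ids)
    plots.loc["p1", "complete"] = False  # criterion 1: incomplete sampling
    plots.loc["p3", "geo_precision"] = 25.0  # criterion 2
    cover = []
    for pid in ids:
        if pid == "p2":  # criterion 1: only 5 species
            cover.append(long_cover(pid, [10.0] * 5))
        elif pid == "p4":  # criterion 3: total 20 <= 30
            cover.append(long_cover(pid, [2.0] * 10))
        elif pid == "p5":  # criterion 3: total 300 >= 250
            cover.append(long_cover(pid, [30.0] * 10))
        elif pid == "p6":  # criterion 4: half the coverage from traitless species
            cover.append(long_cover(pid, [5.0] * 10, prefix="u"))
            cover.append(long_cover(pid, [5.0] * 10))
        else:
            cover.append(long_cover(pid, [8.0] * 10))
    table = dv.CommunityTable(cover=pd.concat(cover, ignore_index=True), plots=plots)
    traits = pd.DataFrame(
        {"SLA": 1.0}, index=pd.Index([f"s{i}" for i in range(10)], name="species_id")
    )
    return table, traits


class TestQualityFilter:
    def test_fixture_survivors_and_audit(self):
        table, traits = eight_plot_fixture()
        out, audit = dv.quality_filter(table, traits)
        assert sorted(out.plots.index) == ["p7", "p8"]
        failures = {e["plot_id"]: e.get("failed") for e in audit if not e["passed"]}
        assert failures == {
            "p1": "sampling", "p2": "sampling", "p3": "geo_precision",
            "p4": "total_coverage", "p5": "total_coverage", "p6": "trait_coverage",
        }

    def test_boundaries(self):
        # exactly 10 species is retained; trait coverage just below 0.8 is dropped
        ids = ["a", "b"]
        plots = plots_frame(ids)
        cover = pd.concat(
            [
                long_cover("a", [8.0] * 10),
                long_cover("b", [7.9] * 10),  # 79 with traits...
                long_cover("b", [2.1] * 10, prefix="u"),  # ...21 without
            ],
            ignore_index=True,
        )
        traits = pd.DataFrame(
            {"SLA": 1.0}, index=pd.Index([f"s{i}" for i in range(10)], name="species_id")
        )
        out, audit = dv.quality_filter(dv.CommunityTable(cover, plots), traits)
        assert list(out.plots.index) == ["a"]
        assert {e["plot_id"]: e.get("failed") for e in audit}["b"] == "trait_coverage"

    def test_idempotent(self):
        table, traits = eight_plot_fixture()
        once, _ = dv.quality_filter(table, traits)
        twice, _ = dv.quality_filter(once, traits)
        assert list(once.plots.index) == list(twice.plots.index)
        pd.testing.assert_frame_equal(once.cover, twice.cover)


class TestAssignEcosystem:
    def _table(self, coverages_by_species):
        cover = pd.DataFrame(
            {
                "plot_id": "p1",
                "species_id": list(coverages_by_species),
                "coverage": list(coverages_by_species.values()),
            }
        )
        return dv.CommunityTable(cover, plots_frame(["p1"]))

    def _flags(self):
        return pd.DataFrame(
            {
                "forest_typical": [True, False, False],
                "grassland_typical": [False, True, False],
            },
            index=pd.Index(["f", "g", "n"], name="species_id"),
        )

    def test_pure_forest(self):
        labels = dv.assign_ecosystem(self._table({"f": 80.0}), self._flags())
        assert labels.loc["p1"] == "forest"

    def test_tie_is_other(self):
        labels = dv.assign_ecosystem(self._table({"f": 40.0, "g": 40.0}), self._flags())
        assert labels.loc["p1"] == "other"

    def test_default_thresholds(self):
        labels = dv.assign_ecosystem(
            self._table({"f": 60.0, "g": 20.0, "n": 20.0}), self._flags()
        )
        assert labels.loc["p1"] == "forest"

    def test_missing_flags_raise(self):
        with pytest.raises(ValueError):
            dv.assign_ecosystem(self._table({"x": 50.0}), self._flags())


class TestBinPlots:
    def test_default_edges_and_boundaries(self):
        out = dv.bin_plots(pd.Series([0.01, 0.02, 0.40, -0.04, 0.32]))
        assert out["bin"].tolist() == [2, 3, -1, 0, 17]
        assert out["out_of_range"].tolist() == [False, False, True, False, False]

    def test_quantile_edges(self, rng):
        ndvi = pd.Series(rng.uniform(0, 0.3, 500))
        edges = dv.quantile_bin_edges(ndvi, step=0.05)
        out = dv.bin_plots(ndvi, edges)
        counts = out.groupby("bin").size()
        assert counts.max() - counts.min() <= 2  # near-equal occupancy


class TestLandUseTertiles:
    def test_thirds_and_ties(self):
        labels = dv.land_use_tertiles(pd.Series(range(1, 10), index=list("abcdefghi")))
        assert labels.tolist() == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3
        equal = dv.land_use_tertiles(pd.Series([2.0, 2.0, 2.0]))
        assert equal.tolist() == ["low"] * 3

    def test_order_invariance_and_minimum(self):
        s = pd.Series([5.0, 1.0, 3.0, 9.0, 7.0], index=list("abcde"))
        l1 = dv.land_use_tertiles(s)
        l2 = dv.land_use_tertiles(s.sample(frac=1, random_state=1))
        assert l1.sort_index().equals(l2.sort_index())
        with pytest.raises(ValueError):
            dv.land_use_tertiles(pd.Series([1.0, 2.0]))


class TestBootstrapBins:
    def _assignments(self, ids):
        return pd.DataFrame(
            {"ndvi": 0.1, "bin": 5, "out_of_range": False},
            index=pd.Index(ids, name="plot_id"),
        )

    def test_full_grid_feasible(self):
        ids = [f"p{i}" for i in range(40)]
        coords = pd.DataFrame(
            {"x": [6000.0 * (i % 7) for i in range(40)],
             "y": [6000.0 * (i // 7) for i in range(40)]},
            index=ids,
        )
        samples, dropped = dv.bootstrap_bins(
            self._assignments(ids), coords, n_reps=5, sample_size=40, seed=0
        )
        assert dropped == []
        for rep in samples[5]:
            assert sorted(rep) == sorted(ids)  # the full set is the only subset
            xy = coords.loc[rep].to_numpy()
            d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
            assert (d[~np.eye(len(rep), dtype=bool)] >= 5000).all()

    def test_infeasible_bin_dropped(self):
        ids = [f"p{i}" for i in range(40)]
        coords = pd.DataFrame(
            {"x": np.linspace(0, 900, 40), "y": 0.0}, index=ids
        )  # all within 1 km
        samples, dropped = dv.bootstrap_bins(
            self._assignments(ids), coords, n_reps=2, sample_size=2, seed=0,
            retry_budget=50,
        )
        assert dropped == [5] and samples == {}

    def test_seeded_determinism(self):
        ids = [f"p{i}" for i in range(30)]
        coords = pd.DataFrame(
            {"x": [7000.0 * (i % 6) for i in range(30)],
             "y": [7000.0 * (i // 6) for i in range(30)]},
            index=ids,
        )
        s1, _ = dv.bootstrap_bins(self._assignments(ids), coords, n_reps=3,
                                  sample_size=10, seed=42)
        s2, _ = dv.bootstrap_bins(self._assignments(ids), coords, n_reps=3,
                                  sample_size=10, seed=42)
        assert s1 == s2
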