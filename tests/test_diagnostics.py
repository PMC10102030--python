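import numpy as np
import pandas as pd
import pytest

from etcfit.diagnostics import (DendrogramResult, aggregate_fva,
                                fva_midpoint_range, pca_ordination, run_fva,
                                select_fva_particles, single_linkage_tree)
from etcfit.history import Individual, RunHistory
from etcfit.particles import FitnessBreakdown


def _fb(f):
    return FitnessBreakdown(components={"f": f}, overall=f)


def make_history(fitnesses):
    records = [Individual(f"p{i}", 0, np.array([float(i), 0.0]), _fb(f))
               for i, f in enumerate(fitnesses)]
    return RunHistory(param_names=["x", "y"], records=records,
                      populations=[[r.particle_id for r in records]])


class TestSelection:
    def test_filters_by_threshold(self):
        hist = make_history([0.1, 0.95, 0.99, 0.5])
        sel = select_fva_particles(hist, 0.9, 10, np.random.default_rng(0))
        assert sorted(p.particle_id for p in sel) == ["p1", "p2"]

    def test_samples_without_replacement(self):
        hist = make_history([0.95] * 20)
        sel = select_fva_particles(hist, 0.9, 5, np.random.default_rng(1))
        ids = [p.particle_id for p in sel]
        assert len(ids) == 5 and len(set(ids)) == 5

    def test_no_qualifying_particle_raises(self):
        hist = make_history([0.1, 0.2])
        with pytest.raises(ValueError):
            select_fva_particles(hist, 0.9, 5, np.random.default_rng(0))


class TestMidpointRange:
    @pytest.mark.parametrize("lo,hi,mid,rng", [
        (2.0, 4.0, 3.0, 2.0),
        (7.0, 7.0, 7.0, 0.0),
        (-1.0, 5.0, 2.0, 6.0),
        (0.0, 10.0, 5.0, 10.0),
    ])
    def test_arithmetic(self, lo, hi, mid, rng):
        assert fva_midpoint_range(lo, hi) == (mid, rng)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fva_midpoint_range(np.nan, 1.0)
        with pytest.raises(ValueError):
            fva_midpoint_range(0.0, np.inf)


class TestRunAndAggregate:
    def test_fva_rows_and_aggregate_match_bruteforce(self, noise_free_bundle):
        nf = noise_free_bundle
        # run on the ground truth twice under two ids to exercise grouping
        import dataclasses
        particles = [dataclasses.replace(nf["truth"], particle_id="a"),
                     dataclasses.replace(nf["truth"], particle_id="b")]
        small = [nf["datasets"][0]]
        rows = run_fva(nf["model"], particles, small, nf["evaluator"],
                       simulation_id="sim")
        assert not rows.empty
        assert set(rows["particle_id"]) == {"a", "b"}
        # midpoint/range columns satisfy their definitions row by row
        np.testing.assert_allclose(
            rows["midpoint"], (rows["flux_min"] + rows["flux_max"]) / 2)
        np.testing.assert_allclose(
            rows["range"], (rows["flux_max"] - rows["flux_min"]).abs())

        agg = aggregate_fva(rows)
        # brute-force recompute one group
        key = agg.iloc[0]
        grp = rows[(rows["dataset"] == key["dataset"])
                   & (rows["temperature_C"] == key["temperature_C"])
                   & (rows["reaction_id"] == key["reaction_id"])]
        assert key["midpoint_mean"] == pytest.approx(grp["midpoint"].mean())
        assert key["range_max"] == pytest.approx(grp["range"].max())
        assert key["n_particles"] == 2

    def test_chemostat_datasets_skipped(self, noise_free_bundle):
        nf = noise_free_bundle
        rows = run_fva(nf["model"], [nf["truth"]], [nf["datasets"][2]],
                       nf["evaluator"])
        assert rows.empty


def line_individuals(n=10):
    # points on a line in 5-D: one direction carries all the variance
    rng = np.random.default_rng(0)
    t = rng.normal(size=n)
    direction = np.array([1.0, -2.0, 0.5, 3.0, 1.0])
    return [Individual(f"p{i}", 0, ti * direction, _fb(0.5))
            for i, ti in enumerate(t)]


class TestOrdination:
    names5 = [f"v{i}" for i in range(5)]

    def test_line_explained_by_first_component(self):
        ord_ = pca_ordination(line_individuals(), self.names5)
        assert ord_.explained_variance_ratio[0] >= 0.999

    def test_evr_properties(self):
        rng = np.random.default_rng(2)
        inds = [Individual(f"p{i}", 0, rng.normal(size=4), _fb(0.5))
                for i in range(12)]
        ord_ = pca_ordination(inds, ["a", "b", "c", "d"])
        evr = ord_.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9
        assert np.all(evr >= 0)

    def test_distances_preserved_with_full_rank(self):
        rng = np.random.default_rng(3)
        inds = [Individual(f"p{i}", 0, rng.normal(size=3), _fb(0.5))
                for i in range(8)]
        ord_ = pca_ordination(inds, ["a", "b", "c"])
        coords = ord_.coordinates[["PC1", "PC2", "PC3"]].to_numpy()
        matrix = np.stack([i.values for i in inds])
        z = (matrix - matrix.mean(0)) / matrix.std(0, ddof=0)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(coords), pdist(z), atol=1e-8)

    def test_constant_column_dropped_with_warning(self):
        inds = [Individual(f"p{i}", 0, np.array([float(i), 7.0]), _fb(0.5))
                for i in range(5)]
        with pytest.warns(UserWarning, match="constant"):
            ord_ = pca_ordination(inds, ["x", "const"])
        assert ord_.columns == ["x"]

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError):
            pca_ordination(line_individuals(2), self.names5)


class TestDendrogram:
    def test_two_tight_pairs_merge_first(self):
        vals = [np.array([0.0, 0.0]), np.array([0.1, 0.0]),
                np.array([10.0, 0.0]), np.array([10.1, 0.0]),
                np.array([5.0, 8.0])]
        inds = [Individual(f"p{i}", 0, v, _fb(0.5))
                for i, v in enumerate(vals)]
        res = single_linkage_tree(inds, ["x", "y"])
        assert isinstance(res, DendrogramResult)
        # the two smallest merge heights join the tight pairs
        first_two = set()
        for row in res.merges[:2]:
            first_two.add(frozenset(int(i) for i in row[:2]))
        assert frozenset({0, 1}) in first_two
        assert frozenset({2, 3}) in first_two

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(1)
        inds = [Individual(f"p{i}", 0, rng.normal(size=3), _fb(0.5))
                for i in range(15)]
        res = single_linkage_tree(inds, ["a", "b", "c"])
        assert np.all(np.diff(res.heights) >= -1e-12)

    def test_three_points_on_line_hand_heights(self):
        # standardized x-coordinates of (0, 1, 3): mean 4/3, std sqrt(14/9)
        vals = [np.array([0.0]), np.array([1.0]), np.array([3.0])]
        inds = [Individual(f"p{i}", 0, v, _fb(0.5))
                for i, v in enumerate(vals)]
        std = np.std([0.0, 1.0, 3.0])
        res = single_linkage_tree(inds, ["x"])
        np.testing.assert_allclose(res.heights, [1.0 / std, 2.0 / std])

    def test_input_order_invariance(self):
        rng = np.random.default_rng(4)
        inds = [Individual(f"p{i}", 0, rng.normal(size=2), _fb(0.5))
                for i in range(8)]
        res1 = single_linkage_tree(inds, ["a", "b"])
        res2 = single_linkage_tree(list(reversed(inds)), ["a", "b"])
        np.testing.assert_array_equal(res1.merges, res2.merges)
        assert res1.leaf_ids == res2.leaf_ids

    def test_simulation_labels_follow_leaves(self):
        inds = [Individual(f"p{i}", 0, np.array([float(i)]), _fb(0.5))
                for i in (2, 0, 1)]
        res = single_linkage_tree(inds, ["x"], simulation_ids=["s2", "s0", "s1"])
        assert res.leaf_ids == ["p0", "p1", "p2"]
        assert res.leaf_simulations == ["s0", "s1", "s2"]
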