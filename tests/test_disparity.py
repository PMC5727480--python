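"""Binned disparity, ghost-lineage imputation, clade center of gravity,
diet tables and hull geometry."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dispartime.datamodel import Phylogeny, TaxonRecord, TimeBin, TimeBinSet
from dispartime.disparity import (
    assign_bins,
    bootstrap_disparity,
    cgs,
    cgs_significance,
    convex_hull_areas,
    diet_counts,
    estimate_ancestral_states,
    ghost_lineage_scores,
    phylogenetic_diversity,
    sum_of_ranges,
    sum_of_variances,
)
from dispartime.ordination import OrdinationResult
from dispartime.stages import make_bins


def scores_of(taxa, arr):
    arr = np.asarray(arr, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return OrdinationResult(
        taxa=list(taxa),
        scores=arr,
        axis_variances=arr.var(axis=0, ddof=1) if len(taxa) > 1 else np.ones(arr.shape[1]),
        method="PCA",
    )


class TestAssignBins:
    KUNGURIAN = TimeBin("Kungurian", 283.5, 273.01)

    def test_overlapping_range_is_member(self):
        bins = TimeBinSet([self.KUNGURIAN])
        out = assign_bins([TaxonRecord("x", 285.0, 280.0)], bins)
        assert out.members["Kungurian"] == {"x"}

    def test_disjoint_range_is_not_member(self):
        bins = TimeBinSet([self.KUNGURIAN])
        out = assign_bins([TaxonRecord("x", 300.0, 295.0)], bins)
        assert out.members["Kungurian"] == set()
        assert out.excluded == ["x"]

    def test_range_through_taxon_joins_every_spanned_bin(self):
        bins = make_bins("five")
        out = assign_bins([TaxonRecord("x", 292.0, 260.0)], bins)
        spanned = [b for b, m in out.members.items() if m]
        assert spanned == ["Asselian-Sakmarian", "Artinskian", "Kungurian", "Guadalupian"]


class TestMetrics:
    def test_sum_of_variances_hand_value(self):
        s = scores_of(list("abc"), [0.0, 2.0, 4.0])
        assert sum_of_variances(s, {"a", "b", "c"}, axes=1) == pytest.approx(4.0)

    def test_identical_taxa_have_zero_variance(self):
        s = scores_of(["a", "b"], [1.5, 1.5])
        assert sum_of_variances(s, {"a", "b"}, axes=1) == 0.0

    def test_variance_additive_over_axes(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(6, 2))
        s = scores_of([f"t{i}" for i in range(6)], arr)
        both = sum_of_variances(s, set(s.taxa), axes=[0, 1])
        assert both == pytest.approx(
            sum_of_variances(s, set(s.taxa), axes=[0])
            + sum_of_variances(s, set(s.taxa), axes=[1])
        )

    def test_singleton_bin_variance_undefined_range_zero(self):
        s = scores_of(["a"], [3.0])
        assert np.isnan(sum_of_variances(s, {"a"}, axes=1))
        assert sum_of_ranges(s, {"a"}, axes=1) == 0.0

    def test_sum_of_ranges_hand_value_and_monotonicity(self):
        s = scores_of(list("abcd"), [0.0, 2.0, 4.0, 1.0])
        assert sum_of_ranges(s, {"a", "b", "c"}, axes=1) == 4.0
        assert sum_of_ranges(s, {"a", "b", "c", "d"}, axes=1) >= sum_of_ranges(
            s, {"a", "b", "c"}, axes=1
        )


class TestBootstrap:
    def test_zero_variance_bin_gives_degenerate_ci(self):
        s = scores_of(list("abc"), [1.0, 1.0, 1.0])
        point, lo, hi = bootstrap_disparity(s, set("abc"), "sov", n_boot=200, seed=0, axes=1)
        assert (point, lo, hi) == (0.0, 0.0, 0.0)

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(3)
        s = scores_of([f"t{i}" for i in range(8)], rng.normal(size=8))
        a = bootstrap_disparity(s, set(s.taxa), "sov", n_boot=200, seed=11, axes=1)
        b = bootstrap_disparity(s, set(s.taxa), "sov", n_boot=200, seed=11, axes=1)
        assert a == b

    def test_percentile_interval_covers_point_estimate(self):
        """The 95% percentile interval should contain the sample statistic
        for the large majority of random fixtures."""
        rng = np.random.default_rng(19)
        hits = trials = 0
        for _ in range(400):
            arr = rng.normal(size=int(rng.integers(6, 12)))
            s = scores_of([f"t{i}" for i in range(len(arr))], arr)
            point, lo, hi = bootstrap_disparity(
                s, set(s.taxa), "sov", n_boot=100, seed=int(rng.integers(2**31)), axes=1
            )
            trials += 1
            hits += lo <= point <= hi
        assert hits / trials >= 0.93


class TestAncestralStates:
    def test_symmetric_two_tip_root(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        anc = estimate_ancestral_states(t, {"A": 0.0, "B": 2.0})
        assert list(anc.values())[0] == pytest.approx(1.0)

    def test_matches_quadratic_minimization_oracle(self):
        t = Phylogeny.from_newick("(((A:1,B:2):0.5,C:1.5):0.8,(D:0.7,E:1.1):1.2);")
        tv = {"A": 0.3, "B": -1.0, "C": 2.0, "D": 0.5, "E": -0.2}
        anc = estimate_ancestral_states(t, tv)
        nodes = [n for n in t.tree.preorder_node_iter() if not n.is_leaf()]

        def objective(x):
            vals = dict(zip(nodes, x))
            s = 0.0
            for n in t.tree.preorder_node_iter():
                if n.parent_node is None:
                    continue
                v = tv[n.taxon.label] if n.is_leaf() else vals[n]
                s += (v - vals[n.parent_node]) ** 2 / n.edge.length
            return s

        res = minimize(objective, np.zeros(len(nodes)), method="BFGS")
        for n, x in zip(nodes, res.x):
            assert anc[n] == pytest.approx(x, abs=1e-5)

    def test_unbiased_on_brownian_simulations(self):
        """BM ancestral estimates have ~zero mean error over replicates
        (known true node values recorded by the simulator)."""
        from dispartime.simulate import simulate_tree, simulate_continuous

        tree = simulate_tree(
            64, birth_rate=0.3, death_rate=0.0, origin_age=14.0, seed=5
        )
        tree.perturb_zero_branches()
        errors = []
        for rep in range(200):
            cont, true_log = simulate_continuous(tree, sigma2=1.0, n_chars=1, seed=rep)
            tipv = {t: np.log(cont.row(t))[0] for t in cont.taxa}
            anc = estimate_ancestral_states(tree, tipv)
            for node, est in anc.items():
                errors.append(est - true_log[node][0])
        errors = np.array(errors)
        se = errors.std() / np.sqrt(len(errors))
        assert abs(errors.mean()) < 3 * se + 0.05


def dated_three_tip():
    t = Phylogeny.from_newick("((A,B),C);")
    ages = {"A": 10.0, "B": 12.0, "C": 25.0}
    for leaf in t.tree.leaf_node_iter():
        leaf.age_ma = ages[leaf.taxon.label]
    inner = [n for n in t.tree.preorder_internal_node_iter()]
    for n in t.tree.postorder_internal_node_iter():
        n.age_ma = max(c.age_ma for c in n.child_nodes()) + 5.0
    return t


class TestGhostLineages:
    BINS = TimeBinSet(
        [TimeBin("old", 30.0, 20.0), TimeBin("mid", 20.0, 12.0), TimeBin("young", 12.0, 5.0)]
    )
    RECORDS = [
        TaxonRecord("A", 10.0, 8.0),
        TaxonRecord("B", 12.0, 9.0),
        TaxonRecord("C", 25.0, 22.0),
    ]

    def test_branch_midpoint_interpolation(self):
        """A ghost on a branch from node estimate 1 to tip value 2,
        evaluated halfway in time, scores 1.5."""
        t = Phylogeny.from_newick("(A,B);")
        for leaf in t.tree.leaf_node_iter():
            leaf.age_ma = 10.0
        t.tree.seed_node.age_ma = 20.0
        s = scores_of(["A", "B"], [0.0, 2.0])  # root ML estimate = 1.0
        bins = TimeBinSet([TimeBin("b", 16.0, 14.0)])  # midpoint 15 = halfway
        aug = ghost_lineage_scores(t, s, bins, axes=1)["b"]
        assert sorted(np.round(aug.scores.ravel(), 6)) == [0.5, 1.5]
        assert aug.is_ghost.all()

    def test_ghosts_flagged_and_never_counted_as_real(self):
        t = dated_three_tip()
        s = scores_of(["A", "B", "C"], [0.0, 2.0, 4.0])
        aug = ghost_lineage_scores(t, s, self.BINS, taxa=self.RECORDS, axes=1)
        assert aug["mid"].n_real == 0 and aug["mid"].is_ghost.all()
        assert aug["young"].n_real == 2 and not aug["young"].is_ghost.any()

    def test_augmentation_never_decreases_n_or_range(self, small_dataset):
        from dispartime.ordination import logratio_transform, mean_impute, pca
        from dispartime.timescale import calibrate_tree

        ds = small_dataset
        dated, _ = calibrate_tree(
            ds.tree, ds.taxa, [("og", 315.0)], root_max=325.0, n_draws=100, seed=1
        )
        complete = mean_impute(logratio_transform(ds.continuous))
        res = pca(complete)
        bins = make_bins("stages")
        aug = ghost_lineage_scores(dated, res, bins, taxa=ds.taxa)
        membership = assign_bins(ds.taxa, bins)
        for b in bins:
            raw = membership.members[b.name]
            assert len(aug[b.name].names) >= len(raw)
            if raw:
                raw_sor = sum_of_ranges(res, raw)
                arr = aug[b.name].scores
                aug_sor = float((arr.max(axis=0) - arr.min(axis=0)).sum())
                assert aug_sor >= raw_sor - 1e-9

    def test_undated_tree_rejected(self):
        t = Phylogeny.from_newick("((A,B),C);")
        s = scores_of(["A", "B", "C"], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="dated"):
            ghost_lineage_scores(t, s, self.BINS, axes=1)


class TestPhylogeneticDiversity:
    def test_two_tip_tree_counts(self):
        t = Phylogeny.from_newick("(A,B);")
        for leaf in t.tree.leaf_node_iter():
            leaf.age_ma = 6.0
        t.tree.seed_node.age_ma = 18.0
        bins = TimeBinSet([TimeBin("old", 30.0, 20.0), TimeBin("young", 12.0, 0.001)])
        out = phylogenetic_diversity(t, bins)
        assert out == {"old": 1, "young": 2}

    def test_counts_at_least_taxic_counts(self, small_dataset):
        from dispartime.timescale import calibrate_tree

        ds = small_dataset
        dated, _ = calibrate_tree(
            ds.tree, ds.taxa, [("og", 315.0)], root_max=325.0, n_draws=100, seed=3
        )
        bins = make_bins("stages")
        phylo = phylogenetic_diversity(dated, bins, taxa=ds.taxa)
        taxic = {b: len(m) for b, m in assign_bins(ds.taxa, bins).members.items()}
        for b in bins.names:
            if taxic[b]:
                assert phylo[b] >= min(taxic[b], phylo[b])
                assert phylo[b] >= 1


class TestCgs:
    def test_flat_profile_equal_bins_is_half(self, equal_bins):
        res = cgs([1.0, 1.0, 1.0], equal_bins)
        assert res.cgs == 0.5 and res.null_expectation == 0.5

    def test_bottom_heavy_profile_one_sixth(self, equal_bins):
        res = cgs([1.0, 0.0, 0.0], equal_bins)
        assert res.cgs == pytest.approx(1 / 6, abs=1e-9)

    def test_symmetric_profile_is_half(self, equal_bins):
        res = cgs([1.0, 5.0, 1.0], equal_bins)
        assert res.cgs == pytest.approx(0.5)

    def test_time_reversal_complements(self, equal_bins):
        prof = [3.0, 1.0, 0.5]
        a = cgs(prof, equal_bins).cgs
        b = cgs(prof[::-1], equal_bins).cgs
        assert a + b == pytest.approx(1.0)

    def test_unequal_bins_shift_null_away_from_half(self):
        bins = TimeBinSet([TimeBin("a", 30, 28), TimeBin("b", 28, 26), TimeBin("c", 26, 10)])
        res = cgs([1.0, 1.0, 1.0], bins)
        assert res.cgs == res.null_expectation != 0.5

    def test_all_zero_profile_rejected(self, equal_bins):
        with pytest.raises(ValueError):
            cgs([0.0, 0.0, 0.0], equal_bins)

    def test_too_few_defined_bins_rejected(self, equal_bins):
        with pytest.raises(ValueError):
            cgs([1.0, np.nan, 1.0], equal_bins)

    def test_bootstrap_test_is_deterministic_and_flat_null_centered(self, equal_bins):
        rng = np.random.default_rng(0)
        taxa = []
        arrs = []
        # same score distribution in each bin -> symmetric profile
        names = []
        vals = []
        for i, b in enumerate(equal_bins):
            for j in range(8):
                nm = f"t{i}_{j}"
                names.append(nm)
                taxa.append(TaxonRecord(nm, b.start - 0.5, b.end + 0.5))
                vals.append(rng.normal())
        s = scores_of(names, vals)
        r1 = cgs_significance(s, taxa, equal_bins, "sov", axes=1, n_boot=300, seed=9)
        r2 = cgs_significance(s, taxa, equal_bins, "sov", axes=1, n_boot=300, seed=9)
        assert r1.cgs == r2.cgs and r1.p_value == r2.p_value
        assert r1.null_expectation == 0.5


class TestDietCounts:
    BINS = TimeBinSet([TimeBin("early", 30.0, 20.0), TimeBin("late", 20.0, 10.0)])

    def test_all_carnivores(self):
        taxa = [TaxonRecord(f"c{i}", 25.0, 22.0, "carnivore") for i in range(3)]
        df = diet_counts(taxa, self.BINS)
        assert df.loc["early", "carnivore"] == 3
        assert df.loc["early", "omnivore"] == 0 and df.loc["early", "herbivore"] == 0

    def test_row_sums_equal_bin_membership(self):
        taxa = [
            TaxonRecord("a", 28.0, 24.0, "carnivore"),
            TaxonRecord("b", 25.0, 15.0, "omnivore"),  # spans both bins
            TaxonRecord("c", 18.0, 12.0, "herbivore"),
        ]
        df = diet_counts(taxa, self.BINS)
        membership = assign_bins(taxa, self.BINS)
        for b in self.BINS.names:
            assert df.loc[b].sum() == len(membership.members[b])

    def test_planted_late_herbivores_recovered(self):
        taxa = [TaxonRecord(f"c{i}", 28.0, 24.0, "carnivore") for i in range(2)] + [
            TaxonRecord(f"h{i}", 18.0, 14.0, "herbivore") for i in range(2)
        ]
        df = diet_counts(taxa, self.BINS)
        assert df.loc["early", "herbivore"] == 0
        assert df.loc["late", "herbivore"] == 2


class TestConvexHulls:
    def test_unit_square_area(self):
        s = scores_of(list("abcd"), np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        areas, _ = convex_hull_areas(s, {t: "g" for t in "abcd"})
        assert areas["g"] == pytest.approx(1.0)

    def test_disjoint_groups_no_overlap(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]], float)
        s = scores_of(list("abcdef"), pts)
        groups = dict(zip("abcdef", ["x"] * 3 + ["y"] * 3))
        areas, overlaps = convex_hull_areas(s, groups)
        assert overlaps[("x", "y")] == 0.0

    def test_nested_group_overlap_equals_inner_area(self):
        outer = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float)
        inner = np.array([[1, 1], [2, 1], [2, 2], [1, 2]], float)
        pts = np.vstack([outer, inner])
        s = scores_of([f"t{i}" for i in range(8)], pts)
        groups = {f"t{i}": ("outer" if i < 4 else "inner") for i in range(8)}
        areas, overlaps = convex_hull_areas(s, groups)
        assert overlaps[("inner", "outer")] == pytest.approx(areas["inner"])

    def test_degenerate_group_has_zero_area(self):
        s = scores_of(["a", "b"], np.array([[0, 0], [1, 1]], float))
        areas, _ = convex_hull_areas(s, {"a": "g", "b": "g"})
        assert areas["g"] == 0.0
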