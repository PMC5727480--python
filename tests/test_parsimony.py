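"""Parsimony engines against brute-force oracles, fit-index identities,
search contracts and resampling support behavior."""

import itertools

import numpy as np
import pytest

from dispartime.datamodel import ContinuousMatrix, DiscreteMatrix, Phylogeny
from dispartime.parsimony import (
    farris_length,
    fit_indices,
    fitch_length,
    fitch_steps_per_character,
    heuristic_search,
    symmetric_resampling,
)

from conftest import random_discrete, single


# ------------------------------------------------------------- oracles

def brute_force_fitch(tree: Phylogeny, m: DiscreteMatrix) -> int:
    """Minimum changes over all internal-state assignments, one character
    at a time (exhaustive; independent of the downpass implementation)."""
    dtree = tree.tree
    internals = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    total = 0
    for j in range(m.nchar):
        obs = sorted(m.observed_states(j)) or [0]
        tip_sets = {}
        for leaf in dtree.leaf_node_iter():
            cell = m.row(leaf.taxon.label)[j]
            tip_sets[leaf] = sorted(cell) if cell is not None else obs
        best = None
        for assign in itertools.product(obs, repeat=len(internals)):
            a = dict(zip(internals, assign))
            # tips may pick their best state given the parent
            cost = 0
            for node in dtree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                pstate = a[node.parent_node]
                if node.is_leaf():
                    cost += min(1 if s != pstate else 0 for s in tip_sets[node])
                else:
                    cost += 1 if a[node] != pstate else 0
            best = cost if best is None else min(best, cost)
        total += best
    return total


def brute_force_farris(tree: Phylogeny, m: ContinuousMatrix, grid_extra=5) -> float:
    """Grid minimization of total |parent - child| over internal values."""
    dtree = tree.tree
    internals = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    total = 0.0
    for j in range(m.nchar):
        vals = [v for v in m.values[:, j] if not np.isnan(v)]
        if not vals:
            continue
        grid = sorted(set(vals))  # optima lie on tip values (medians)
        tipv = {
            leaf: m.row(leaf.taxon.label)[j] for leaf in dtree.leaf_node_iter()
        }
        best = None
        for assign in itertools.product(grid, repeat=len(internals)):
            a = dict(zip(internals, assign))
            cost = 0.0
            for node in dtree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                pv = a[node.parent_node]
                if node.is_leaf():
                    v = tipv[node]
                    if not np.isnan(v):
                        cost += abs(v - pv)
                else:
                    cost += abs(a[node] - pv)
            best = cost if best is None else min(best, cost)
        total += best
    return total


def random_topology(rng, taxa) -> Phylogeny:
    pool = [t for t in taxa]
    rng.shuffle(pool)
    newick = f"({pool[0]},{pool[1]})"
    for t in pool[2:]:
        newick = f"({newick},{t})"
    return Phylogeny.from_newick(newick + ";")


# ------------------------------------------------------------ scoring

class TestFitch:
    def test_single_synapomorphy(self, quartet_tree):
        m = DiscreteMatrix(taxa=list("ABCD"), states=[[single(s)] for s in (0, 0, 1, 1)])
        assert fitch_length(quartet_tree, m) == 1

    def test_incongruent_character_needs_two_steps(self, quartet_tree):
        m = DiscreteMatrix(taxa=list("ABCD"), states=[[single(s)] for s in (0, 1, 0, 1)])
        assert fitch_length(quartet_tree, m) == 2

    def test_all_missing_character_is_free(self, quartet_tree):
        m = DiscreteMatrix(taxa=list("ABCD"), states=[[None]] * 4)
        assert fitch_length(quartet_tree, m) == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            ntax = int(rng.integers(4, 7))
            m = random_discrete(rng, ntax, nchar=4, missing_frac=0.2, poly_frac=0.1)
            tree = random_topology(rng, m.taxa)
            assert fitch_length(tree, m) == brute_force_fitch(tree, m)

    def test_length_invariant_to_rerooting(self):
        rng = np.random.default_rng(7)
        m = random_discrete(rng, 6, nchar=10, missing_frac=0.2)
        t1 = random_topology(rng, m.taxa)
        base = fitch_length(t1, m)
        import dendropy

        for edge in list(t1.tree.preorder_edge_iter())[2:5]:
            t2 = Phylogeny(dendropy.Tree(t1.tree))
            e = [
                ed
                for ed in t2.tree.preorder_edge_iter()
                if ed.head_node.leaf_nodes()
                and sorted(l.taxon.label for l in ed.head_node.leaf_iter())
                == sorted(l.taxon.label for l in edge.head_node.leaf_iter())
            ][0]
            t2.tree.reroot_at_edge(e)
            assert fitch_length(t2, m) == base

    def test_all_missing_taxon_does_not_change_length(self):
        rng = np.random.default_rng(9)
        m = random_discrete(rng, 5, nchar=8, missing_frac=0.1)
        t = random_topology(rng, m.taxa)
        base = fitch_length(t, m)
        m2 = DiscreteMatrix(
            taxa=m.taxa + ["ghostly"],
            states=[list(r) for r in m.states] + [[None] * m.nchar],
        )
        t2 = Phylogeny.from_newick(t.to_newick(False)[:-1].rstrip(";") + ";")
        # attach the new taxon next to t0
        nwk = t.to_newick(False).replace("t0", "(t0,ghostly)")
        assert fitch_length(Phylogeny.from_newick(nwk), m2) == base


class TestFarris:
    def test_three_tip_example(self):
        t = Phylogeny.from_newick("((A,B),C);")
        m = ContinuousMatrix(taxa=list("ABC"), values=np.array([[0.1], [0.2], [0.5]]))
        assert farris_length(t, m) == pytest.approx(0.4)

    def test_equal_tips_cost_nothing(self):
        t = Phylogeny.from_newick("((A,B),(C,D));")
        m = ContinuousMatrix(taxa=list("ABCD"), values=np.full((4, 3), 2.5))
        assert farris_length(t, m) == 0.0

    def test_two_tip_distance(self):
        t = Phylogeny.from_newick("(A,B);")
        m = ContinuousMatrix(taxa=list("AB"), values=np.array([[0.3], [0.9]]))
        assert farris_length(t, m) == pytest.approx(0.6)

    def test_matches_grid_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            ntax = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(ntax)]
            vals = rng.uniform(0.1, 3.0, size=(ntax, 2))
            vals[rng.random(vals.shape) < 0.15] = np.nan
            if np.isnan(vals).all(axis=0).any():
                continue
            m = ContinuousMatrix(taxa=taxa, values=vals)
            tree = random_topology(rng, taxa)
            assert farris_length(tree, m) == pytest.approx(
                brute_force_farris(tree, m), abs=1e-9
            )


class TestFitIndices:
    def test_homoplastic_character_worked_example(self, quartet_tree):
        m = DiscreteMatrix(taxa=list("ABCD"), states=[[single(s)] for s in (0, 1, 0, 1)])
        fit = fit_indices(quartet_tree, m)
        assert (fit.s[0], fit.m[0], fit.g[0]) == (2, 1, 2)
        assert fit.ci == pytest.approx(0.5)
        assert fit.ri == pytest.approx(0.0)

    def test_perfectly_congruent_matrix(self, quartet_tree):
        m = DiscreteMatrix(
            taxa=list("ABCD"),
            states=[
                [single(0), single(0)],
                [single(0), single(0)],
                [single(1), single(1)],
                [single(1), single(1)],
            ],
        )
        fit = fit_indices(quartet_tree, m)
        assert fit.ci == 1.0 and fit.hi == 0.0 and fit.ri == 1.0

    def test_index_identities_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = random_discrete(rng, 8, nchar=20, missing_frac=0.25, poly_frac=0.05)
            t = random_topology(rng, m.taxa)
            fit = fit_indices(t, m)
            if fit.ci is None:
                continue
            assert fit.ci * fit.s.sum() == pytest.approx(fit.m.sum())
            assert fit.ci + fit.hi == pytest.approx(1.0)
            assert np.all(fit.m <= fit.s) and np.all(fit.s <= fit.g)
            if fit.ri_defined:
                assert 0.0 <= fit.ri <= 1.0

    def test_constant_matrix_flags_ri_undefined(self, quartet_tree):
        m = DiscreteMatrix(taxa=list("ABCD"), states=[[single(0)]] * 4)
        fit = fit_indices(quartet_tree, m)
        assert not fit.ri_defined and fit.ri is None


# ------------------------------------------------------------- search

def synapomorphy_matrix(newick: str, outgroup: str) -> DiscreteMatrix:
    """Homoplasy-free matrix: one binary character per internal clade."""
    t = Phylogeny.from_newick(newick)
    taxa = sorted(t.taxon_labels)
    clades = [c for c in t.bipartitions()]
    states = [[single(1 if tx in cl else 0) for cl in clades] for tx in taxa]
    return DiscreteMatrix(taxa=taxa, states=states)


class TestSearch:
    TRUE = "(O,((A,B),(C,(D,E))));"

    def test_recovers_generating_topology_at_minimum_length(self):
        m = synapomorphy_matrix(self.TRUE, "O")
        fit_true = fit_indices(Phylogeny.from_newick(self.TRUE), m)
        res = heuristic_search(m, outgroup="O", n_replicates=8, seed=3)
        assert res.length == fit_true.m.sum()  # no homoplasy: length = sum(m)
        assert len(res.trees) == 1
        assert res.trees[0].bipartitions() == Phylogeny.from_newick(self.TRUE).bipartitions()

    def test_same_seed_same_output(self):
        rng = np.random.default_rng(31)
        m = random_discrete(rng, 8, nchar=15, missing_frac=0.2)
        a = heuristic_search(m, outgroup="t0", n_replicates=4, seed=99)
        b = heuristic_search(m, outgroup="t0", n_replicates=4, seed=99)
        assert a.length == b.length
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]

    def test_never_beats_exhaustive_minimum(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            m = random_discrete(rng, 6, nchar=6, missing_frac=0.2)
            res = heuristic_search(m, outgroup="t0", n_replicates=10, seed=1)
            # exhaustive lower bound: sum of per-character minima
            fit = fit_indices(res.trees[0], m)
            assert res.length >= fit.m.sum()

    def test_unknown_outgroup_raises(self):
        rng = np.random.default_rng(1)
        m = random_discrete(rng, 5, nchar=4)
        with pytest.raises(KeyError):
            heuristic_search(m, outgroup="nope", n_replicates=1, seed=0)

    def test_mixed_continuous_contributes_to_length(self):
        m = synapomorphy_matrix(self.TRUE, "O")
        vals = np.ones((6, 2))
        vals[0] = [5.0, 5.0]  # outgroup divergent ratios
        cont = ContinuousMatrix(taxa=m.taxa, values=vals)
        res = heuristic_search(m, cont, outgroup="O", n_replicates=4, seed=0)
        assert res.length == pytest.approx(fit_indices(res.trees[0], m).length + 8.0)


class TestSymmetricResampling:
    def test_unconflicted_clade_gets_full_support(self):
        m = synapomorphy_matrix("(O,((A,B),(C,(D,E))));", "O")
        ref = heuristic_search(m, outgroup="O", n_replicates=4, seed=0).trees[0]
        sup = symmetric_resampling(
            m, None, ref, outgroup="O", n_reps=25, seed=5, n_addition_replicates=2
        )
        assert sup.support_for({"A", "B"}) == 1.0
        assert sup.support_for({"D", "E"}) == 1.0

    def test_zero_change_probability_reproduces_reference(self):
        m = synapomorphy_matrix("(O,((A,B),(C,(D,E))));", "O")
        ref = heuristic_search(m, outgroup="O", n_replicates=4, seed=0).trees[0]
        sup = symmetric_resampling(
            m, None, ref, outgroup="O", n_reps=10, p_change=0.0, seed=5
        )
        assert all(f == 1.0 for f in sup.frequencies.values())

    def test_rejects_bad_rep_count(self):
        rng = np.random.default_rng(1)
        m = random_discrete(rng, 5, nchar=4)
        ref = heuristic_search(m, outgroup="t0", n_replicates=1, seed=0).trees[0]
        with pytest.raises(ValueError):
            symmetric_resampling(m, None, ref, outgroup="t0", n_reps=0)
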