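"""Tau distances, neighbor joining, exact least-squares branch lengths,
and NNI topology search."""

import itertools

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microhap.relationships import distance_matrix, tau_distance
from microhap.simulate import SimulationConfig, simulate_frequencies
from microhap.stats import FrequencyTable
from microhap.trees import (DistanceMatrix, Tree, explore_topologies,
                            neighbor_joining, nni_neighbors,
                            ols_branch_lengths, random_binary_tree,
                            read_phylip, tree_distance_matrix, write_phylip)


class TestTauDistance:
    def test_identical_populations_have_zero_distance(self):
        p = {"L1": np.array([0.2, 0.8]), "L2": np.array([0.5, 0.5])}
        assert tau_distance(p, p) == 0.0

    def test_single_locus_hand_arithmetic(self):
        # (0.6,0.4) vs (0.4,0.6): num 0.08, denom 2*(0.25+0.25) = 1.0
        p1 = {"L1": np.array([0.6, 0.4])}
        p2 = {"L1": np.array([0.4, 0.6])}
        assert tau_distance(p1, p2) == pytest.approx(0.08)

    def test_no_shared_loci_is_an_error(self):
        with pytest.raises(ValueError, match="share no loci"):
            tau_distance({"L1": np.array([1.0])}, {"L2": np.array([1.0])})

    def test_fixed_identical_loci_carry_no_information(self):
        p1 = {"L1": np.array([1.0, 0.0]), "L2": np.array([0.6, 0.4])}
        p2 = {"L1": np.array([1.0, 0.0]), "L2": np.array([0.4, 0.6])}
        # L1 is 0/0 and must be excluded from the mean, not counted as 0
        assert tau_distance(p1, p2) == pytest.approx(0.08)

    def test_calibration_recovers_drift_time(self):
        # two populations drifted t = 0.05 * 2Ne generations from a common
        # ancestor: mean tau over replicates ~ 0.05 within 3 SE
        target = 0.05
        estimates = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_regions=1, populations_per_region=(2,), n_loci=50,
                alleles_per_locus=(3, 6), region_drift=(0.0,),
                population_drift=target, effective_size=200, seed=100 + seed)
            fs = simulate_frequencies(cfg)
            p1 = {l: fs.freq("R1P01", l) for l in fs.loci}
            p2 = {l: fs.freq("R1P02", l) for l in fs.loci}
            estimates.append(tau_distance(p1, p2))
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - target) < 3 * se


class TestDistanceMatrix:
    @staticmethod
    def _table(cells):
        rows = [(pop, locus, allele, f, 100)
                for (pop, locus), d in cells.items()
                for allele, f in d.items()]
        return FrequencyTable(pd.DataFrame(
            rows, columns=["population", "locus", "allele", "frequency",
                           "n_copies"]))

    def test_identical_populations_give_zero_matrix(self):
        ft = self._table({("P1", "L1"): {"A": 0.4, "B": 0.6},
                          ("P2", "L1"): {"A": 0.4, "B": 0.6}})
        dm = distance_matrix(ft)
        assert np.array_equal(dm.matrix, np.zeros((2, 2)))

    def test_matrix_equals_elementwise_tau_calls(self, small_world):
        from microhap.stats import allele_frequencies
        ft = allele_frequencies(small_world["genotypes"])
        dm = distance_matrix(ft)
        a, b = dm.labels[1], dm.labels[4]
        pa = {l: ft.matrix(l).loc[a].to_numpy() for l in ft.loci}
        pb = {l: ft.matrix(l).loc[b].to_numpy() for l in ft.loci}
        assert dm.value(a, b) == pytest.approx(tau_distance(pa, pb))

    def test_reorder_permutes_rows_and_columns_consistently(self):
        ft = self._table({("P1", "L1"): {"A": 0.4, "B": 0.6},
                          ("P2", "L1"): {"A": 0.9, "B": 0.1},
                          ("P3", "L1"): {"A": 0.5, "B": 0.5}})
        dm = distance_matrix(ft)
        perm = dm.reorder(["P3", "P1", "P2"])
        assert perm.value("P1", "P2") == dm.value("P1", "P2")
        assert perm.labels == ("P3", "P1", "P2")


def _four_taxon_matrix():
    """Additive matrix of ((A:1,B:2):1,(C:3,D:4)) joined by the internal
    branch of length 1."""
    labels = ("A", "B", "C", "D")
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], dtype=float)
    return DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_recovers_four_taxon_additive_tree(self):
        tree = neighbor_joining(_four_taxon_matrix())
        assert tree.splits() == frozenset({frozenset({"C", "D"})})
        lengths = tree.branch_lengths()
        leaf_lengths = {leaf: length for (a, b), length in lengths.items()
                        for leaf in (a, b) if isinstance(leaf, str)}
        assert leaf_lengths == pytest.approx(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [l for (a, b), l in lengths.items()
                    if not isinstance(a, str) and not isinstance(b, str)]
        assert internal == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                                    dtype=float))
        tree = neighbor_joining(d)
        lengths = {leaf: length
                   for (a, b), length in tree.branch_lengths().items()
                   for leaf in (a, b) if isinstance(leaf, str)}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_ultrametric_matrix_matches_single_linkage_topology(self):
        # cophenetic distances of nested clusters {A,B} < {A,B,C} < all
        d = DistanceMatrix(("A", "B", "C", "D"), np.array([
            [0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]],
            dtype=float))
        tree = neighbor_joining(d)
        assert tree.splits() == frozenset({frozenset({"C", "D"})}) or \
            tree.splits() == frozenset({frozenset({"A", "B"})})

    @given(st.integers(min_value=4, max_value=12), st.integers(0, 10 ** 6))
    @settings(max_examples=20)
    def test_exact_recovery_on_random_additive_matrices(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = [f"T{i:02d}" for i in range(n)]
        truth = random_binary_tree(labels, rng)
        dm = tree_distance_matrix(truth)
        recovered = neighbor_joining(dm)
        assert recovered.splits() == truth.splits()
        fit = ols_branch_lengths(recovered, dm)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-16)
        want = truth.branch_lengths()
        got = fit.tree.branch_lengths()
        # compare by split (internal node ids differ between trees)
        def by_split(tree):
            return {tree.split_of_edge(a, b): l
                    for (a, b), l in tree.branch_lengths().items()}
        truth_map, got_map = by_split(truth), by_split(fit.tree)
        for split, length in truth_map.items():
            assert got_map[split] == pytest.approx(length, abs=1e-9)


def _independent_ols(tree: Tree, dm: DistanceMatrix) -> np.ndarray:
    """Independent normal-equations oracle: edge-path membership via the
    split characterization (edge is on path(i,j) iff exactly one endpoint
    lies in the edge's leaf-side component), solved with numpy.linalg.solve.
    """
    edges = tree.edges
    leaves = tree.leaves
    pairs = list(itertools.combinations(leaves, 2))
    a = np.zeros((len(pairs), len(edges)))
    for col, (u, v) in enumerate(edges):
        g = tree.graph.copy()
        g.remove_edge(u, v)
        side = set(nx.node_connected_component(g, u))
        for row, (p, q) in enumerate(pairs):
            if (p in side) != (q in side):
                a[row, col] = 1.0
    y = np.array([dm.value(p, q) for p, q in pairs])
    return np.linalg.solve(a.T @ a, a.T @ y)


class TestOLSBranchLengths:
    def test_additive_matrix_is_fit_exactly(self):
        dm = _four_taxon_matrix()
        tree = neighbor_joining(dm)
        fit = ols_branch_lengths(tree, dm)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)
        assert fit.n_negative_internal == 0

    def test_matches_independent_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        dm0 = _four_taxon_matrix()
        noisy = dm0.matrix + rng.uniform(-0.3, 0.3, dm0.matrix.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(dm0.labels, noisy)
        tree = neighbor_joining(dm0)  # fixed topology
        fit = ols_branch_lengths(tree, dm)
        oracle = _independent_ols(tree, dm)
        got = [fit.tree.branch_lengths()[e] for e in fit.tree.edges]
        assert np.allclose(sorted(got), sorted(oracle), atol=1e-9)

    def test_conflicting_matrix_produces_negative_internal_branch(self):
        # matrix strongly supports AC|BD but we fit the AB|CD topology
        d = np.array([
            [0, 10, 2, 9],
            [10, 0, 9, 2],
            [2, 9, 0, 10],
            [9, 2, 10, 0]], dtype=float)
        dm = DistanceMatrix(("A", "B", "C", "D"), d)
        ab_cd = neighbor_joining(_four_taxon_matrix())  # AB|CD topology
        fit = ols_branch_lengths(ab_cd, dm)
        assert fit.n_negative_internal == 1

    def test_leaf_mismatch_is_an_error(self):
        dm = _four_taxon_matrix()
        tree = neighbor_joining(dm)
        other = DistanceMatrix(("A", "B", "C", "E"), dm.matrix)
        with pytest.raises(ValueError, match="labels"):
            ols_branch_lengths(tree, other)


def _all_five_taxon_trees(labels):
    """All 15 unrooted binary topologies on 5 labels, by inserting the
    fifth leaf into every edge of every 4-taxon topology."""
    a, b, c, d, e = labels
    quartets = []
    for pair in ((b, c), (b, d), (c, d)):
        # 4-taxon tree with split {a, other}|rest
        rest = [x for x in (b, c, d) if x not in pair]
        g = nx.Graph()
        g.add_edge(a, 0, length=1.0)
        g.add_edge(rest[0], 0, length=1.0)
        g.add_edge(pair[0], 1, length=1.0)
        g.add_edge(pair[1], 1, length=1.0)
        g.add_edge(0, 1, length=1.0)
        quartets.append(Tree(g))
    out = {}
    for q in quartets:
        for u, v in list(q.graph.edges):
            g = q.graph.copy()
            g.remove_edge(u, v)
            g.add_edge(u, 9, length=1.0)
            g.add_edge(v, 9, length=1.0)
            g.add_edge(e, 9, length=1.0)
            t = Tree(g)
            out[t.splits()] = t
    assert len(out) == 15
    return list(out.values())


class TestTopologySearch:
    def test_four_taxa_enumerates_all_three_topologies(self):
        dm = _four_taxon_matrix()
        search = explore_topologies(neighbor_joining(dm), dm, radius=1)
        assert search.n_evaluated == 3

    def test_generating_topology_ranks_first_on_additive_input(self):
        dm = _four_taxon_matrix()
        search = explore_topologies(neighbor_joining(dm), dm, radius=1)
        assert search.best.residual_ss == pytest.approx(0.0, abs=1e-18)
        assert search.best.tree.splits() == frozenset(
            {frozenset({"C", "D"})})

    def test_five_taxon_search_matches_exhaustive_oracle(self):
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(17)
        truth = random_binary_tree(labels, rng)
        noisy = tree_distance_matrix(truth).matrix.copy()
        noisy += rng.uniform(-0.05, 0.05, noisy.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(tuple(sorted(labels)), noisy)
        search = explore_topologies(neighbor_joining(dm), dm, radius=4)
        assert search.n_evaluated == 15
        oracle = sorted(
            ols_branch_lengths(t, dm).residual_ss
            for t in _all_five_taxon_trees(labels))
        got = [f.residual_ss for f in search.ranked]
        assert np.allclose(got, oracle, atol=1e-9)

    def test_nni_of_internal_edge_gives_two_rearrangements(self):
        dm = _four_taxon_matrix()
        tree = neighbor_joining(dm)
        neighbors = nni_neighbors(tree)
        assert len(neighbors) == 2
        assert len({t.splits() for t in neighbors} | {tree.splits()}) == 3


class TestSerialization:
    def test_newick_round_trips_through_dendropy(self):
        dm = _four_taxon_matrix()
        tree = neighbor_joining(dm)
        newick = tree.to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for a, b in itertools.combinations("ABCD", 2):
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                dm.value(a, b))

    def test_negative_lengths_serialized_as_is(self):
        g = nx.Graph()
        g.add_edge("A", 0, length=0.5)
        g.add_edge("B", 0, length=-0.25)
        g.add_edge("C", 0, length=1.0)
        assert "-0.25" in Tree(g).to_newick()

    def test_phylip_round_trip(self, tmp_path):
        dm = _four_taxon_matrix()
        path = tmp_path / "dist.phy"
        write_phylip(dm, path)
        again = read_phylip(path)
        assert again.labels == dm.labels
        assert np.allclose(again.matrix, dm.matrix, atol=1e-6)
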