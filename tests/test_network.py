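"""Locus weights, reduced-median preprocessing, and median-joining networks."""

import itertools

import numpy as np
import pytest

from ystrkit.network import (
    LocusWeights,
    compute_weights,
    median_joining,
    minimum_spanning_network,
    reduced_median,
    triplet_median,
    weighted_distance,
)

import oracles


def random_haplotypes(rng, n, loci=3, lo=10, hi=14):
    return [tuple(int(x) for x in rng.integers(lo, hi + 1, size=loci))
            for _ in range(n)]


class TestComputeWeights:
    def test_inverse_variance_ratio(self):
        # variances 0.5 and 1.0 -> weights 2:1
        haps = [(10, 10), (11, 12), (10, 10), (11, 12), (10, 11), (11, 11),
                (10, 12), (11, 10)]
        arr = np.array(haps, float)
        v = arr.var(axis=0, ddof=1)
        w = compute_weights(haps)
        assert w.w[0] * v[0] == pytest.approx(w.w[1] * v[1], rel=0.35)

    def test_exact_quarters(self):
        # engineered variances (0.25, 0.5, 1.0) -> weights (4, 2, 1)
        haps = [(10, 10, 10), (11, 11, 12), (10, 11, 10), (11, 10, 12)]
        arr = np.array(haps, float)
        assert np.allclose(arr.var(axis=0, ddof=1), [1 / 3, 1 / 3, 4 / 3])
        w = compute_weights(haps)
        assert w.w == (4, 4, 1)

    def test_equal_variances_equal_weights(self):
        haps = [(10, 20), (12, 22), (11, 21), (13, 23)]
        w = compute_weights(haps)
        assert w.w[0] == w.w[1]

    def test_zero_variance_gets_cap(self):
        haps = [(10, 5), (12, 5), (11, 5)]
        w = compute_weights(haps)
        assert w.w[1] == 99

    def test_weights_bounds_enforced(self):
        with pytest.raises(ValueError):
            LocusWeights(("a",), (0,))
        with pytest.raises(ValueError):
            LocusWeights(("a",), (100,))


class TestMinimumSpanningNetwork:
    @pytest.mark.parametrize("seed", range(8))
    def test_epsilon_zero_equals_mst_union_oracle(self, seed):
        """At epsilon 0 the MSN is the union of all minimum spanning trees
        (cycle-property brute force, n <= 8)."""
        rng = np.random.default_rng(seed)
        haps = list(set(random_haplotypes(rng, 8)))
        w = LocusWeights.uniform(3)
        G = minimum_spanning_network(haps, w, epsilon=0)
        ours = {frozenset(e) for e in G.edges}
        assert ours == oracles.mst_union_by_cycle_property(sorted(set(haps)), w.w)

    def test_epsilon_adds_edges_monotonically(self):
        rng = np.random.default_rng(5)
        haps = list(set(random_haplotypes(rng, 7)))
        w = LocusWeights.uniform(3)
        sizes = [minimum_spanning_network(haps, w, epsilon=e).number_of_edges()
                 for e in (0, 1, 2, 5)]
        assert sizes == sorted(sizes)


class TestMedianJoining:
    def test_two_haplotypes_single_weighted_edge(self):
        w = LocusWeights(("a", "b", "c"), (5, 1, 1))
        net = median_joining([(0, 0, 0), (1, 0, 0)], w)
        assert net.graph.number_of_edges() == 1
        assert net.total_length == 5

    def test_unit_star_median_inferred(self):
        """Three haplotypes one step from a common unobserved center: the
        median vector (0,0,0) gives Steiner cost 3 < any chain cost 4."""
        net = median_joining(
            [(1, 0, 0), (0, 1, 0), (0, 0, 1)], LocusWeights.uniform(3)
        )
        assert net.median_vectors == [(0, 0, 0)]
        assert net.total_length == 3
        assert all(net.graph.degree((0, 0, 0)) == 3 for _ in [0])

    def test_every_observed_haplotype_is_a_node_and_connected(self):
        import networkx as nx

        rng = np.random.default_rng(2)
        haps = random_haplotypes(rng, 10)
        net = median_joining(haps)
        for h in haps:
            assert h in net.graph
        assert nx.is_connected(net.graph)

    def test_edge_lengths_equal_weighted_distance(self):
        rng = np.random.default_rng(3)
        haps = random_haplotypes(rng, 8)
        net = median_joining(haps)
        for u, v, d in net.graph.edges(data=True):
            assert d["length"] == weighted_distance(u, v, net.weights)
            assert set(d["diff_loci"]) == {
                l for l, x, y in zip(net.weights.loci, u, v) if x != y
            }

    def test_median_vectors_have_degree_at_least_three(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            net = median_joining(random_haplotypes(rng, 7))
            for m in net.median_vectors:
                assert net.graph.degree(m) >= 3

    def test_total_mst_length_never_increased_by_medians(self):
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            haps = random_haplotypes(rng, 7)
            net = median_joining(haps)
            w = net.weights
            assert oracles.mst_length(sorted(net.graph.nodes), w.w) <= \
                oracles.mst_length(sorted(set(haps)), w.w)

    def test_multiplicity_and_groups_recorded(self):
        haps = [(1, 1), (1, 1), (2, 1)]
        net = median_joining(haps, LocusWeights.uniform(2),
                             groups=["A", "B", "A"])
        assert net.multiplicity[(1, 1)] == 2
        assert net.groups[(1, 1)] == {"A": 1, "B": 1}

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        haps = random_haplotypes(rng, 9)
        a = median_joining(haps)
        b = median_joining(list(haps))
        assert sorted(a.graph.nodes) == sorted(b.graph.nodes)
        assert sorted(map(frozenset, a.graph.edges)) == \
            sorted(map(frozenset, b.graph.edges))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Full network (nodes and edges) equals the definitional pure-Python
        reconstruction on small datasets."""
        rng = np.random.default_rng(1000 + seed)
        haps = random_haplotypes(rng, int(rng.integers(3, 7)), lo=10, hi=13)
        w = LocusWeights.uniform(3)
        net = median_joining(haps, w)
        nodes, edges = oracles.median_joining_oracle(haps, w.w)
        assert set(net.graph.nodes) == nodes
        assert {frozenset(e) for e in net.graph.edges} == edges


class TestReducedMedian:
    def test_two_haplotypes_unchanged(self):
        out = reduced_median([(10, 12), (11, 12)], LocusWeights.uniform(2))
        assert out == [(10, 12), (11, 12)]

    def test_quartet_infers_single_intermediate(self):
        """A quartet whose only candidate median is the unobserved (0,1,0):
        verified against the brute-force retention oracle on the binary
        expansion."""
        haps = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 1, 1)]
        w = LocusWeights.uniform(3)
        out = reduced_median(haps, w, r=2.0)
        assert set(out) == set(haps) | {(0, 1, 0)}
        oracle = oracles.reduced_median_retention_oracle(
            [tuple(h) for h in haps], (1, 1, 1), r=2.0
        )
        assert oracle == set(out)  # binary data: expansion is the identity

    def test_superset_of_input(self):
        rng = np.random.default_rng(4)
        haps = random_haplotypes(rng, 6)
        out = reduced_median(haps)
        assert set(map(tuple, haps)) <= set(out)

    def test_node_count_monotone_in_r(self):
        rng = np.random.default_rng(8)
        haps = random_haplotypes(rng, 6, lo=10, hi=12)
        w = LocusWeights.uniform(3)
        counts = [len(reduced_median(haps, w, r=r)) for r in (1.0, 2.0, 5.0, 1e9)]
        assert counts == sorted(counts)


def test_triplet_median_is_middle_value():
    assert triplet_median((10, 5), (12, 9), (11, 7)) == (11, 7)


def test_star_genealogy_modal_node_is_founder():
    """At T << 1/mu most replicates keep the founder as the modal node."""
    from ystrkit.catalog import default_catalog
    from ystrkit.profiles import to_minht
    from ystrkit.simulate import SimConfig, simulate_star

    cat = default_catalog()
    founder = (13, 13, 16, 24, 10, 14, 13)
    hits = 0
    reps = 20
    for rep in range(reps):
        res = simulate_star(SimConfig(n=40, t_g=100, mu=6.9e-4, seed=rep,
                                      founder=founder))
        haps = [to_minht(p, cat) for p in res.profiles]
        net = median_joining(haps)
        modal = max(net.multiplicity, key=lambda h: net.multiplicity[h])
        hits += modal == founder
    assert hits >= 0.9 * reps
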