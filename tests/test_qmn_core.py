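import itertools
import random

import pytest

from conftest import EMPTY_FILTER, naive_quasi_median_closure, network_for
from qmnet import FilterList, fixtures, reduce_table
from qmnet.qmn_core import (
    ACCENT,
    DIM,
    ClosureExplosionError,
    build_network,
    compute_network,
    node_haplotypes,
    parallel_class_by_label,
    quasi_median_closure,
    quasi_median_triple,
    select_highlight,
    torso,
)


class TestQuasiMedianTriple:
    def test_majority_everywhere_returns_majority_vector(self):
        x, y = ("A", "C", "G"), ("T", "T", "T")
        assert quasi_median_triple(x, x, y) == {x}

    def test_per_character_majority(self):
        u, v, w = ("A", "A"), ("G", "G"), ("A", "G")
        assert quasi_median_triple(u, v, w) == {("A", "G")}

    def test_all_distinct_yields_three(self):
        out = quasi_median_triple(("A",), ("C",), ("G",))
        assert out == {("A",), ("C",), ("G",)}

    def test_mixed_majority_and_conflict(self):
        # first char: majority A; second char: all distinct
        out = quasi_median_triple(("A", "A"), ("A", "C"), ("G", "G"))
        assert out == {("A", "A"), ("A", "C"), ("A", "G")}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quasi_median_triple(("A",), ("A", "C"), ("A",))


class TestClosure:
    def test_four_cycle_vertex_set_already_closed(self):
        S = {("0", "0"), ("0", "1"), ("1", "0"), ("1", "1")}
        assert quasi_median_closure(S) == S

    def test_three_conflicting_binary_chars_fill_the_cube(self):
        S = {("0", "0", "0"), ("1", "1", "0"), ("1", "0", "1"), ("0", "1", "1")}
        closed = quasi_median_closure(S)
        assert closed == set(itertools.product("01", repeat=3))

    def test_idempotence(self):
        S = {("0", "0", "0"), ("1", "1", "0"), ("1", "0", "1")}
        once = quasi_median_closure(S)
        assert quasi_median_closure(once) == once

    def test_node_cap_explosion(self):
        S = [("0", "0", "0"), ("1", "1", "0"), ("1", "0", "1"), ("0", "1", "1")]
        with pytest.raises(ClosureExplosionError):
            quasi_median_closure(S, node_cap=5)

    def test_explosion_error_names_filter_candidates(self):
        table, _, _ = fixtures.generate(fixtures.FixtureSpec(
            n_samples=20, n_backbone_lineages=4,
            backbone_variants_per_lineage=2, seed=13))
        cm = reduce_table(list(table), EMPTY_FILTER)
        with pytest.raises(ClosureExplosionError) as exc:
            compute_network(cm, node_cap=len(cm.row_vectors))
        assert "position" in str(exc.value)

    def test_matches_naive_oracle_on_random_instances(self):
        # production worklist closure vs independent all-triples fixpoint
        rng = random.Random(20240)
        checked = 0
        while checked < 110:
            k = rng.randint(1, 6)
            alphabets = [rng.randint(2, 4) for _ in range(k)]
            n = rng.randint(2, 8)
            S = {tuple(str(rng.randrange(a)) for a in alphabets)
                 for _ in range(n)}
            if len(S) < 2:
                continue
            # keep the brute-force oracle tractable on one CPU
            if _product_bound(S) > 160:
                continue
            assert quasi_median_closure(S) == naive_quasi_median_closure(S)
            checked += 1

    def test_closure_is_superset_and_order_free(self):
        rng = random.Random(7)
        S = {tuple(str(rng.randrange(3)) for _ in range(4)) for _ in range(6)}
        closed = quasi_median_closure(S)
        assert S <= closed
        assert quasi_median_closure(sorted(S, reverse=True)) == closed


def _degree(g, node_id):
    return sum(1 for e in g.edges if node_id in e.endpoints)


def _product_bound(S):
    bound = 1
    for i in range(len(next(iter(S)))):
        bound *= len({v[i] for v in S})
    return bound


class TestBuildNetwork:
    def test_zero_characters_single_node(self):
        # fully filtered fixture: every variant documented -> single node
        spec = fixtures.FixtureSpec(n_samples=5, n_backbone_lineages=2, seed=1)
        tab, flt, _ = fixtures.generate(spec)
        g = network_for(tab, flt)
        assert len(g.nodes) == 1
        assert g.nodes[0].node_id == "h1"
        assert len(g.nodes[0].sample_ids) == 5
        assert g.edges == ()

    def test_star_topology(self, fig1b_run):
        table, flt, _ = fig1b_run
        g = network_for(table, flt)
        assert len(g.nodes) == 6
        assert len(g.edges) == 5
        assert g.n_virtual == 0
        degrees = {}
        for e in g.edges:
            for nid in e.endpoints:
                degrees[nid] = degrees.get(nid, 0) + 1
        assert sorted(degrees.values()) == [1, 1, 1, 1, 1, 5]

    def test_four_cycle_with_two_parallel_classes(self):
        g = network_for(fixtures.conflict_quartet(2), EMPTY_FILTER)
        assert len(g.nodes) == 4 and len(g.edges) == 4
        classes = g.parallel_classes
        assert len(classes) == 2
        assert all(len(edges) == 2 for edges in classes.values())

    def test_edge_endpoints_differ_in_exactly_one_character(self, datasetB_run):
        table, flt, _ = datasetB_run
        g = network_for(table, flt)
        vec = {n.node_id: n.vector for n in g.nodes}
        for e in g.edges:
            a, b = (vec[x] for x in e.endpoints)
            diff = [i for i, (s, t) in enumerate(zip(a, b)) if s != t]
            assert diff == [e.character_index]
            assert tuple(sorted((a[diff[0]], b[diff[0]]))) == e.state_pair

    def test_connected_and_conserving(self, datasetA_run):
        table, flt, _ = datasetA_run
        g = network_for(table, flt)
        assert sum(len(n.sample_ids) for n in g.nodes) == len(table)
        # connectivity by union-find over edges
        parent = {n.node_id: n.node_id for n in g.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in g.edges:
            parent[find(e.endpoints[0])] = find(e.endpoints[1])
        assert len({find(n.node_id) for n in g.nodes}) == 1

    def test_node_ids_sampled_then_virtual(self):
        g = network_for(fixtures.conflict_quartet(3), EMPTY_FILTER)
        sampled = [n.node_id for n in g.nodes if n.sampled]
        virtual = [n.node_id for n in g.nodes if not n.sampled]
        assert all(i.startswith("h") for i in sampled)
        assert all(i.startswith("q") for i in virtual)


class TestHypercubeAndTreeLaws:
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_hypercube_law(self, k):
        g = network_for(fixtures.conflict_quartet(k), EMPTY_FILTER)
        assert len(g.nodes) == 2 ** k
        assert len(g.edges) == k * 2 ** (k - 1)
        assert g.n_virtual == 0  # all combinations sampled

    def test_compatible_characters_give_trees(self):
        # nested/disjoint character state classes -> acyclic, n-1 edges
        rng = random.Random(99)
        for _ in range(30):
            n_lineages = rng.randint(2, 5)
            spec = fixtures.FixtureSpec(
                n_samples=rng.randint(6, 20), n_backbone_lineages=n_lineages,
                backbone_variants_per_lineage=1, seed=rng.randrange(10_000),
                phantoms=(("A366G", rng.randint(2, 4)),))
            table, flt, _ = fixtures.generate(spec)
            # keep backbone characters: lineage-membership characters have
            # pairwise disjoint carrier sets -> compatible; the phantom may
            # conflict, so filter it out and keep only the tree-like part
            g = network_for(table, FilterList("only-366", frozenset({"A366G"})))
            assert len(g.edges) == len(g.nodes) - 1
            # connected + n-1 edges == acyclic tree; virtual nodes appear
            # only as forced unsampled intermediates (e.g. the star center)
            assert all(not n.sampled and _degree(g, n.node_id) >= 2
                       or n.sampled for n in g.nodes)


class TestTorso:
    def test_filtered_mode_is_identity(self, fig1b_run):
        table, flt, _ = fig1b_run
        g = network_for(table, flt)
        assert torso(g, "filtered") is g

    def test_pruned_mode_keeps_sampled_pendants(self, fig1b_run):
        table, flt, _ = fig1b_run
        g = network_for(table, flt)
        p = torso(g, "pruned")
        assert len(p.nodes) == len(g.nodes) and len(p.edges) == len(g.edges)

    def test_pruned_mode_strips_virtual_pendant_chain(self):
        # build a graph, then graft a virtual pendant chain onto it
        from qmnet.qmn_core import QMNEdge, QMNGraph, QMNNode
        g = network_for(fixtures.conflict_quartet(2), EMPTY_FILTER)
        chain = (QMNNode("q1", ("x", "x")), QMNNode("q2", ("y", "y")))
        extra = (
            QMNEdge("e90", (g.nodes[0].node_id, "q1"), 0, ("0", "x"), "X", "cX"),
            QMNEdge("e91", ("q1", "q2"), 0, ("x", "y"), "Y", "cY"),
        )
        grafted = QMNGraph(g.nodes + chain, g.edges + extra, g.characters)
        pruned = torso(grafted, "pruned")
        assert {n.node_id for n in pruned.nodes} == {n.node_id for n in g.nodes}
        assert len(pruned.edges) == len(g.edges)


class TestSelection:
    def test_node_listing_matches_planted_carriers(self, datasetA_run):
        table, flt, truth = datasetA_run
        g = network_for(table, flt)
        expected = truth.group_for(["A366G"])
        node = next(n for n in g.nodes
                    if sorted(n.sample_ids) == sorted(expected))
        assert len(node_haplotypes(g, node.node_id)) == 17

    def test_virtual_node_lists_nothing(self):
        # drop one sampled hypercube corner: the closure restores it virtually
        sub = list(fixtures.conflict_quartet(3))[:-1]
        g = compute_network(reduce_table(sub, EMPTY_FILTER))
        virtuals = [n for n in g.nodes if not n.sampled]
        assert virtuals and node_haplotypes(g, virtuals[0].node_id) == []

    def test_unknown_node_raises(self, fig1b_run):
        table, flt, _ = fig1b_run
        g = network_for(table, flt)
        with pytest.raises(KeyError):
            node_haplotypes(g, "h999")

    def test_star_center_selection_accentuates_everything(self, fig1b_run):
        table, flt, _ = fig1b_run
        g = network_for(table, flt)
        center = max(g.nodes, key=lambda n: len(n.sample_ids))
        hl = select_highlight(g, center.node_id)
        assert set(hl.values()) == {ACCENT}

    def test_leaf_selection_dims_complement(self, fig1b_run):
        table, flt, _ = fig1b_run
        g = network_for(table, flt)
        leaf = min((n for n in g.nodes if n.sampled),
                   key=lambda n: len(n.sample_ids))
        hl = select_highlight(g, leaf.node_id)
        accent = {k for k, v in hl.items() if v == ACCENT}
        # leaf, its one edge, and the center
        assert len([a for a in accent if a.startswith(("h", "q"))]) == 2
        assert len([a for a in accent if a.startswith("e")]) == 1

    def test_branch_selection_on_four_cycle(self):
        g = network_for(fixtures.conflict_quartet(2), EMPTY_FILTER)
        class_id = sorted(g.parallel_classes)[0]
        hl = select_highlight(g, class_id)
        accent_edges = [e for e in g.edges if hl[e.edge_id] == ACCENT]
        dim_edges = [e for e in g.edges if hl[e.edge_id] == DIM]
        assert len(accent_edges) == 2 and len(dim_edges) == 2
        assert all(hl[n.node_id] == ACCENT for n in g.nodes)

    def test_highlight_partition_covers_everything_once(self, datasetB_run):
        table, flt, _ = datasetB_run
        g = network_for(table, flt)
        hl = select_highlight(g, g.nodes[0].node_id)
        ids = {n.node_id for n in g.nodes} | {e.edge_id for e in g.edges}
        assert set(hl) == ids
        assert set(hl.values()) <= {ACCENT, DIM}

    def test_branch_lookup_by_label(self, datasetA_run):
        table, flt, _ = datasetA_run
        g = network_for(table, flt)
        classes = parallel_class_by_label(g, "A366G")
        assert classes
        edges = [e for c in classes for e in g.parallel_classes[c]]
        assert all(e.label == "A366G" for e in edges)

    def test_unknown_selection_raises(self, fig1b_run):
        table, flt, _ = fig1b_run
        g = network_for(table, flt)
        with pytest.raises(KeyError):
            select_highlight(g, "nope")
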