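import itertools
import random

import pytest
from hypothesis import given, strategies as st

from netsat.architectures import (
    ArchitectureClass,
    DirectedNetwork,
    Hypergraph,
    canonical_form,
    count_cyclic_classes,
    derive_ai_hypergraph,
    enumerate_architectures,
    graham_reduce,
    hasse_diagram,
    is_acyclic,
    is_reduced_cover,
)


def edgeset(h):
    return {frozenset(e) for e in h.edges}


class TestDeriveAI:
    def test_single_context_node_yields_full_edge(self):
        net = DirectedNetwork(
            nodes=["c", "a", "b", "d"],
            arcs=[("c", "a"), ("c", "b"), ("c", "d")],
            focal=["a", "b", "d"],
        )
        h = derive_ai_hypergraph(net)
        assert edgeset(h) == {frozenset("abd")}

    def test_three_independent_pair_contexts_yield_triangle(self):
        arcs = [("c1", "a"), ("c1", "b"), ("c2", "b"), ("c2", "d"),
                ("c3", "d"), ("c3", "a")]
        net = DirectedNetwork(["c1", "c2", "c3", "a", "b", "d"], arcs, ["a", "b", "d"])
        h = derive_ai_hypergraph(net)
        assert edgeset(h) == {frozenset("ab"), frozenset("bd"), frozenset("ad")}
        assert not is_acyclic(h)

    def test_focal_node_without_ancestors_gets_singleton(self):
        net = DirectedNetwork(["c", "a", "b"], [("c", "a")], ["a", "b"])
        h = derive_ai_hypergraph(net)
        assert edgeset(h) == {frozenset("a"), frozenset("b")}

    def test_connected_context_collapses_to_one_influence(self):
        # two context nodes linked by an arc act as a single AI node
        arcs = [("c1", "c2"), ("c1", "a"), ("c2", "b")]
        net = DirectedNetwork(["c1", "c2", "a", "b"], arcs, ["a", "b"])
        h = derive_ai_hypergraph(net)
        assert edgeset(h) == {frozenset("ab")}

    def test_dominated_edges_are_reduced_away(self):
        arcs = [("c1", "a"), ("c1", "b"), ("c2", "a")]
        net = DirectedNetwork(["c1", "c2", "a", "b"], arcs, ["a", "b"])
        h = derive_ai_hypergraph(net)
        assert edgeset(h) == {frozenset("ab")}
        assert is_reduced_cover(h)

    def test_empty_focal_rejected(self):
        with pytest.raises(ValueError):
            derive_ai_hypergraph(DirectedNetwork(["a"], [], []))


class TestReducedCover:
    @pytest.mark.parametrize(
        "variables,edges,expected",
        [
            ("ab", [["a", "b"], ["a"]], False),  # subset edge
            ("abc", [["a", "b"], ["c"]], True),
            ("abc", [["a", "b"]], False),  # c uncovered
            ("abc", [["a", "b"], ["b", "c"], ["c", "a"]], True),
        ],
    )
    def test_examples(self, variables, edges, expected):
        assert is_reduced_cover(Hypergraph(list(variables), edges)) is expected


class TestAcyclicity:
    def test_path_is_acyclic(self, path3):
        assert is_acyclic(path3)

    def test_triangle_is_cyclic(self, triangle):
        assert not is_acyclic(triangle)

    def test_two_overlapping_triples_acyclic(self):
        # GYO trace: drop solitary c and d, then one duplicate {a,b}, then all
        h = Hypergraph("abcd", [["a", "b", "c"], ["a", "b", "d"]])
        assert is_acyclic(h)

    def test_single_edge_acyclic(self):
        assert is_acyclic(Hypergraph("abc", [["a", "b", "c"]]))

    def test_reduction_confluence_and_isomorphism_invariance(self):
        rng = random.Random(7)
        for _ in range(100):
            n = rng.randint(2, 5)
            names = [f"l{i}" for i in range(n)]
            edges = set()
            while not edges or set().union(*edges) != set(names):
                k = rng.randint(1, n)
                edges.add(frozenset(rng.sample(names, k)))
            edges = [e for e in edges if not any(e < f for f in edges)]
            h = Hypergraph(names, edges)
            base = not graham_reduce(h)
            # confluence: random deletion scan orders agree
            for _ in range(3):
                order = list(range(len(h.edges)))
                rng.shuffle(order)
                assert (not graham_reduce(h, order)) == base
            # isomorphism invariance under a random relabeling
            perm = names[:]
            rng.shuffle(perm)
            relab = dict(zip(names, perm))
            h2 = Hypergraph(perm, [[relab[v] for v in e] for e in h.edges])
            assert is_acyclic(h2) == base


def brute_force_classes(n, min_edge_size):
    """Independent oracle: filter all subsets of the power set."""
    ground = list(range(n))
    subsets = [
        frozenset(c)
        for k in range(min_edge_size, n + 1)
        for c in itertools.combinations(ground, k)
    ]
    names = [f"l{i + 1}" for i in ground]
    forms = {}
    for mask in range(1, 2 ** len(subsets)):
        edges = [subsets[i] for i in range(len(subsets)) if mask >> i & 1]
        if set().union(*edges) != set(ground):
            continue
        if any(a < b for a, b in itertools.permutations(edges, 2)):
            continue
        h = Hypergraph(names, [[names[i] for i in e] for e in edges])
        form = canonical_form(h)
        forms[form] = forms.get(form, 0) + 1
    return forms


class TestEnumeration:
    def test_two_variables(self):
        classes = enumerate_architectures(2, 1)
        ids = {c.class_id for c in classes}
        assert ids == {"l1,l2", "l1;l2"}
        assert count_cyclic_classes(2, 1) == 0

    @pytest.mark.parametrize("n,mes", [(3, 1), (4, 2)])
    def test_against_brute_force_oracle(self, n, mes):
        oracle = brute_force_classes(n, mes)
        classes = enumerate_architectures(n, mes)
        got = {canonical_form(c.canonical): c.size for c in classes}
        assert got == oracle

    def test_three_variable_classes(self):
        classes = enumerate_architectures(3, 1)
        ids = {c.class_id for c in classes}
        assert "l1,l2,l3" in ids  # single 3-edge
        assert "l1;l2;l3" in ids  # all singletons
        assert "l1,l2;l1,l3;l2,l3" in ids  # triangle
        assert count_cyclic_classes(3, 1) == 1

    def test_nine_cyclic_classes_on_four_variables(self):
        assert count_cyclic_classes(4, 2) == 9

    def test_graph_architectures_cyclic_iff_three_or_more_variables(self):
        for n in (2, 3, 4):
            classes = enumerate_architectures(n, 1)
            graphs = [
                c for c in classes if all(len(e) <= 2 for e in c.canonical.edges)
            ]
            assert any(c.cyclic for c in graphs) == (n >= 3)

    def test_canonical_form_idempotent(self):
        for c in enumerate_architectures(4, 2):
            assert canonical_form(c.canonical) == canonical_form(c.canonical)
            # the canonical representative is already in canonical form
            idx = {v: i for i, v in enumerate(c.canonical.variables)}
            as_tuples = sorted(
                tuple(sorted(idx[v] for v in e)) for e in c.canonical.edges
            )
            as_tuples.sort(key=lambda t: (len(t), t))
            assert tuple(as_tuples) == canonical_form(c.canonical)

    def test_refusal_beyond_guard(self):
        with pytest.raises(ValueError, match="n <= 6"):
            enumerate_architectures(7, 1)

    @given(st.integers(min_value=2, max_value=4))
    def test_class_sizes_sum_to_labeled_count(self, n):
        classes = enumerate_architectures(n, n - 1)
        oracle = brute_force_classes(n, n - 1)
        assert sum(c.size for c in classes) == sum(oracle.values())


class TestHasse:
    def test_lattice_structure_three_variables(self):
        classes = enumerate_architectures(3, 1)
        covers = hasse_diagram(classes)
        by_id = {c.class_id: i for i, c in enumerate(classes)}
        top = by_id["l1,l2,l3"]
        bottom = by_id["l1;l2;l3"]
        tri = by_id["l1,l2;l1,l3;l2,l3"]
        # top has no outgoing cover, bottom no incoming
        assert all(i != top for i, _ in covers)
        assert all(j != bottom for _, j in covers)
        # reachability: bottom <= triangle <= top
        reach = {(i, j) for i, j in covers}
        closure = set(reach)
        changed = True
        while changed:
            changed = False
            for (a, b) in list(closure):
                for (c, d) in list(closure):
                    if b == c and (a, d) not in closure:
                        closure.add((a, d))
                        changed = True
        assert (tri, top) in closure
        assert (bottom, tri) in closure
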