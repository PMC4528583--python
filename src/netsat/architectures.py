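"""Hypergraph network architectures.

A *network architecture* records how a network context constrains a focal
subnetwork: the variables of the subnetwork form the vertex set ``L`` and each
hyperedge (module) ``O ⊆ L`` is one jointly-constrained subset — one
independent element of the context.  Architectures are required to be
*reduced covers*: every variable lies in at least one edge, and no edge is
contained in another (constraints on a subset of an already-constrained set
carry no extra information).

The central structural dichotomy is hypergraph acyclicity in the
Graham/GYO sense, the notion under which locally consistent edge marginals
always extend to a joint distribution.  Cyclic architectures admit
"frustrated" constraint families that are pairwise satisfiable but jointly
unsatisfiable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "Hypergraph",
    "DirectedNetwork",
    "ArchitectureClass",
    "derive_ai_hypergraph",
    "is_reduced_cover",
    "is_acyclic",
    "graham_reduce",
    "canonical_form",
    "enumerate_architectures",
    "count_cyclic_classes",
    "hasse_diagram",
]

MAX_ENUM_VARIABLES = 6


@dataclass(frozen=True)
class Hypergraph:
    """A hypergraph over named variables.

    Parameters
    ----------
    variables:
        Ordered distinct labels (the set ``L``).  Order is significant: it
        fixes row/column conventions downstream.
    edges:
        Non-empty subsets of the variables (the modules ``O``), kept in the
        order given.
    """

    variables: tuple[str, ...]
    edges: tuple[frozenset[str], ...]

    def __init__(self, variables: Iterable[str], edges: Iterable[Iterable[str]]):
        variables = tuple(variables)
        if len(set(variables)) != len(variables):
            raise ValueError("variables must be distinct")
        vset = set(variables)
        edges = tuple(frozenset(e) for e in edges)
        for e in edges:
            if not e:
                raise ValueError("edges must be non-empty")
            if not e <= vset:
                raise ValueError(f"edge {sorted(e)} references unknown variables")
        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "edges", edges)

    def edge_tuple(self, i: int) -> tuple[str, ...]:
        """Edge ``i`` as a tuple ordered consistently with ``variables``."""
        e = self.edges[i]
        return tuple(v for v in self.variables if v in e)

    def edge_label(self, i: int) -> str:
        return ",".join(self.edge_tuple(i))

    def __repr__(self) -> str:  # compact, deterministic
        es = ";".join(",".join(sorted(e)) for e in self.edges)
        return f"Hypergraph({','.join(self.variables)} | {es})"


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed interaction network with a designated focal subnetwork."""

    nodes: tuple[str, ...]
    arcs: tuple[tuple[str, str], ...]
    focal: tuple[str, ...]

    def __init__(self, nodes, arcs, focal):
        nodes = tuple(nodes)
        arcs = tuple((u, v) for u, v in arcs)
        focal = tuple(focal)
        nset = set(nodes)
        for u, v in arcs:
            if u not in nset or v not in nset:
                raise ValueError(f"arc ({u},{v}) references unknown node")
        if not set(focal) <= nset:
            raise ValueError("focal nodes must be a subset of nodes")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arcs", arcs)
        object.__setattr__(self, "focal", focal)


@dataclass(frozen=True)
class ArchitectureClass:
    """An isomorphism class of architectures under variable relabeling."""

    canonical: Hypergraph
    size: int  # number of labeled members of the class
    cyclic: bool

    @property
    def class_id(self) -> str:
        return ";".join(",".join(sorted(e)) for e in _sorted_edges(self.canonical))


def _sorted_edges(h: Hypergraph) -> list[frozenset[str]]:
    order = {v: i for i, v in enumerate(h.variables)}
    return sorted(h.edges, key=lambda e: (len(e), sorted(order[v] for v in e)))


# ---------------------------------------------------------------------------
# Abstract-influence derivation from a directed network
# ---------------------------------------------------------------------------

def derive_ai_hypergraph(network: DirectedNetwork) -> Hypergraph:
    """Collapse the network context of ``network.focal`` into a hypergraph.

    Each focal node's *context ancestors* are the non-focal nodes with a
    directed path to it.  Connected components of the induced ancestor
    subgraph (undirected connectivity, so shared upstream machinery is one
    influence) become abstract-influence nodes; each maps to the hyperedge of
    focal nodes it reaches.  Focal nodes with no context ancestors contribute
    singleton edges.  The result is reduced to an antichain cover.
    """
    if not network.focal:
        raise ValueError("focal subnetwork must be non-empty")
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.arcs)
    focal = list(network.focal)
    fset = set(focal)

    # context nodes with a path to each focal node (paths may pass anywhere;
    # focal-internal arcs are irrelevant to which context nodes have influence)
    ancestors: dict[str, set[str]] = {
        f: {a for a in nx.ancestors(g, f) if a not in fset} for f in focal
    }
    context = set().union(*ancestors.values()) if ancestors else set()
    comp_graph = g.subgraph(context).to_undirected()
    edges: list[frozenset[str]] = []
    for comp in nx.connected_components(comp_graph):
        influenced = frozenset(f for f in focal if ancestors[f] & comp)
        if influenced:
            edges.append(influenced)
    for f in focal:
        if not ancestors[f]:
            edges.append(frozenset({f}))
    edges = _reduce_antichain(edges)
    return Hypergraph(focal, edges)


def _reduce_antichain(edges: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    """Drop duplicate edges and edges contained in another edge."""
    uniq: list[frozenset[str]] = []
    for e in edges:
        if e not in uniq:
            uniq.append(e)
    return [e for e in uniq if not any(e < f for f in uniq)]


def is_reduced_cover(h: Hypergraph) -> bool:
    """True iff ``h`` covers every variable and its edges form an antichain."""
    covered = set().union(*h.edges) if h.edges else set()
    if covered != set(h.variables):
        return False
    if len(set(h.edges)) != len(h.edges):
        return False
    return not any(
        e < f for e, f in itertools.permutations(h.edges, 2)
    )


# ---------------------------------------------------------------------------
# Graham / GYO reduction and acyclicity
# ---------------------------------------------------------------------------

def graham_reduce(
    h: Hypergraph, order: Sequence[int] | None = None
) -> list[frozenset[str]]:
    """Run the Graham (GYO) reduction and return the residual edge list.

    Repeatedly (i) delete any variable occurring in exactly one edge and
    (ii) delete any edge that is a subset of another remaining edge (empty
    edges included).  The residual is empty exactly for acyclic hypergraphs;
    the reduction is confluent, so ``order`` (a permutation over edge indices
    used only to vary scan order) never changes emptiness of the result.
    """
    edges: list[set[str]] = [set(e) for e in h.edges]
    if order is not None:
        edges = [edges[i] for i in order]
    changed = True
    while changed and edges:
        changed = False
        counts: dict[str, int] = {}
        for e in edges:
            for v in e:
                counts[v] = counts.get(v, 0) + 1
        solitary = {v for v, c in counts.items() if c == 1}
        if solitary:
            for e in edges:
                if e & solitary:
                    e -= solitary
                    changed = True
        for i, e in enumerate(edges):
            if any(j != i and e <= f for j, f in enumerate(edges)):
                del edges[i]
                changed = True
                break
    if len(edges) == 1 and not edges[0]:
        edges = []
    return [frozenset(e) for e in edges]


def is_acyclic(h: Hypergraph) -> bool:
    """Graham/GYO acyclicity: the reduction empties the hypergraph.

    This is the acyclicity notion under which local consistency of edge
    marginals implies global consistency (existence of a joint extension).
    """
    return not graham_reduce(h)


# ---------------------------------------------------------------------------
# Enumeration of architecture classes
# ---------------------------------------------------------------------------

def canonical_form(h: Hypergraph) -> tuple[tuple[int, ...], ...]:
    """Lexicographically minimal sorted edge list over all variable relabelings.

    Variables are mapped to indices ``0..n-1``; the canonical form is the
    minimum, over all permutations, of the sorted tuple of sorted edge tuples
    (edges keyed by size then lexicographic content).
    """
    n = len(h.variables)
    idx = {v: i for i, v in enumerate(h.variables)}
    base = [frozenset(idx[v] for v in e) for e in h.edges]
    best = None
    for perm in itertools.permutations(range(n)):
        relab = sorted(
            tuple(sorted(perm[i] for i in e)) for e in base
        )
        relab.sort(key=lambda t: (len(t), t))
        key = tuple(relab)
        if best is None or key < best:
            best = key
    return best


def _canonical_hypergraph(n: int, form: tuple[tuple[int, ...], ...]) -> Hypergraph:
    names = [f"l{i + 1}" for i in range(n)]
    return Hypergraph(names, [[names[i] for i in e] for e in form])


def _antichain_covers(
    n: int, min_edge_size: int
) -> Iterable[tuple[frozenset[int], ...]]:
    """All antichain covers of {0..n-1} with edges of size >= min_edge_size.

    Recursive inclusion/exclusion over candidate edges ordered by decreasing
    size, pruning branches that can no longer cover the ground set.
    """
    universe = frozenset(range(n))
    candidates = sorted(
        (frozenset(c)
         for k in range(min_edge_size, n + 1)
         for c in itertools.combinations(range(n), k)),
        key=lambda e: (-len(e), sorted(e)),
    )
    # suffix_union[i]: what the candidates from i onward can still cover
    suffix_union = [frozenset()] * (len(candidates) + 1)
    for i in range(len(candidates) - 1, -1, -1):
        suffix_union[i] = suffix_union[i + 1] | candidates[i]

    chosen: list[frozenset[int]] = []

    def rec(i: int, covered: frozenset[int]):
        if i == len(candidates):
            if covered == universe and chosen:
                yield tuple(chosen)
            return
        if not (covered | suffix_union[i]) >= universe:
            return
        # exclude candidates[i]
        yield from rec(i + 1, covered)
        # include it, if the antichain property survives (candidates are in
        # decreasing size order, so only containment in a chosen edge can occur)
        e = candidates[i]
        if not any(e <= f for f in chosen):
            chosen.append(e)
            yield from rec(i + 1, covered | e)
            chosen.pop()

    yield from rec(0, frozenset())


def enumerate_architectures(
    n: int, min_edge_size: int = 1
) -> list[ArchitectureClass]:
    """Enumerate isomorphism classes of reduced covers on ``n`` variables.

    Every labeled antichain cover with all edges of size >= ``min_edge_size``
    is generated and grouped by canonical form; each class carries its
    labeled-member count and its Graham/GYO cyclicity flag.  Classes are
    returned sorted by (edge count, canonical form) for stable output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > MAX_ENUM_VARIABLES:
        raise ValueError(
            f"enumeration is limited to n <= {MAX_ENUM_VARIABLES} variables "
            f"(got n={n}); the search over antichain covers is combinatorial"
        )
    if min_edge_size < 1:
        raise ValueError("min_edge_size must be >= 1")
    names = [f"l{i + 1}" for i in range(n)]
    counts: dict[tuple, int] = {}
    for cover in _antichain_covers(n, min_edge_size):
        h = Hypergraph(names, [[names[i] for i in e] for e in cover])
        counts[canonical_form(h)] = counts.get(canonical_form(h), 0) + 1
    classes = []
    for form, size in counts.items():
        h = _canonical_hypergraph(n, form)
        classes.append(ArchitectureClass(h, size, cyclic=not is_acyclic(h)))
    classes.sort(key=lambda c: (len(c.canonical.edges), canonical_form(c.canonical)))
    return classes


def count_cyclic_classes(n: int, min_edge_size: int = 1) -> int:
    """Number of enumerated classes whose canonical hypergraph is cyclic."""
    return sum(c.cyclic for c in enumerate_architectures(n, min_edge_size))


# ---------------------------------------------------------------------------
# Lattice of architectures
# ---------------------------------------------------------------------------

def _refines(a: Hypergraph, b: Hypergraph) -> bool:
    """A <= B iff some relabeling sends every edge of A inside an edge of B."""
    n = len(a.variables)
    idx_a = {v: i for i, v in enumerate(a.variables)}
    idx_b = {v: i for i, v in enumerate(b.variables)}
    ea = [frozenset(idx_a[v] for v in e) for e in a.edges]
    eb = [frozenset(idx_b[v] for v in e) for e in b.edges]
    for perm in itertools.permutations(range(n)):
        mapped = [frozenset(perm[i] for i in e) for e in ea]
        if all(any(m <= f for f in eb) for m in mapped):
            return True
    return False


def hasse_diagram(
    classes: Sequence[ArchitectureClass],
) -> list[tuple[int, int]]:
    """Covering pairs (i, j) of the refinement order: classes[i] < classes[j].

    The order is edge-wise refinement up to isomorphism: A <= B when every
    edge of A is contained in some edge of B under the best relabeling.
    Covering pairs are the transitive reduction of the strict order.
    """
    m = len(classes)
    less = [[False] * m for _ in range(m)]
    for i in range(m):
        for j in range(m):
            if i != j and _refines(classes[i].canonical, classes[j].canonical):
                less[i][j] = True
    covers = []
    for i in range(m):
        for j in range(m):
            if less[i][j] and not any(
                less[i][k] and less[k][j] for k in range(m)
            ):
                covers.append((i, j))
    return covers
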