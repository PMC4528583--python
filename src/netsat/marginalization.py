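"""Marginalization operators and their fundamental subspaces.

Coarse-grained network states live on a finite state space: each variable
``l_i`` takes values in a finite level set ``P_i``, and a joint state is a
function ``e: L -> P``.  Marginalizing a joint distribution ``x`` over all
variables down to the hyperedges of an architecture is a linear map
``v = G x`` where ``G`` is a 0/1 matrix with one row per (edge, edge-state)
pair and one column per joint state.

Consistency of an edge-marginal family ``v`` is governed by the fundamental
subspaces of ``G`` over the rationals:

* ``u . v = 0`` for every ``u`` in coker(G) is exactly *local* consistency —
  shared sub-marginals agree and the edge tables carry equal total mass;
* feasibility of ``{G x = v, x >= 0}`` is *global* consistency, analysed via
  ker(G) and a transverse complement (see :mod:`netsat.consistency`).

All subspace computation here is exact rational (sympy / fractions): the
consistency conditions are exact linear identities and must not flip on
floating-point rounding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import sympy

from .architectures import Hypergraph, is_reduced_cover

__all__ = [
    "StateSpace",
    "MarginalizationOperator",
    "LinearSubspaceBasis",
    "LinearEquality",
    "build_marginalization_matrix",
    "fundamental_subspaces",
    "local_consistency_conditions",
    "transverse_complement",
]


@dataclass(frozen=True)
class StateSpace:
    """Finite per-variable level sets with lexicographic joint indexing.

    The joint-state index runs lexicographically with the *first* variable
    slowest, i.e. ``itertools.product`` order over the per-variable level
    sets.
    """

    variables: tuple[str, ...]
    levels: tuple[tuple[Hashable, ...], ...]

    def __init__(self, variables: Iterable[str], levels):
        variables = tuple(variables)
        if isinstance(levels, Mapping):
            levels = tuple(tuple(levels[v]) for v in variables)
        else:
            levels = tuple(tuple(l) for l in levels)
        if len(levels) != len(variables):
            raise ValueError("one level set per variable required")
        for v, ls in zip(variables, levels):
            if len(ls) < 2:
                raise ValueError(f"variable {v} needs >= 2 levels")
            if len(set(ls)) != len(ls):
                raise ValueError(f"duplicate levels for variable {v}")
        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "levels", levels)

    @classmethod
    def binary(cls, variables: Iterable[str]) -> "StateSpace":
        variables = tuple(variables)
        return cls(variables, [(0, 1)] * len(variables))

    def levels_of(self, var: str) -> tuple:
        return self.levels[self.variables.index(var)]

    @property
    def n_joint_states(self) -> int:
        out = 1
        for ls in self.levels:
            out *= len(ls)
        return out

    def joint_states(self) -> list[tuple]:
        return list(itertools.product(*self.levels))

    def edge_variables(self, edge: Iterable[str]) -> tuple[str, ...]:
        e = set(edge)
        return tuple(v for v in self.variables if v in e)

    def edge_states(self, edge: Iterable[str]) -> list[tuple]:
        """States of a sub-collection of variables, same lexicographic rule."""
        evars = self.edge_variables(edge)
        return list(itertools.product(*(self.levels_of(v) for v in evars)))

    def restrict(self, joint_state: Sequence, edge: Iterable[str]) -> tuple:
        """Restriction of a joint state to the variables of ``edge``."""
        e = set(edge)
        return tuple(s for v, s in zip(self.variables, joint_state) if v in e)


@dataclass(frozen=True)
class MarginalizationOperator:
    """The 0/1 matrix ``G`` mapping joint distributions to edge marginals.

    Rows are indexed by (edge index, edge state) in edge order then
    lexicographic state order; columns by joint states, lexicographically.
    """

    space: StateSpace
    hypergraph: Hypergraph
    matrix: np.ndarray  # int8, shape (n_rows, n_joint_states)
    row_index: tuple[tuple[int, tuple], ...]  # (edge index, edge state)
    col_index: tuple[tuple, ...]  # joint states

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_labels(self) -> list[str]:
        h = self.hypergraph
        return [
            f"{h.edge_label(ei)}|{''.join(map(str, st))}"
            for ei, st in self.row_index
        ]

    def col_labels(self) -> list[str]:
        return ["".join(map(str, st)) for st in self.col_index]

    def as_sympy(self) -> sympy.Matrix:
        return sympy.Matrix(self.matrix.tolist())

    def apply(self, x: Sequence) -> list:
        """Exact matrix-vector product (works for Fractions and floats)."""
        m = self.matrix
        return [
            sum(xj for gij, xj in zip(row, x) if gij) for row in m
        ]

    def to_frame(self):
        """Dense labeled export for debugging (pandas DataFrame)."""
        import pandas as pd

        return pd.DataFrame(
            self.matrix, index=self.row_labels(), columns=self.col_labels()
        )


@dataclass(frozen=True)
class LinearSubspaceBasis:
    """A basis of exact rational vectors with a declared role."""

    vectors: tuple[tuple[Fraction, ...], ...]
    role: str  # "kernel" | "cokernel" | "transverse"

    @property
    def dim(self) -> int:
        return len(self.vectors)


@dataclass(frozen=True)
class LinearEquality:
    """An equality ``sum_i coefficients[i] * v[i] = rhs`` over labeled coords."""

    coefficients: tuple[Fraction, ...]
    rhs: Fraction
    label: str = ""


def build_marginalization_matrix(
    space: StateSpace, h: Hypergraph
) -> MarginalizationOperator:
    """Construct ``G``: entry ((O, s), e) = 1 iff ``e`` restricted to O is s."""
    unknown = set().union(*h.edges) - set(space.variables)
    if unknown:
        raise ValueError(f"hypergraph uses variables not in the state space: {sorted(unknown)}")
    joint = space.joint_states()
    row_index: list[tuple[int, tuple]] = []
    for ei in range(len(h.edges)):
        for st in space.edge_states(h.edges[ei]):
            row_index.append((ei, st))
    mat = np.zeros((len(row_index), len(joint)), dtype=np.int8)
    row_of = {key: r for r, key in enumerate(row_index)}
    for c, e in enumerate(joint):
        for ei in range(len(h.edges)):
            r = row_of[(ei, space.restrict(e, h.edges[ei]))]
            mat[r, c] = 1
    return MarginalizationOperator(
        space, h, mat, tuple(row_index), tuple(joint)
    )


def _sympy_to_fraction_vec(v: sympy.Matrix) -> tuple[Fraction, ...]:
    return tuple(Fraction(int(x.p), int(x.q)) for x in (sympy.Rational(e) for e in v))


def fundamental_subspaces(
    G: MarginalizationOperator,
) -> tuple[LinearSubspaceBasis, LinearSubspaceBasis]:
    """Exact rational bases of ker(G) and coker(G).

    dim ker + rank = number of columns; dim coker + rank = number of rows.
    """
    M = G.as_sympy()
    kernel = tuple(_sympy_to_fraction_vec(v) for v in M.nullspace())
    cokernel = tuple(_sympy_to_fraction_vec(v) for v in M.T.nullspace())
    return (
        LinearSubspaceBasis(kernel, "kernel"),
        LinearSubspaceBasis(cokernel, "cokernel"),
    )


def local_consistency_conditions(
    space: StateSpace, h: Hypergraph
) -> list[LinearEquality]:
    """Local consistency equalities over the edge-marginal coordinates.

    For every unordered pair of edges with non-empty intersection ``S`` and
    every state of ``S``, the two marginalizations onto ``S`` must agree;
    additionally each edge table must sum to 1.  Coordinates are ordered as
    the rows of the marginalization operator.
    """
    if not is_reduced_cover(h):
        raise ValueError("hypergraph must be a reduced cover")
    G = build_marginalization_matrix(space, h)
    ncoord = G.shape[0]
    pos = {key: r for r, key in enumerate(G.row_index)}
    conditions: list[LinearEquality] = []
    for ei in range(len(h.edges)):
        coeff = [Fraction(0)] * ncoord
        for st in space.edge_states(h.edges[ei]):
            coeff[pos[(ei, st)]] = Fraction(1)
        conditions.append(
            LinearEquality(tuple(coeff), Fraction(1), f"norm[{h.edge_label(ei)}]")
        )
    for ei, ej in itertools.combinations(range(len(h.edges)), 2):
        shared = h.edges[ei] & h.edges[ej]
        if not shared:
            continue
        svars = space.edge_variables(shared)
        for sstate in space.edge_states(shared):
            coeff = [Fraction(0)] * ncoord
            for st in space.edge_states(h.edges[ei]):
                if space_restrict_edge(space, h.edges[ei], st, svars) == sstate:
                    coeff[pos[(ei, st)]] += Fraction(1)
            for st in space.edge_states(h.edges[ej]):
                if space_restrict_edge(space, h.edges[ej], st, svars) == sstate:
                    coeff[pos[(ej, st)]] -= Fraction(1)
            label = (
                f"overlap[{h.edge_label(ei)}~{h.edge_label(ej)}|"
                f"{''.join(map(str, sstate))}]"
            )
            conditions.append(LinearEquality(tuple(coeff), Fraction(0), label))
    return conditions


def space_restrict_edge(
    space: StateSpace,
    edge: Iterable[str],
    edge_state: tuple,
    subset_vars: tuple[str, ...],
) -> tuple:
    """Restrict an edge state to a subset of the edge's variables."""
    evars = space.edge_variables(edge)
    lookup = dict(zip(evars, edge_state))
    return tuple(lookup[v] for v in subset_vars)


def transverse_complement(G: MarginalizationOperator) -> LinearSubspaceBasis:
    """A coordinate-subspace complement ``T`` of ker(G).

    Pivot columns of the reduced row-echelon form of ``G`` index the
    coordinates spanning ``T`` (free columns zeroed), so ``v = G x`` has a
    unique solution with ``x in T`` whenever it has any.
    """
    _, pivots = G.as_sympy().rref()
    ncols = G.shape[1]
    vectors = []
    for p in pivots:
        vec = [Fraction(0)] * ncols
        vec[p] = Fraction(1)
        vectors.append(tuple(vec))
    return LinearSubspaceBasis(tuple(vectors), "transverse")
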