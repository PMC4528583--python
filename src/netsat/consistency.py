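"""Local and global consistency of edge-marginal families.

An :class:`EdgeMarginalFamily` assigns one probability table per hyperedge of
an architecture.  It is *locally consistent* (a point of the local polytope
L(G)) when tables agree on every shared variable subset; it is *globally
consistent* (a point of the marginal polytope M(G)) when a single joint
distribution over all variables has every table as a marginal.  Global
consistency always implies local consistency; the converse holds exactly for
Graham/GYO-acyclic architectures, where a junction-tree factorization
constructs an explicit joint witness.  For cyclic architectures the gap is
witnessed by "frustrated" families such as perfect pairwise anticorrelation
around a triangle.

Global consistency is decided as feasibility of ``{G x = v, x >= 0}``
(normalization is implied because each edge block of ``G x`` sums to
``sum x``).  The inequality description of M(G) in the marginal coordinates
alone is derived by Fourier-Motzkin elimination of the kernel coefficients
after solving ``v = G x`` on a transverse complement of ker(G).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from fractions import Fraction
from math import gcd
from numbers import Rational
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from ._simplex import exact_feasible_point
from .architectures import Hypergraph, is_acyclic
from .marginalization import (
    LinearEquality,
    StateSpace,
    build_marginalization_matrix,
    fundamental_subspaces,
    local_consistency_conditions,
    space_restrict_edge,
)

__all__ = [
    "EdgeMarginalFamily",
    "JointDistribution",
    "LinearInequality",
    "PolytopeDescription",
    "ConsistencyReport",
    "local_polytope",
    "is_locally_consistent",
    "is_globally_consistent",
    "extend_acyclic",
    "global_inequalities",
    "minimal_inequality_set",
    "check_family",
]

EXACT_JOINT_LIMIT = 256
ELIMINATION_JOINT_LIMIT = 64
FLOAT_TOL = 1e-9


@dataclass(frozen=True)
class EdgeMarginalFamily:
    """One probability table per hyperedge: a candidate point of L(G)/M(G).

    ``tables[i]`` maps each state of edge ``i`` (lexicographic over the
    edge's variables in state-space order) to its probability, as exact
    rationals or floats.
    """

    architecture: Hypergraph
    space: StateSpace
    tables: tuple[Mapping[tuple, object], ...]

    def __post_init__(self):
        if len(self.tables) != len(self.architecture.edges):
            raise ValueError("one table per edge required")
        for ei, table in enumerate(self.tables):
            states = self.space.edge_states(self.architecture.edges[ei])
            if set(table) != set(states):
                raise ValueError(
                    f"table for edge {self.architecture.edge_label(ei)} must "
                    "cover exactly the edge's states"
                )

    @property
    def exact(self) -> bool:
        return all(
            isinstance(x, Rational) for t in self.tables for x in t.values()
        )

    def as_vector(self) -> list:
        """Concatenated tables in marginalization row order."""
        out = []
        for ei, table in enumerate(self.tables):
            for st in self.space.edge_states(self.architecture.edges[ei]):
                out.append(table[st])
        return out

    @classmethod
    def from_vector(cls, space: StateSpace, h: Hypergraph, vec: Sequence):
        tables = []
        k = 0
        for ei in range(len(h.edges)):
            states = space.edge_states(h.edges[ei])
            tables.append(dict(zip(states, vec[k:k + len(states)])))
            k += len(states)
        if k != len(vec):
            raise ValueError("vector length does not match edge state counts")
        return cls(h, space, tuple(tables))

    @classmethod
    def uniform(cls, space: StateSpace, h: Hypergraph) -> "EdgeMarginalFamily":
        tables = []
        for e in h.edges:
            states = space.edge_states(e)
            p = Fraction(1, len(states))
            tables.append({st: p for st in states})
        return cls(h, space, tuple(tables))

    def table_marginal(self, ei: int, subset: Iterable[str]) -> dict:
        """Marginal of edge ``ei``'s table onto a subset of its variables."""
        svars = self.space.edge_variables(subset)
        out: dict[tuple, object] = {}
        for st, p in self.tables[ei].items():
            key = space_restrict_edge(self.space, self.architecture.edges[ei], st, svars)
            out[key] = out.get(key, 0) + p
        return out


@dataclass(frozen=True)
class JointDistribution:
    """A distribution over all joint states (the vector x, or a witness y)."""

    space: StateSpace
    weights: tuple  # aligned with space.joint_states()

    def __post_init__(self):
        if len(self.weights) != self.space.n_joint_states:
            raise ValueError("one weight per joint state required")

    @classmethod
    def uniform(cls, space: StateSpace) -> "JointDistribution":
        n = space.n_joint_states
        return cls(space, tuple([Fraction(1, n)] * n))

    def marginal_family(self, h: Hypergraph) -> EdgeMarginalFamily:
        """Exact marginals of this joint on each hyperedge."""
        G = build_marginalization_matrix(self.space, h)
        return EdgeMarginalFamily.from_vector(
            self.space, h, G.apply(self.weights)
        )


@dataclass(frozen=True)
class LinearInequality:
    """``sum_i coefficients[i] * v[i] >= rhs`` over the marginal coordinates."""

    coefficients: tuple[Fraction, ...]
    rhs: Fraction
    label: str = ""


@dataclass(frozen=True)
class PolytopeDescription:
    """H-representation of L(G) (role='local') or M(G) (role='global')."""

    coordinates: tuple[str, ...]
    equalities: tuple[LinearEquality, ...]
    inequalities: tuple[LinearInequality, ...]
    role: str

    def contains(self, vec: Sequence, tol: float = 0.0) -> bool:
        for eq in self.equalities:
            val = sum(c * x for c, x in zip(eq.coefficients, vec) if c)
            if abs(val - eq.rhs) > tol:
                return False
        for iq in self.inequalities:
            val = sum(c * x for c, x in zip(iq.coefficients, vec) if c)
            if val < iq.rhs - tol:
                return False
        return True


@dataclass(frozen=True)
class ConsistencyReport:
    local: bool
    global_: bool
    witness: JointDistribution | None
    violated: tuple[str, ...] = ()


def local_polytope(space: StateSpace, h: Hypergraph) -> PolytopeDescription:
    """L(G): local equalities plus non-negativity of every coordinate."""
    G = build_marginalization_matrix(space, h)
    conds = local_consistency_conditions(space, h)
    n = G.shape[0]
    ineqs = []
    for i, lab in enumerate(G.row_labels()):
        coeff = [Fraction(0)] * n
        coeff[i] = Fraction(1)
        ineqs.append(LinearInequality(tuple(coeff), Fraction(0), f"nonneg[{lab}]"))
    return PolytopeDescription(
        tuple(G.row_labels()), tuple(conds), tuple(ineqs), "local"
    )


def is_locally_consistent(
    v: EdgeMarginalFamily, tol: float | None = None
) -> bool:
    """Check all shared-subset agreements and per-edge normalizations.

    ``tol`` defaults to 0 for exact rational tables and 1e-9 for floats.
    """
    if tol is None:
        tol = 0 if v.exact else FLOAT_TOL
    conds = local_consistency_conditions(v.space, v.architecture)
    vec = v.as_vector()
    for eq in conds:
        val = sum(c * x for c, x in zip(eq.coefficients, vec) if c)
        if abs(val - eq.rhs) > tol:
            return False
    return True


def is_globally_consistent(
    v: EdgeMarginalFamily, tol: float = FLOAT_TOL
) -> tuple[bool, JointDistribution | None]:
    """Feasibility of ``{G x = v, x >= 0}``; returns a joint witness if any.

    Exact rational Phase-I simplex when the tables are exact rationals and
    the joint state count is at most 256; otherwise a float LP minimizing the
    L1 residual of ``G x = v`` (feasible iff the optimum is below ``tol``,
    which absorbs the rounding already present in float input).
    """
    G = build_marginalization_matrix(v.space, v.architecture)
    vec = v.as_vector()
    if v.exact and G.shape[1] <= EXACT_JOINT_LIMIT:
        A = [[Fraction(int(g)) for g in row] for row in G.matrix]
        b = [Fraction(x) for x in vec]
        x = exact_feasible_point(A, b)
        if x is None:
            return False, None
        return True, JointDistribution(v.space, tuple(x))
    m, n = G.shape
    # min 1.s  s.t.  G x + s+ - s- = v,  x, s+/- >= 0
    A_eq = np.hstack([G.matrix.astype(float), np.eye(m), -np.eye(m)])
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    res = linprog(c, A_eq=A_eq, b_eq=np.asarray(vec, dtype=float),
                  bounds=(0, None), method="highs")
    if res.status != 0:  # pragma: no cover - HiGHS always solves this form
        raise RuntimeError(f"LP solver failure: {res.message}")
    if res.fun > tol:
        return False, None
    x = np.clip(res.x[:n], 0, None)
    total = x.sum()
    if total > 0:
        x = x / total
    return True, JointDistribution(v.space, tuple(x.tolist()))


# ---------------------------------------------------------------------------
# Constructive extension on acyclic architectures
# ---------------------------------------------------------------------------

def _junction_tree(h: Hypergraph) -> list[tuple[int, int | None]]:
    """BFS-ordered (edge, parent) pairs of a junction tree of ``h``.

    Maximum-weight spanning tree of the complete edge-intersection graph;
    for a reduced Graham-acyclic hypergraph (the maximal cliques of a
    chordal graph) this satisfies the running-intersection property.
    """
    m = len(h.edges)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    for i, j in itertools.combinations(range(m), 2):
        g.add_edge(i, j, weight=len(h.edges[i] & h.edges[j]))
    tree = nx.maximum_spanning_tree(g) if m > 1 else g
    order: list[tuple[int, int | None]] = [(0, None)]
    seen = {0}
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for nb in sorted(tree.neighbors(cur)):
            if nb not in seen:
                seen.add(nb)
                order.append((nb, cur))
                queue.append(nb)
    return order


def extend_acyclic(v: EdgeMarginalFamily) -> JointDistribution:
    """Joint witness for a locally consistent family on an acyclic architecture.

    Assembles the joint as a product of conditionals along a junction tree
    (equivalently, a Graham-reduction elimination order):
    ``x(e) = p_root(e) * prod_children p_child(e) / p_sep(e)``, with 0/0 = 0.
    The result reproduces every table exactly.
    """
    h, space = v.architecture, v.space
    if not is_acyclic(h):
        raise ValueError("not acyclic: a joint extension may not exist")
    if not is_locally_consistent(v):
        raise ValueError("family is not locally consistent")
    order = _junction_tree(h)
    sep_marginals: dict[int, tuple[tuple[str, ...], dict]] = {}
    for ei, parent in order:
        if parent is None:
            continue
        sep = h.edges[ei] & h.edges[parent]
        svars = space.edge_variables(sep)
        sep_marginals[ei] = (svars, v.table_marginal(ei, sep))
    weights = []
    for e in space.joint_states():
        w = v.tables[order[0][0]][space.restrict(e, h.edges[order[0][0]])]
        for ei, parent in order[1:]:
            num = v.tables[ei][space.restrict(e, h.edges[ei])]
            svars, smarg = sep_marginals[ei]
            den = smarg[space.restrict(e, svars)] if svars else 1
            if den == 0:
                w = 0 * w
                break
            w = w * num / den
        weights.append(w)
    joint = JointDistribution(space, tuple(weights))
    # defensive exact check: the factorization must reproduce v
    check = joint.marginal_family(h).as_vector()
    vec = v.as_vector()
    tol = 0 if v.exact else 1e-8
    if any(abs(a - b) > tol for a, b in zip(check, vec)):
        raise AssertionError("junction-tree extension failed to reproduce v")
    return joint


# ---------------------------------------------------------------------------
# Fourier-Motzkin derivation of the marginal polytope
# ---------------------------------------------------------------------------

def _normalize_int_row(coeffs: Iterable[Fraction]) -> tuple[int, ...]:
    """Scale a rational row to coprime integers (canonical up to sign)."""
    fracs = [Fraction(c) for c in coeffs]
    lcm = 1
    for f in fracs:
        lcm = lcm * f.denominator // gcd(lcm, f.denominator)
    ints = [int(f * lcm) for f in fracs]
    g = 0
    for x in ints:
        g = gcd(g, abs(x))
    if g > 1:
        ints = [x // g for x in ints]
    return tuple(ints)


def global_inequalities(
    space: StateSpace,
    h: Hypergraph,
    column_order: Sequence[int] | None = None,
) -> PolytopeDescription:
    """H-representation of M(G) in marginal coordinates alone.

    Solves ``v = G x`` uniquely on a transverse complement of ker(G) (free
    coordinates zeroed), writes every candidate joint as
    ``y = x(v) + sum_j c_j k_j`` over a kernel basis ``{k_j}``, and
    Fourier-Motzkin-eliminates the ``c_j`` from ``y >= 0``.  The equalities
    are the cokernel (local-consistency) conditions plus one normalization.

    ``column_order`` permutes the joint-state columns before pivoting, which
    selects a different transverse complement; the described feasible set
    does not depend on this choice.
    """
    G = build_marginalization_matrix(space, h)
    m, n = G.shape
    if n > ELIMINATION_JOINT_LIMIT:
        raise ValueError(
            f"joint state count {n} exceeds the elimination guard "
            f"({ELIMINATION_JOINT_LIMIT}); use is_globally_consistent (LP "
            "membership) instead"
        )
    import sympy

    order = list(column_order) if column_order is not None else list(range(n))
    if sorted(order) != list(range(n)):
        raise ValueError("column_order must be a permutation of the joint states")
    mat = G.matrix[:, order]
    aug = sympy.Matrix(mat.tolist()).row_join(sympy.eye(m))
    R, pivots = aug.rref()
    pivots = [p for p in pivots if p < n]
    r = len(pivots)

    def frac(x) -> Fraction:
        q = sympy.Rational(x)
        return Fraction(int(q.p), int(q.q))

    # x(v): pivot coordinate p_t carries row t of the transform E
    # (indices are in the permuted column order; only the inequality set
    # matters, and it is invariant to the relabeling of eliminated joints)
    xrows: dict[int, list[Fraction]] = {}
    for t, p in enumerate(pivots):
        xrows[p] = [frac(R[t, n + j]) for j in range(m)]
    kernel, _ = fundamental_subspaces(G)
    k = kernel.dim
    # rows: (v-part | c-part) with the inequality  row . (v, c) >= 0;
    # kernel coordinates follow the same column permutation as x
    rows: set[tuple[int, ...]] = set()
    for i in range(n):
        vpart = xrows.get(i, [Fraction(0)] * m)
        cpart = [kernel.vectors[j][order[i]] for j in range(k)]
        if any(vpart) or any(cpart):
            rows.add(_normalize_int_row(list(vpart) + cpart))
    # eliminate c variables right-to-left
    for cv in range(m + k - 1, m - 1, -1):
        pos, neg, keep = [], [], []
        for row in rows:
            if row[cv] > 0:
                pos.append(row)
            elif row[cv] < 0:
                neg.append(row)
            else:
                keep.append(row[:cv] + row[cv + 1:])
        new = set(keep)
        for rp in pos:
            for rn in neg:
                comb = [
                    Fraction(-rn[cv] * rp[j] + rp[cv] * rn[j])
                    for j in range(cv)
                ]
                if any(comb):
                    new.add(_normalize_int_row(comb))
        rows = new
    ineqs = []
    for idx, row in enumerate(sorted(rows)):
        ineqs.append(
            LinearInequality(
                tuple(Fraction(x) for x in row), Fraction(0), f"fm[{idx}]"
            )
        )
    # cokernel rows of the augmented rref (zero G-part) are the local equalities
    eqs: list[LinearEquality] = []
    for t in range(R.rows):
        if all(R[t, j] == 0 for j in range(n)):
            coeff = tuple(frac(R[t, n + j]) for j in range(m))
            if any(coeff):
                eqs.append(LinearEquality(coeff, Fraction(0), f"coker[{t}]"))
    norm = [Fraction(0)] * m
    for rpos, (ei, _) in enumerate(G.row_index):
        if ei == 0:
            norm[rpos] = Fraction(1)
    eqs.append(LinearEquality(tuple(norm), Fraction(1), "norm"))
    return PolytopeDescription(
        tuple(G.row_labels()), tuple(eqs), tuple(ineqs), "global"
    )


def minimal_inequality_set(p: PolytopeDescription) -> PolytopeDescription:
    """Drop every inequality implied by the remaining ones plus the equalities.

    Sequential LP redundancy test: inequality ``a.v >= b`` is redundant when
    minimizing ``a.v`` subject to the rest cannot go below ``b`` (within a
    1e-9 slack).  Unbounded or failed subproblems keep the inequality.
    """
    n = len(p.coordinates)
    A_eq = np.array([[float(c) for c in eq.coefficients] for eq in p.equalities])
    b_eq = np.array([float(eq.rhs) for eq in p.equalities])
    active = list(p.inequalities)
    i = 0
    while i < len(active):
        trial = active[:i] + active[i + 1:]
        A_ub = np.array(
            [[-float(c) for c in iq.coefficients] for iq in trial]
        ) if trial else None
        b_ub = np.array([-float(iq.rhs) for iq in trial]) if trial else None
        c = np.array([float(x) for x in active[i].coefficients])
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub,
            A_eq=A_eq if len(p.equalities) else None,
            b_eq=b_eq if len(p.equalities) else None,
            bounds=(None, None), method="highs",
        )
        if res.status == 0 and res.fun >= float(active[i].rhs) - 1e-9:
            active.pop(i)  # redundant
        else:
            i += 1
    return replace(p, inequalities=tuple(active))


def check_family(v: EdgeMarginalFamily) -> ConsistencyReport:
    """Full report: local flag, global flag, witness, violated inequalities."""
    local = is_locally_consistent(v)
    feasible, witness = is_globally_consistent(v)
    violated: tuple[str, ...] = ()
    if not feasible and v.space.n_joint_states <= ELIMINATION_JOINT_LIMIT:
        desc = global_inequalities(v.space, v.architecture)
        vec = v.as_vector()
        tol = 0 if v.exact else FLOAT_TOL
        bad = []
        for iq in desc.inequalities:
            val = sum(c * x for c, x in zip(iq.coefficients, vec) if c)
            if val < iq.rhs - tol:
                bad.append(iq.label)
        violated = tuple(bad)
    return ConsistencyReport(local, feasible, witness, violated)
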