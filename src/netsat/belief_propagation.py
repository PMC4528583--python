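"""Loopy belief propagation (sum-product) on architecture factor graphs.

Treating each hyperedge's probability table as a factor gives a factor graph
whose sum-product fixed points are the "ostensible" marginals an observer
would infer from per-edge measurements.  On acyclic architectures BP is
exact; on cyclic ones its edge beliefs can sit away from the marginals of
every joint distribution — the algorithmic face of local-without-global
consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .consistency import EdgeMarginalFamily

__all__ = [
    "FactorGraph",
    "BeliefResult",
    "factor_graph_from_family",
    "sum_product",
    "compare_marginals",
    "total_variation",
]


@dataclass(frozen=True)
class FactorGraph:
    """Bipartite variable/factor graph with non-negative factor tables.

    ``factors[i] = (vars, table)`` where ``table`` has one axis per variable
    in ``vars`` (axis length = that variable's level count).
    """

    variables: tuple[str, ...]
    levels: tuple[int, ...]  # level count per variable
    factors: tuple[tuple[tuple[str, ...], np.ndarray], ...]

    def __post_init__(self):
        nl = dict(zip(self.variables, self.levels))
        for fvars, table in self.factors:
            if table.shape != tuple(nl[v] for v in fvars):
                raise ValueError(f"factor over {fvars} has wrong shape {table.shape}")
            if np.any(table < 0) or not np.any(table > 0):
                raise ValueError(f"factor over {fvars} must be non-negative and not all-zero")

    def var_index(self, v: str) -> int:
        return self.variables.index(v)


@dataclass(frozen=True)
class BeliefResult:
    node_beliefs: Mapping[str, np.ndarray]
    edge_beliefs: tuple[np.ndarray, ...]
    converged: bool
    iterations: int
    residual: float


def factor_graph_from_family(v: EdgeMarginalFamily) -> FactorGraph:
    """Use each edge's marginal table itself as that edge's factor."""
    space = v.space
    h = v.architecture
    levels = tuple(len(ls) for ls in space.levels)
    factors = []
    for ei, table in enumerate(v.tables):
        evars = space.edge_variables(h.edges[ei])
        shape = tuple(len(space.levels_of(x)) for x in evars)
        arr = np.zeros(shape)
        for st, p in table.items():
            idx = tuple(space.levels_of(x).index(s) for x, s in zip(evars, st))
            arr[idx] = float(p)
        factors.append((evars, arr))
    return FactorGraph(space.variables, levels, tuple(factors))


def sum_product(
    fg: FactorGraph,
    max_iters: int = 10_000,
    tol: float = 1e-10,
    damping: float = 0.5,
) -> BeliefResult:
    """Flooding-schedule sum-product with damping.

    Messages start uniform and are normalized each pass; convergence is
    declared when the largest message change falls below ``tol``.
    Non-convergence within ``max_iters`` is reported, not raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not 0 <= damping < 1:
        raise ValueError("damping must lie in [0, 1)")
    nl = dict(zip(fg.variables, fg.levels))
    # message keys: (fi, var, direction); store as dict of arrays
    msg_fv = {
        (fi, v): np.full(nl[v], 1.0 / nl[v])
        for fi, (fvars, _) in enumerate(fg.factors)
        for v in fvars
    }
    msg_vf = {key: np.full(nl[key[1]], 1.0 / nl[key[1]]) for key in msg_fv}
    neighbors = {
        v: [fi for fi, (fvars, _) in enumerate(fg.factors) if v in fvars]
        for v in fg.variables
    }
    residual = np.inf
    iters = 0
    for iters in range(1, max_iters + 1):
        residual = 0.0
        new_vf = {}
        for (fi, v) in msg_vf:
            prod = np.ones(nl[v])
            for fj in neighbors[v]:
                if fj != fi:
                    prod = prod * msg_fv[(fj, v)]
            s = prod.sum()
            if s <= 0:
                raise FloatingPointError(
                    f"all-zero message product into factor {fi} at variable {v}"
                )
            new_vf[(fi, v)] = prod / s
        for key, val in new_vf.items():
            mixed = damping * msg_vf[key] + (1 - damping) * val
            residual = max(residual, float(np.abs(mixed - msg_vf[key]).max()))
            msg_vf[key] = mixed
        new_fv = {}
        for fi, (fvars, table) in enumerate(fg.factors):
            for ax, v in enumerate(fvars):
                t = table.copy()
                for ax2, u in enumerate(fvars):
                    if u != v:
                        shape = [1] * t.ndim
                        shape[ax2] = nl[u]
                        t = t * msg_vf[(fi, u)].reshape(shape)
                out = t.sum(axis=tuple(a for a in range(t.ndim) if a != ax))
                s = out.sum()
                if s <= 0:
                    raise FloatingPointError(
                        f"all-zero message from factor {fi} to variable {v}"
                    )
                new_fv[(fi, v)] = out / s
        for key, val in new_fv.items():
            mixed = damping * msg_fv[key] + (1 - damping) * val
            residual = max(residual, float(np.abs(mixed - msg_fv[key]).max()))
            msg_fv[key] = mixed
        if residual < tol:
            break
    node_beliefs = {}
    for v in fg.variables:
        b = np.ones(nl[v])
        for fi in neighbors[v]:
            b = b * msg_fv[(fi, v)]
        node_beliefs[v] = b / b.sum()
    edge_beliefs = []
    for fi, (fvars, table) in enumerate(fg.factors):
        t = table.copy()
        for ax, u in enumerate(fvars):
            shape = [1] * t.ndim
            shape[ax] = nl[u]
            t = t * msg_vf[(fi, u)].reshape(shape)
        edge_beliefs.append(t / t.sum())
    return BeliefResult(
        node_beliefs, tuple(edge_beliefs), residual < tol, iters, residual
    )


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def compare_marginals(
    exact: EdgeMarginalFamily, bp: BeliefResult
) -> tuple[dict[str, float], dict[str, float]]:
    """Total-variation distances between exact tables and BP beliefs.

    Returns (per-node, per-edge) distance maps; node marginals of the exact
    family are taken from the first edge containing the node.
    """
    space, h = exact.space, exact.architecture
    node_d = {}
    for v in space.variables:
        ei = next(i for i, e in enumerate(h.edges) if v in e)
        marg = exact.table_marginal(ei, [v])
        p = np.array([float(marg[(s,)]) for s in space.levels_of(v)])
        node_d[v] = total_variation(p, bp.node_beliefs[v])
    edge_d = {}
    for ei, table in enumerate(exact.tables):
        evars = space.edge_variables(h.edges[ei])
        shape = tuple(len(space.levels_of(x)) for x in evars)
        arr = np.zeros(shape)
        for st, p in table.items():
            idx = tuple(space.levels_of(x).index(s) for x, s in zip(evars, st))
            arr[idx] = float(p)
        edge_d[h.edge_label(ei)] = total_variation(arr, bp.edge_beliefs[ei])
    return node_d, edge_d
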