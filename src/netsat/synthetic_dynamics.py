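"""Synthetic data: master-equation stationary states, coarse-graining, and
per-edge measurement datasets.

This module generates every input the consistency pipeline needs without any
external data.  A small chemical master equation on a truncated count
lattice is solved for its stationary distribution; thresholding molecule
counts into discrete levels produces a coarse-grained joint distribution
over network states; per-edge measurement campaigns are then simulated
either from such a joint (always globally consistent in the large-sample
limit) or independently per edge from an arbitrary edge-marginal family —
the observation model under which locally-but-not-globally-consistent data
can arise.
"""

from __future__ import annotations

import itertools
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .architectures import Hypergraph, is_acyclic
from .consistency import (
    EdgeMarginalFamily,
    JointDistribution,
    is_globally_consistent,
)
from .marginalization import StateSpace

__all__ = [
    "RateModel",
    "StationaryDistribution",
    "CoarseGraining",
    "Dataset",
    "stationary_distribution",
    "coarse_grain",
    "sample_dataset",
    "empirical_edge_marginals",
    "generate_inconsistent_family",
    "two_state_switch",
    "birth_death",
]

DEFAULT_TRUNCATION = 30
TAIL_MASS_WARN = 1e-6


@dataclass(frozen=True)
class RateModel:
    """A reaction network on a truncated count lattice ``{0..truncation}^k``.

    Each reaction is ``(change, propensity)``: an integer state-change
    vector and a non-negative rate function of the current count vector
    (rate constants are folded into the propensity).  Transitions leaving
    the lattice are dropped (reflecting truncation).
    """

    species: tuple[str, ...]
    truncation: int
    reactions: tuple[tuple[tuple[int, ...], Callable[[tuple[int, ...]], float]], ...]

    def __post_init__(self):
        if self.truncation < 1:
            raise ValueError("truncation must be >= 1")
        for change, _ in self.reactions:
            if len(change) != len(self.species):
                raise ValueError("state-change vector length mismatch")

    def states(self) -> list[tuple[int, ...]]:
        r = range(self.truncation + 1)
        return list(itertools.product(r, repeat=len(self.species)))


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary law of the truncated master equation, indexed by counts."""

    model: RateModel
    probabilities: np.ndarray  # aligned with model.states()

    def as_dict(self) -> dict[tuple[int, ...], float]:
        return dict(zip(self.model.states(), self.probabilities.tolist()))

    def marginal(self, species: str) -> np.ndarray:
        ax = self.model.species.index(species)
        k = len(self.model.species)
        n = self.model.truncation + 1
        arr = self.probabilities.reshape((n,) * k)
        return arr.sum(axis=tuple(a for a in range(k) if a != ax))


@dataclass(frozen=True)
class CoarseGraining:
    """Per-species count thresholds defining discrete levels.

    ``thresholds[s] = (T1, T2, ...)`` bins a count ``n`` into level
    ``#{i : n > Ti}``; a single threshold ``T`` gives the binary map
    0 for ``n <= T``, 1 for ``n > T``.
    """

    thresholds: Mapping[str, tuple[int, ...]]

    def level_of(self, species: str, count: int) -> int:
        return bisect_right(sorted(self.thresholds[species]), count - 1)

    def n_levels(self, species: str) -> int:
        return len(self.thresholds[species]) + 1


@dataclass(frozen=True)
class Dataset:
    """Per-edge measurement records: (edge index -> observed edge states)."""

    space: StateSpace
    architecture: Hypergraph
    records: tuple[tuple[tuple, ...], ...]  # per edge, sequence of edge states
    seed: int | None

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(len(r) for r in self.records)


def _build_generator(m: RateModel) -> tuple[sp.csr_matrix, bool]:
    """Generator matrix plus a flag: did the truncation clip any transition?"""
    states = m.states()
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    hi = m.truncation
    clipped = False
    for i, s in enumerate(states):
        for change, prop in m.reactions:
            a = float(prop(s))
            if a < 0:
                raise ValueError(f"negative propensity at state {s}")
            if a == 0:
                continue
            t = tuple(x + dx for x, dx in zip(s, change))
            if any(x > hi for x in t):
                clipped = True
                continue  # reflecting truncation
            if any(x < 0 for x in t):
                continue
            rows.append(index[t])
            cols.append(i)
            vals.append(a)
            diag[i] -= a
    rows += list(range(n))
    cols += list(range(n))
    vals += diag.tolist()
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n)), clipped


def stationary_distribution(m: RateModel) -> StationaryDistribution:
    """Solve ``M P = 0`` on the truncated lattice, normalized to 1.

    Raises on reducible chains, listing the closed communicating classes.
    Warns when the stationary mass on the truncation boundary exceeds 1e-6
    (the finite lattice is then visibly distorting the infinite chain).
    """
    M, clipped = _build_generator(m)
    n = M.shape[0]
    adj = sp.csr_matrix((np.ones(len(M.data)), M.indices, M.indptr), shape=M.shape)
    ncomp, labels = connected_components(adj.T, directed=True, connection="strong")
    if ncomp > 1:
        # closed classes: strong components with no outgoing rate
        states = m.states()
        out = M.tocoo()
        has_exit = set()
        for r, c in zip(out.row, out.col):
            if labels[r] != labels[c]:
                has_exit.add(labels[c])
        closed = sorted(set(range(ncomp)) - has_exit)
        examples = {
            cl: [states[i] for i in np.flatnonzero(labels == cl)[:3]]
            for cl in closed
        }
        raise ValueError(
            f"generator is reducible ({ncomp} strong components); closed "
            f"classes (sample states): {examples}"
        )
    A = M.tolil()
    A[n - 1, :] = 1.0  # replace one balance equation by normalization
    b = np.zeros(n)
    b[n - 1] = 1.0
    p = spsolve(A.tocsr(), b)
    p = np.clip(p, 0, None)
    p = p / p.sum()
    boundary = [
        i for i, s in enumerate(m.states()) if any(x == m.truncation for x in s)
    ]
    tail = float(p[boundary].sum()) if boundary else 0.0
    if clipped and tail > TAIL_MASS_WARN:
        warnings.warn(
            f"stationary mass {tail:.2e} on the truncation boundary exceeds "
            f"{TAIL_MASS_WARN:.0e}; increase truncation", RuntimeWarning,
        )
    return StationaryDistribution(m, p)


def coarse_grain(p: StationaryDistribution, cg: CoarseGraining) -> JointDistribution:
    """Sum stationary mass over the preimage of each level combination."""
    m = p.model
    for s in m.species:
        if s not in cg.thresholds:
            raise ValueError(f"no thresholds for species {s}")
        for t in cg.thresholds[s]:
            if not 0 <= t <= m.truncation:
                raise ValueError(f"threshold {t} outside the count range of {s}")
    levels = {s: tuple(range(cg.n_levels(s))) for s in m.species}
    space = StateSpace(m.species, levels)
    acc: dict[tuple, float] = {st: 0.0 for st in space.joint_states()}
    for counts, mass in zip(m.states(), p.probabilities):
        key = tuple(cg.level_of(s, c) for s, c in zip(m.species, counts))
        acc[key] += float(mass)
    return JointDistribution(space, tuple(acc[st] for st in space.joint_states()))


def sample_dataset(
    source: JointDistribution | EdgeMarginalFamily,
    h: Hypergraph,
    n_per_edge: int,
    seed: int | None = None,
) -> Dataset:
    """Simulate independent per-edge measurement campaigns.

    From a joint source, each edge's records are restrictions of fresh joint
    draws; from a family source, each edge's records are drawn from its own
    table.  Only the latter protocol — per-edge observation with no shared
    samples — can produce globally inconsistent empirical families.
    """
    if n_per_edge < 1:
        raise ValueError("n_per_edge must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    if isinstance(source, JointDistribution):
        # one shared measurement campaign: every edge sees the same draws, so
        # the empirical family is exactly the marginal family of the
        # empirical joint and a witness always exists
        space = source.space
        joint_states = space.joint_states()
        w = np.array([float(x) for x in source.weights])
        w = w / w.sum()
        idx = rng.choice(len(joint_states), size=n_per_edge, p=w)
        for e in h.edges:
            records.append(tuple(space.restrict(joint_states[i], e) for i in idx))
    else:
        space = source.space
        if source.architecture.edges != h.edges:
            raise ValueError("family source must share the architecture")
        for ei in range(len(h.edges)):
            states = space.edge_states(h.edges[ei])
            w = np.array([float(source.tables[ei][st]) for st in states])
            w = w / w.sum()
            idx = rng.choice(len(states), size=n_per_edge, p=w)
            records.append(tuple(states[i] for i in idx))
    return Dataset(space, h, tuple(records), seed)


def empirical_edge_marginals(d: Dataset) -> EdgeMarginalFamily:
    """Per-edge relative frequencies: the edge-wise maximum-likelihood family."""
    tables = []
    for ei, recs in enumerate(d.records):
        if not recs:
            raise ValueError(
                f"edge {d.architecture.edge_label(ei)} has no records"
            )
        states = d.space.edge_states(d.architecture.edges[ei])
        n = len(recs)
        counts = {st: 0 for st in states}
        for r in recs:
            counts[r] += 1
        tables.append({st: Fraction(c, n) for st, c in counts.items()})
    return EdgeMarginalFamily(d.architecture, d.space, tuple(tables))


def generate_inconsistent_family(
    space: StateSpace,
    h: Hypergraph,
    seed: int | None = None,
    max_tries: int = 1000,
    return_tries: bool = False,
) -> EdgeMarginalFamily | tuple[EdgeMarginalFamily, int]:
    """A locally consistent, globally inconsistent family on a cyclic architecture.

    Rejection-samples uniform points of L(G) (hit-and-run) until one is
    LP-infeasible; the expected number of tries is 1/(1 - volume ratio).
    """
    if is_acyclic(h):
        raise ValueError(
            "architecture admits no unsatisfiable constraints: it is acyclic, "
            "so every locally consistent family extends to a joint"
        )
    from .geometry import sample_local_polytope

    chunk = 32
    tries = 0
    while tries < max_tries:
        n = min(chunk, max_tries - tries)
        # advance a fresh chain deterministically past the already-used draws
        samples = sample_local_polytope(
            space, h, tries + n, seed=seed
        )[tries:]
        for fam in samples:
            tries += 1
            feasible, _ = is_globally_consistent(fam)
            if not feasible:
                return (fam, tries) if return_tries else fam
    raise RuntimeError(
        f"no globally inconsistent family found in {max_tries} tries "
        f"(all sampled families were globally consistent)"
    )


# ---------------------------------------------------------------------------
# Ready-made small models
# ---------------------------------------------------------------------------

def two_state_switch(k12: float, k21: float) -> RateModel:
    """A single species flipping between counts 0 and 1."""
    return RateModel(
        ("s",), 1,
        (
            ((1,), lambda st, k=k12: k if st[0] == 0 else 0.0),
            ((-1,), lambda st, k=k21: k if st[0] == 1 else 0.0),
        ),
    )


def birth_death(lam: float, mu: float, truncation: int = DEFAULT_TRUNCATION,
                species: str = "x") -> RateModel:
    """Constant birth at rate lam, per-capita death at rate mu."""
    return RateModel(
        (species,), truncation,
        (
            ((1,), lambda st: lam),
            ((-1,), lambda st: mu * st[0]),
        ),
    )
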