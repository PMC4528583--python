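"""Geometry of the local and marginal polytopes.

For an architecture G the locally consistent families form the local
polytope L(G) and the globally consistent ones the marginal polytope
M(G) ⊆ L(G).  Both have the same affine hull, so the ratio
Vol(M(G))/Vol(L(G)) — measured with Lebesgue measure on that common hull —
is a well-defined, parametrization-invariant number in (0, 1]:
the a-priori probability that constraints drawn uniformly from the locally
consistent families are actually satisfiable by a joint distribution.
Acyclic architectures have ratio exactly 1; every cyclic architecture has
ratio strictly below 1.

Two routes are provided: a hit-and-run Monte-Carlo estimate (fraction of
uniform L(G) samples that are LP-feasible) and, in low dimension, an exact
computation by vertex enumeration and triangulation in a common rational
affine chart.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import factorial, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import Delaunay, QhullError

from .architectures import Hypergraph, is_acyclic
from .consistency import (
    EdgeMarginalFamily,
    PolytopeDescription,
    local_polytope,
)
from .marginalization import (
    StateSpace,
    build_marginalization_matrix,
    fundamental_subspaces,
)

__all__ = [
    "VolumeEstimate",
    "BayesAssessment",
    "AffineChart",
    "affine_chart",
    "affine_dimension",
    "local_polytope_dimension",
    "marginal_polytope_dimension",
    "sample_local_polytope",
    "volume_ratio",
    "exact_volume_ratio",
    "posterior_local_model",
    "architecture_survey",
]

EXACT_DIM_LIMIT = 8
DEFAULT_BURN_IN = 1000


@dataclass(frozen=True)
class VolumeEstimate:
    """Vol(M)/Vol(L) with sampling metadata."""

    ratio: float
    stderr: float
    n_samples: int
    seed: int | None
    method: str  # "monte_carlo" | "exact"
    exact_ratio: Fraction | None = None


@dataclass(frozen=True)
class BayesAssessment:
    """Posterior weight of a merely-locally-consistent model.

    ``likelihood_ratio`` is the global:local volume ratio, i.e. the chance
    that a locally consistent model nevertheless produces globally
    consistent observations; a globally consistent model produces them with
    probability 1.
    """

    prior: float
    likelihood_ratio: float
    posterior: float


@dataclass(frozen=True)
class AffineChart:
    """Exact rational parametrization v = v0 + N z of an equality set.

    The chart keeps the free coordinates of the (rref-reduced) equality
    system as parameters, so mapping a point into the chart is coordinate
    extraction.  Volumes computed in any such chart differ only by a
    constant factor, which cancels in volume ratios.
    """

    origin: tuple[Fraction, ...]  # v0
    basis: tuple[tuple[Fraction, ...], ...]  # N, shape (ncoord, dim)
    free_columns: tuple[int, ...]

    @property
    def dim(self) -> int:
        return len(self.free_columns)

    def to_chart(self, v: Sequence) -> list:
        return [v[j] for j in self.free_columns]

    def from_chart(self, z: Sequence) -> list:
        return [
            o + sum(nij * zj for nij, zj in zip(row, z) if nij)
            for o, row in zip(self.origin, self.basis)
        ]


def affine_chart(p: PolytopeDescription) -> AffineChart:
    """Rational chart of the affine hull defined by ``p``'s equalities."""
    import sympy

    n = len(p.coordinates)
    rows = [list(eq.coefficients) + [eq.rhs] for eq in p.equalities]
    if not rows:
        ident = tuple(
            tuple(Fraction(int(i == j)) for j in range(n)) for i in range(n)
        )
        return AffineChart(tuple([Fraction(0)] * n), tuple(zip(*ident)), tuple(range(n)))
    aug = sympy.Matrix([[sympy.Rational(x) for x in row] for row in rows])
    R, pivots = aug.rref()
    if n in pivots:
        raise ValueError("equality system is inconsistent (empty polytope)")
    free = [j for j in range(n) if j not in pivots]

    def frac(x) -> Fraction:
        q = sympy.Rational(x)
        return Fraction(int(q.p), int(q.q))

    origin = [Fraction(0)] * n
    basis = [[Fraction(0)] * len(free) for _ in range(n)]
    for t, pcol in enumerate(pivots):
        origin[pcol] = frac(R[t, n])
        for fi, j in enumerate(free):
            basis[pcol][fi] = -frac(R[t, j])
    for fi, j in enumerate(free):
        basis[j][fi] = Fraction(1)
    return AffineChart(
        tuple(origin), tuple(tuple(r) for r in basis), tuple(free)
    )


def affine_dimension(p: PolytopeDescription) -> int:
    """Dimension of the affine hull of a non-empty polytope description."""
    n = len(p.coordinates)
    A_ub = (
        np.array([[-float(c) for c in iq.coefficients] for iq in p.inequalities])
        if p.inequalities else None
    )
    b_ub = (
        np.array([-float(iq.rhs) for iq in p.inequalities])
        if p.inequalities else None
    )
    A_eq = (
        np.array([[float(c) for c in eq.coefficients] for eq in p.equalities])
        if p.equalities else None
    )
    b_eq = (
        np.array([float(eq.rhs) for eq in p.equalities])
        if p.equalities else None
    )
    res = linprog(np.zeros(n), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(None, None), method="highs")
    if res.status != 0:
        raise ValueError("polytope is empty")
    return affine_chart(p).dim


def local_polytope_dimension(space: StateSpace, h: Hypergraph) -> int:
    return affine_chart(local_polytope(space, h)).dim


def marginal_polytope_dimension(space: StateSpace, h: Hypergraph) -> int:
    """dim M(G) = rank(G) - 1: the affine hull of the image of the simplex."""
    G = build_marginalization_matrix(space, h)
    kernel, _ = fundamental_subspaces(G)
    return G.shape[1] - kernel.dim - 1


class _ChartSampler:
    """Hit-and-run over ``{z : o + C z >= 0}`` started at the uniform family."""

    def __init__(self, space: StateSpace, h: Hypergraph):
        self.space, self.h = space, h
        desc = local_polytope(space, h)
        self.chart = affine_chart(desc)
        A = np.array(
            [[float(c) for c in iq.coefficients] for iq in desc.inequalities]
        )
        b = np.array([float(iq.rhs) for iq in desc.inequalities])
        N = np.array([[float(x) for x in row] for row in self.chart.basis])
        v0 = np.array([float(x) for x in self.chart.origin])
        self.C = A @ N
        self.o = A @ v0 - b
        z0 = self.chart.to_chart(
            EdgeMarginalFamily.uniform(space, h).as_vector()
        )
        self.z = np.array([float(x) for x in z0])

    def step(self, rng: np.random.Generator) -> None:
        d = rng.standard_normal(self.chart.dim)
        d /= np.linalg.norm(d)
        cu = self.C @ d
        val = self.o + self.C @ self.z
        val = np.maximum(val, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -val / cu
        lo = t[cu > 1e-14]
        hi = t[cu < -1e-14]
        tmin = lo.max(initial=-np.inf)
        tmax = hi.min(initial=np.inf)
        if not np.isfinite(tmin) or not np.isfinite(tmax) or tmax < tmin:
            return  # degenerate direction; keep current point
        self.z = self.z + rng.uniform(tmin, tmax) * d

    def current_vector(self) -> np.ndarray:
        N = np.array([[float(x) for x in row] for row in self.chart.basis])
        v0 = np.array([float(x) for x in self.chart.origin])
        return v0 + N @ self.z


def sample_local_polytope(
    space: StateSpace,
    h: Hypergraph,
    n_samples: int,
    seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    thinning: int | None = None,
) -> list[EdgeMarginalFamily]:
    """Asymptotically uniform samples of L(G) via hit-and-run.

    The walk runs in an affine chart of the equality set, starting from the
    uniform family (always relative-interior).  ``thinning`` defaults to the
    polytope dimension.
    """
    sampler = _ChartSampler(space, h)
    if thinning is None:
        thinning = max(1, sampler.chart.dim)
    rng = np.random.default_rng(seed)
    for _ in range(burn_in):
        sampler.step(rng)
    out = []
    N = np.array([[float(x) for x in row] for row in sampler.chart.basis])
    v0 = np.array([float(x) for x in sampler.chart.origin])
    for _ in range(n_samples):
        for _ in range(thinning):
            sampler.step(rng)
        v = np.clip(v0 + N @ sampler.z, 0.0, None)
        out.append(EdgeMarginalFamily.from_vector(space, h, v.tolist()))
    return out


def volume_ratio(
    space: StateSpace,
    h: Hypergraph,
    n_samples: int = 10_000,
    seed: int | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    thinning: int | None = None,
    method: str = "auto",
) -> VolumeEstimate:
    """Vol(M(G))/Vol(L(G)) on the common affine hull.

    Acyclic architectures short-circuit to exactly 1 (local consistency
    implies global consistency).  Cyclic architectures are estimated as the
    fraction of uniform L(G) samples that are LP-feasible, with the binomial
    standard error.  ``method="monte_carlo"`` disables the short-circuit so
    the analytic value can be cross-checked by sampling.
    """
    if method not in ("auto", "monte_carlo"):
        raise ValueError("method must be 'auto' or 'monte_carlo'")
    if method == "auto" and is_acyclic(h):
        return VolumeEstimate(1.0, 0.0, 0, seed, "exact", Fraction(1))
    sampler = _ChartSampler(space, h)
    if thinning is None:
        thinning = max(1, sampler.chart.dim)
    rng = np.random.default_rng(seed)
    G = build_marginalization_matrix(space, h)
    m, n = G.shape
    A_eq = np.hstack([G.matrix.astype(float), np.eye(m), -np.eye(m)])
    c = np.concatenate([np.zeros(n), np.ones(2 * m)])
    N = np.array([[float(x) for x in row] for row in sampler.chart.basis])
    v0 = np.array([float(x) for x in sampler.chart.origin])
    for _ in range(burn_in):
        sampler.step(rng)
    hits = 0
    for _ in range(n_samples):
        for _ in range(thinning):
            sampler.step(rng)
        v = np.clip(v0 + N @ sampler.z, 0.0, None)
        res = linprog(c, A_eq=A_eq, b_eq=v, bounds=(0, None), method="highs")
        if res.status == 0 and res.fun <= 1e-9:
            hits += 1
    p = hits / n_samples
    se = sqrt(p * (1 - p) / n_samples)
    return VolumeEstimate(p, se, n_samples, seed, "monte_carlo")


# ---------------------------------------------------------------------------
# Exact volumes by vertex enumeration + triangulation
# ---------------------------------------------------------------------------

def _solve_square(rows: list[list[Fraction]], rhs: list[Fraction]):
    """Exact solve of a square system; None if singular."""
    n = len(rows)
    M = [list(r) + [b] for r, b in zip(rows, rhs)]
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        pv = M[col][col]
        M[col] = [x / pv for x in M[col]]
        for r in range(n):
            if r != col and M[r][col]:
                f = M[r][col]
                M[r] = [a - f * b for a, b in zip(M[r], M[col])]
    return [M[r][n] for r in range(n)]


def _enumerate_vertices(
    chart: AffineChart, ineq_rows: list[tuple[list[Fraction], Fraction]]
) -> list[tuple[Fraction, ...]]:
    """Vertices of ``{z : a.z >= b}`` by exhausting d-subsets of tight rows."""
    d = chart.dim
    verts: set[tuple[Fraction, ...]] = set()
    for combo in itertools.combinations(range(len(ineq_rows)), d):
        rows = [ineq_rows[i][0] for i in combo]
        rhs = [ineq_rows[i][1] for i in combo]
        z = _solve_square([list(r) for r in rows], list(rhs))
        if z is None:
            continue
        ok = all(
            sum(a * x for a, x in zip(row, z)) >= b
            for row, b in ineq_rows
        )
        if ok:
            verts.add(tuple(z))
    return sorted(verts)


def _exact_volume(points: list[tuple[Fraction, ...]], dim: int) -> Fraction:
    """Exact volume of conv(points) via a float Delaunay triangulation whose
    simplex determinants are recomputed in rational arithmetic."""
    if len(points) < dim + 1:
        return Fraction(0)
    arr = np.array([[float(x) for x in p] for p in points])
    try:
        tri = Delaunay(arr)
    except QhullError:
        tri = Delaunay(arr, qhull_options="QJ")
    total = Fraction(0)
    for simplex in tri.simplices:
        p0 = points[simplex[0]]
        mat = [
            [points[i][j] - p0[j] for j in range(dim)] for i in simplex[1:]
        ]
        total += abs(_det(mat))
    return total / factorial(dim)


def _det(mat: list[list[Fraction]]) -> Fraction:
    """Exact determinant by fraction-free-ish Gaussian elimination."""
    n = len(mat)
    M = [row[:] for row in mat]
    det = Fraction(1)
    for col in range(n):
        piv = next((r for r in range(col, n) if M[r][col] != 0), None)
        if piv is None:
            return Fraction(0)
        if piv != col:
            M[col], M[piv] = M[piv], M[col]
            det = -det
        det *= M[col][col]
        inv = M[col][col]
        for r in range(col + 1, n):
            if M[r][col]:
                f = M[r][col] / inv
                M[r] = [a - f * b for a, b in zip(M[r], M[col])]
    return det


def exact_volume_ratio(space: StateSpace, h: Hypergraph) -> VolumeEstimate:
    """Exact Vol(M(G))/Vol(L(G)) by vertex enumeration and triangulation.

    L(G) vertices come from its H-representation in a rational affine chart;
    M(G) is the convex hull of the images under G of the deterministic
    joints (the simplex vertices).  Both volumes are computed in the same
    chart, so the ratio is chart-independent.
    """
    if is_acyclic(h):
        return VolumeEstimate(1.0, 0.0, 0, None, "exact", Fraction(1))
    desc = local_polytope(space, h)
    chart = affine_chart(desc)
    d = chart.dim
    if d > EXACT_DIM_LIMIT:
        raise ValueError(
            f"affine dimension {d} exceeds the exact-volume guard "
            f"({EXACT_DIM_LIMIT}); use volume_ratio (Monte Carlo) instead"
        )
    # inequalities of L(G) pushed into the chart: a.(v0 + N z) >= b
    ineq_rows = []
    for iq in desc.inequalities:
        arow = [
            sum(c * chart.basis[i][k] for i, c in enumerate(iq.coefficients) if c)
            for k in range(d)
        ]
        off = sum(c * chart.origin[i] for i, c in enumerate(iq.coefficients) if c)
        ineq_rows.append((arow, iq.rhs - off))
    lverts = _enumerate_vertices(chart, ineq_rows)
    G = build_marginalization_matrix(space, h)
    mverts = sorted(
        {
            tuple(chart.to_chart([Fraction(int(x)) for x in G.matrix[:, cidx]]))
            for cidx in range(G.shape[1])
        }
    )
    vol_l = _exact_volume(lverts, d)
    vol_m = _exact_volume(mverts, d)
    if vol_l == 0:
        raise ValueError("local polytope has zero volume in its chart")
    ratio = vol_m / vol_l
    return VolumeEstimate(float(ratio), 0.0, 0, None, "exact", ratio)


def local_polytope_vertices(
    space: StateSpace, h: Hypergraph
) -> list[list[Fraction]]:
    """Vertices of L(G) in marginal coordinates (exact)."""
    desc = local_polytope(space, h)
    chart = affine_chart(desc)
    if chart.dim > EXACT_DIM_LIMIT:
        raise ValueError("dimension exceeds the vertex-enumeration guard")
    ineq_rows = []
    for iq in desc.inequalities:
        arow = [
            sum(c * chart.basis[i][k] for i, c in enumerate(iq.coefficients) if c)
            for k in range(chart.dim)
        ]
        off = sum(c * chart.origin[i] for i, c in enumerate(iq.coefficients) if c)
        ineq_rows.append((arow, iq.rhs - off))
    return [chart.from_chart(z) for z in _enumerate_vertices(chart, ineq_rows)]


def marginal_polytope_vertices(
    space: StateSpace, h: Hypergraph
) -> list[list[Fraction]]:
    """Vertices of M(G): distinct images of the deterministic joints."""
    G = build_marginalization_matrix(space, h)
    cols = {
        tuple(Fraction(int(x)) for x in G.matrix[:, c]) for c in range(G.shape[1])
    }
    return [list(c) for c in sorted(cols)]


def posterior_local_model(prior: float, ratio: float) -> BayesAssessment:
    """Bayes update for "is the model merely locally consistent?".

    With unit likelihood of globally consistent observations under a
    globally consistent model, observing global consistency gives
    ``posterior = ratio * prior / (ratio * prior + (1 - prior))``.
    """
    if not (0 <= prior <= 1 and 0 <= ratio <= 1):
        raise ValueError("prior and ratio must lie in [0, 1]")
    denom = ratio * prior + (1 - prior)
    if denom == 0:
        warnings.warn(
            "prior=1 with ratio=0: observation has probability 0; "
            "posterior defined as 0", RuntimeWarning,
        )
        return BayesAssessment(prior, ratio, 0.0)
    return BayesAssessment(prior, ratio, ratio * prior / denom)


def architecture_survey(
    n: int,
    min_edge_size: int = 2,
    n_samples: int = 10_000,
    seed: int = 0,
    n_levels: int = 2,
) -> pd.DataFrame:
    """Volume-ratio survey over all architecture classes on ``n`` variables.

    One row per isomorphism class with its cyclicity, the common dimension
    of L(G) and M(G), and the volume ratio (exact 1 for acyclic classes,
    Monte-Carlo otherwise, seeded per class for reproducibility).
    """
    if n > 4:
        raise ValueError("survey supports n <= 4")
    from .architectures import enumerate_architectures

    rows = []
    for ci, cls in enumerate(enumerate_architectures(n, min_edge_size)):
        h = cls.canonical
        space = StateSpace(
            h.variables, [tuple(range(n_levels))] * len(h.variables)
        )
        dim_l = local_polytope_dimension(space, h)
        dim_g = marginal_polytope_dimension(space, h)
        est = volume_ratio(space, h, n_samples=n_samples, seed=seed + ci)
        rows.append(
            {
                "class_id": cls.class_id,
                "canonical_edges": cls.class_id,
                "cyclic": cls.cyclic,
                "dim_local": dim_l,
                "dim_global": dim_g,
                "ratio": est.ratio,
                "stderr": est.stderr,
                "n_samples": est.n_samples,
                "seed": est.seed if est.method == "monte_carlo" else seed + ci,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows)
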