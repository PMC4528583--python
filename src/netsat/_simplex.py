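"""Exact rational Phase-I simplex for linear feasibility.

Decides feasibility of ``{A x = b, x >= 0}`` in exact ``fractions.Fraction``
arithmetic.  Bland's anti-cycling rule guarantees termination.  Intended for
small systems (a few hundred columns); no pre-installed library offers exact
rational LP, and boundary cases of the marginal polytope must not flip on
floating-point rounding.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

__all__ = ["exact_feasible_point"]

ZERO = Fraction(0)
ONE = Fraction(1)


def exact_feasible_point(
    A: Sequence[Sequence[Fraction]], b: Sequence[Fraction]
) -> list[Fraction] | None:
    """Return some x with ``A x = b``, ``x >= 0``, or ``None`` if infeasible."""
    m = len(A)
    if m == 0:
        return []
    n = len(A[0])
    # normalize rhs to be non-negative
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    for i in range(m):
        bi = Fraction(b[i])
        if bi < 0:
            rows.append([-Fraction(a) for a in A[i]])
            rhs.append(-bi)
        else:
            rows.append([Fraction(a) for a in A[i]])
            rhs.append(bi)

    # tableau columns: x (n) + artificials (m) + rhs
    width = n + m + 1
    T = [rows[i] + [ONE if j == i else ZERO for j in range(m)] + [rhs[i]]
         for i in range(m)]
    basis = [n + i for i in range(m)]
    # Phase-I objective row: minimize sum of artificials. Reduced-cost row
    # starts as -(sum of constraint rows) on the x columns, 0 on artificials.
    z = [ZERO] * width
    for i in range(m):
        for j in range(n):
            z[j] -= T[i][j]
        z[width - 1] -= T[i][width - 1]

    while True:
        # Bland: entering = lowest-index column with negative reduced cost
        enter = -1
        for j in range(n + m):
            if z[j] < 0:
                enter = j
                break
        if enter == -1:
            break
        # ratio test, Bland tie-break on basis variable index
        leave = -1
        best: Fraction | None = None
        for i in range(m):
            a = T[i][enter]
            if a > 0:
                ratio = T[i][width - 1] / a
                if best is None or ratio < best or (
                    ratio == best and basis[i] < basis[leave]
                ):
                    best = ratio
                    leave = i
        if leave == -1:  # pragma: no cover - Phase-I objective is bounded
            raise RuntimeError("unbounded Phase-I problem")
        _pivot(T, z, basis, leave, enter, width)

    if -z[width - 1] != 0:  # optimum of sum of artificials
        return None
    x = [ZERO] * n
    for i in range(m):
        if basis[i] < n:
            x[basis[i]] = T[i][width - 1]
    return x


def _pivot(T, z, basis, leave, enter, width):
    piv = T[leave][enter]
    row = T[leave]
    if piv != 1:
        for j in range(width):
            if row[j]:
                row[j] /= piv
        row[enter] = ONE
    for i, other in enumerate(T):
        if i != leave and other[enter]:
            f = other[enter]
            for j in range(width):
                if row[j]:
                    other[j] -= f * row[j]
            other[enter] = ZERO
    if z[enter]:
        f = z[enter]
        for j in range(width):
            if row[j]:
                z[j] -= f * row[j]
        z[enter] = ZERO
    basis[leave] = enter
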