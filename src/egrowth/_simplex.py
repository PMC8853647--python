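"""Exact rational LP via the primal simplex method with Bland's rule.

Solves small feasibility and optimisation problems in standard form

    min c.x  s.t.  A x = b,  x >= 0

entirely in :class:`fractions.Fraction` arithmetic. Bland's rule guarantees
termination; the problems in this package have a few dozen variables at most,
so no effort is spent on sparsity or revised-simplex updates.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

from ._rational import Vec, frac


class Unbounded(Exception):
    """The LP has unbounded optimum."""


def _simplex_tableau(
    tab: list[list[Fraction]], basis: list[int], rhs_col: int, n_enter: int
) -> None:
    """Run primal simplex on a tableau in-place (last row = objective,
    column `rhs_col` = rhs). Only columns < n_enter may enter the basis.
    Bland's rule for both entering and leaving."""
    m = len(tab) - 1
    while True:
        obj = tab[m]
        enter = next((j for j in range(n_enter) if obj[j] < 0), None)
        if enter is None:
            return
        leave, best = None, None
        for i in range(m):
            a = tab[i][enter]
            if a > 0:
                ratio = tab[i][rhs_col] / a
                if best is None or ratio < best or (ratio == best and basis[i] < basis[leave]):
                    best, leave = ratio, i
        if leave is None:
            raise Unbounded
        piv = tab[leave][enter]
        tab[leave] = [x / piv for x in tab[leave]]
        for i in range(m + 1):
            if i != leave and tab[i][enter] != 0:
                f = tab[i][enter]
                tab[i] = [x - f * y for x, y in zip(tab[i], tab[leave])]
        basis[leave] = enter


def solve_standard_form(
    a_rows: Sequence[Sequence],
    b: Sequence,
    c: Sequence | None = None,
) -> Vec | None:
    """Solve min c.x s.t. Ax = b, x >= 0 exactly.

    Returns an optimal basic solution, or None if infeasible.
    With c=None, returns any basic feasible solution (pure phase 1).
    """
    a = [[frac(x) for x in row] for row in a_rows]
    rhs = [frac(x) for x in b]
    m = len(a)
    n = len(a[0]) if a else 0
    for i in range(m):  # make rhs nonnegative
        if rhs[i] < 0:
            a[i] = [-x for x in a[i]]
            rhs[i] = -rhs[i]

    # phase 1: artificials
    total = n + m
    tab = [a[i] + [Fraction(int(j == i)) for j in range(m)] + [rhs[i]] for i in range(m)]
    basis = list(range(n, n + m))
    objrow = [Fraction(0)] * (total + 1)
    for i in range(m):  # reduced costs of min(sum of artificials)
        objrow = [o - x for o, x in zip(objrow, tab[i])]
    for j in range(n, n + m):
        objrow[j] = Fraction(0)
    tab.append(objrow)
    _simplex_tableau(tab, basis, total, total)
    if -tab[m][total] != 0:  # phase-1 optimum > 0
        return None
    # drive any remaining artificials out of the basis
    for i in range(m):
        if basis[i] >= n:
            enter = next((j for j in range(n) if tab[i][j] != 0), None)
            if enter is None:
                continue  # redundant row
            piv = tab[i][enter]
            tab[i] = [x / piv for x in tab[i]]
            for k in range(m + 1):
                if k != i and tab[k][enter] != 0:
                    f = tab[k][enter]
                    tab[k] = [x - f * y for x, y in zip(tab[k], tab[i])]
            basis[i] = enter

    if c is not None:
        cost = [frac(x) for x in c] + [Fraction(0)] * (m + 1)
        for i in range(m):
            if basis[i] < n and cost[basis[i]] != 0:
                f = cost[basis[i]]
                cost = [x - f * y for x, y in zip(cost, tab[i])]
        tab[m] = cost
        _simplex_tableau(tab, basis, total, n)  # artificials may not re-enter

    x = [Fraction(0)] * n
    for i in range(m):
        if basis[i] < n:
            x[basis[i]] = tab[i][total]
    return tuple(x)


def feasible_point(
    *,
    n: int,
    eq_rows: Sequence[tuple[Sequence, object]] = (),
    ineq_rows: Sequence[tuple[Sequence, object]] = (),
    nonneg: Sequence[bool] | None = None,
    objective: Sequence | None = None,
) -> Vec | None:
    """Find x in R^n with eq rows a.x = b, ineq rows a.x >= b and x_i >= 0
    where nonneg[i]; optionally minimising `objective`. Returns None if
    infeasible. Free variables are split internally."""
    nonneg = [True] * n if nonneg is None else list(nonneg)
    # variable layout: x_i (nonneg) or x_i+, x_i- (free), then slacks
    layout: list[tuple[int, int]] = []
    for i in range(n):
        layout.append((i, +1))
        if not nonneg[i]:
            layout.append((i, -1))
    n_vars = len(layout)
    n_slack = len(ineq_rows)
    a_std: list[list[Fraction]] = []
    b_std: list[Fraction] = []

    def expand(row: Sequence) -> list[Fraction]:
        row = [frac(x) for x in row]
        return [row[i] * s for i, s in layout]

    for row, b in eq_rows:
        a_std.append(expand(row) + [Fraction(0)] * n_slack)
        b_std.append(frac(b))
    for k, (row, b) in enumerate(ineq_rows):
        slack = [Fraction(0)] * n_slack
        slack[k] = Fraction(-1)
        a_std.append(expand(row) + slack)
        b_std.append(frac(b))

    c = None
    if objective is not None:
        c = expand(objective) + [Fraction(0)] * n_slack
    sol = solve_standard_form(a_std, b_std, c)
    if sol is None:
        return None
    x = [Fraction(0)] * n
    for (i, s), val in zip(layout, sol[:n_vars]):
        x[i] += s * val
    return tuple(x)
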