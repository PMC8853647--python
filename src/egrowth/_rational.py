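"""Exact rational linear algebra on small dense matrices.

Matrices are lists/tuples of rows of :class:`fractions.Fraction` (or ints).
Everything here is O(n^3)-ish and intended for desk-scale systems; vertex/ray
enumeration is numerically brittle, so all core computations stay exact.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

Vec = tuple[Fraction, ...]
Mat = tuple[Vec, ...]


def frac(x) -> Fraction:
    """Convert ints, Fractions, floats and 'p/q' strings to Fraction.

    Floats convert exactly (binary expansion); use strings for decimals.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, str):
        return Fraction(x)
    return Fraction(x)


def vec(entries: Iterable) -> Vec:
    return tuple(frac(e) for e in entries)


def mat(rows: Iterable[Iterable]) -> Mat:
    return tuple(vec(r) for r in rows)


def dot(a: Sequence, b: Sequence) -> Fraction:
    return sum((x * y for x, y in zip(a, b, strict=True)), Fraction(0))


def mat_vec(m: Sequence[Sequence], v: Sequence) -> Vec:
    return tuple(dot(row, v) for row in m)


def rref(rows: Sequence[Sequence]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form; returns (rref rows, pivot column indices)."""
    a = [[frac(x) for x in row] for row in rows]
    if not a:
        return [], []
    n_rows, n_cols = len(a), len(a[0])
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        if r == n_rows:
            break
        piv = next((i for i in range(r, n_rows) if a[i][c] != 0), None)
        if piv is None:
            continue
        a[r], a[piv] = a[piv], a[r]
        inv = a[r][c]
        a[r] = [x / inv for x in a[r]]
        for i in range(n_rows):
            if i != r and a[i][c] != 0:
                f = a[i][c]
                a[i] = [x - f * y for x, y in zip(a[i], a[r])]
        pivots.append(c)
        r += 1
    return a, pivots


def rank(rows: Sequence[Sequence]) -> int:
    return len(rref(rows)[1])


def nullspace(rows: Sequence[Sequence], n_cols: int | None = None) -> list[Vec]:
    """Basis of {x : Ax = 0} as a list of rational vectors."""
    rows = [list(r) for r in rows]
    if not rows:
        assert n_cols is not None, "need n_cols for an empty system"
        return [tuple(Fraction(int(i == j)) for j in range(n_cols)) for i in range(n_cols)]
    n = len(rows[0]) if n_cols is None else n_cols
    red, pivots = rref(rows)
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for f in free:
        x = [Fraction(0)] * n
        x[f] = Fraction(1)
        for r, p in enumerate(pivots):
            x[p] = -red[r][f]
        basis.append(tuple(x))
    return basis


def solve(rows: Sequence[Sequence], rhs: Sequence) -> Vec | None:
    """One exact solution of Ax = b, or None if inconsistent.

    If the system is underdetermined, free variables are set to zero.
    """
    aug = [list(r) + [frac(b)] for r, b in zip(rows, rhs, strict=True)]
    n = len(rows[0]) if rows else 0
    red, pivots = rref(aug)
    if n in pivots:  # pivot in the rhs column -> inconsistent
        return None
    x = [Fraction(0)] * n
    for r, p in enumerate(pivots):
        x[p] = red[r][n]
    return tuple(x)


def scale_to_coprime_ints(v: Sequence) -> tuple[int, ...]:
    """Scale a rational vector by a positive rational to coprime integers."""
    fr = [frac(x) for x in v]
    if all(x == 0 for x in fr):
        return tuple(0 for _ in fr)
    denom_lcm = 1
    for x in fr:
        d = x.denominator
        denom_lcm = denom_lcm * d // gcd(denom_lcm, d)
    ints = [int(x * denom_lcm) for x in fr]
    g = 0
    for i in ints:
        g = gcd(g, abs(i))
    return tuple(i // g for i in ints)


def support(v: Sequence) -> frozenset[int]:
    return frozenset(i for i, x in enumerate(v) if x != 0)


def sign_leq(e: Sequence, x: Sequence) -> bool:
    """Componentwise sign(e) <= sign(x): e vanishes where x does and never
    opposes the sign of x (the 'no cancellation' order on sign vectors)."""
    for a, b in zip(e, x, strict=True):
        if a != 0 and (b == 0 or (a > 0) != (b > 0)):
            return False
    return True
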