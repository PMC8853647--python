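"""Independent brute-force oracles for elementary-vector enumeration.

These deliberately avoid the double-description code path: support-minimal
vectors are found by exhaustive support-pattern enumeration with exact rank
tests, and conformal generators of a cone by active-set vertex/ray
enumeration within every closed orthant (a conformally non-decomposable
vector is precisely an extreme ray of the cone intersected with any closed
orthant containing it).
"""

from fractions import Fraction
from itertools import combinations, product

from egrowth._rational import dot, nullspace, rank, scale_to_coprime_ints


def scone_evs_bruteforce(eq_rows, n, nonneg):
    """Support-minimal vectors of {x in ker(M) : x_I >= 0} by support-pattern
    enumeration: a support S carries an elementary vector iff the kernel of
    M restricted to S is one-dimensional and spanned by a vector with full
    support S whose sign pattern can satisfy the nonnegativity constraints."""
    out = set()
    for size in range(1, n + 1):
        for sup in combinations(range(n), size):
            cols = list(sup)
            sub = [[row[j] for j in cols] for row in eq_rows]
            ns = nullspace(sub, len(cols)) if sub else nullspace([], len(cols))
            if len(ns) != 1:
                continue
            z = ns[0]
            if any(x == 0 for x in z):
                continue
            full = [Fraction(0)] * n
            for j, x in zip(cols, z):
                full[j] = x
            for cand in (tuple(full), tuple(-x for x in full)):
                if all(cand[i] >= 0 for i in nonneg):
                    out.add(tuple(scale_to_coprime_ints(cand)))
    # collapse +/- pairs to a canonical representative
    canon = set()
    for v in out:
        neg = tuple(-x for x in v)
        if neg in out:
            first = next(x for x in v if x != 0)
            canon.add(v if first > 0 else neg)
        else:
            canon.add(v)
    return canon


def _extreme_rays_active_set(rows, n):
    """Extreme rays of a pointed cone {x : rows . x >= 0} by enumerating
    (n-1)-subsets of rows with one-dimensional kernel."""
    out = set()
    for sub in combinations(range(len(rows)), n - 1):
        ns = nullspace([rows[i] for i in sub], n)
        if len(ns) != 1:
            continue
        z = ns[0]
        for cand in (z, tuple(-x for x in z)):
            if all(dot(r, cand) >= 0 for r in rows):
                # extremality: active rows at cand must have rank n-1
                act = [r for r in rows if dot(r, cand) == 0]
                if rank(act) == n - 1:
                    out.add(tuple(scale_to_coprime_ints(cand)))
    return out


def cone_evs_bruteforce(ineq_rows, n):
    """Conformal generators of {x : Ax >= 0}: union over all closed orthants
    of the extreme rays of the cone restricted to that orthant."""
    out = set()
    for signs in product((1, -1), repeat=n):
        orthant = [
            tuple(Fraction(signs[i] * (j == i)) for j in range(n))
            for i in range(n)
        ]
        out |= _extreme_rays_active_set(list(ineq_rows) + orthant, n)
    return out


def polytope_vertices_bruteforce(a_rows, b, n):
    """Vertices of {x : Ax >= b} by n-subset basic-solution enumeration."""
    from egrowth._rational import solve

    out = set()
    for sub in combinations(range(len(a_rows)), n):
        rows = [a_rows[i] for i in sub]
        if rank(rows) < n:
            continue
        x = solve(rows, [b[i] for i in sub])
        if x is None:
            continue
        if all(dot(r, x) >= bb for r, bb in zip(a_rows, b)):
            out.add(tuple(x))
    return out
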