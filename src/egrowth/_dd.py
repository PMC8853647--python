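"""Double description in the nonnegative orthant, in exact arithmetic.

The single primitive here enumerates the extreme rays of a cone

    {v in R^d : v >= 0, M v = 0},

i.e. the support-minimal vectors of a fully irreversible flux cone. All other
enumeration problems in this package (s-cones with free coordinates, general
polyhedral cones, polyhedra via homogenisation) are reduced to this form by
splitting free variables and slacking inequality rows — the classical
correspondence between conformally non-decomposable vectors and support-
minimal vectors of the lifted system.

The algorithm is the incremental double description method: start from the
unit rays of the orthant and intersect with one hyperplane M_k v = 0 at a
time, keeping zero rays and combining adjacent (positive, negative) pairs.
Adjacency uses the standard combinatorial test on coordinate zero-sets,
stored as bitmasks. Rays are kept as coprime integer tuples, which bounds
coefficient growth and makes deduplication exact.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

from ._rational import scale_to_coprime_ints


def _zero_mask(ray: Sequence[int]) -> int:
    m = 0
    for i, x in enumerate(ray):
        if x == 0:
            m |= 1 << i
    return m


def extreme_rays_orthant(
    eq_rows: Sequence[Sequence[Fraction]], n_vars: int
) -> list[tuple[int, ...]]:
    """Extreme rays of {v >= 0 : M v = 0} as coprime integer tuples.

    Returns the empty list for the trivial cone {0}. The result is sorted
    for reproducibility.
    """
    rays: list[tuple[int, ...]] = [
        tuple(int(i == j) for j in range(n_vars)) for i in range(n_vars)
    ]
    masks = [_zero_mask(r) for r in rays]
    full = (1 << n_vars) - 1

    # process rows cutting away fewest rays first; cheap heuristic that keeps
    # intermediate ray counts small
    pending = [tuple(Fraction(x) for x in row) for row in eq_rows]
    while pending:
        scored = []
        for row in pending:
            vals = [sum(row[i] * r[i] for i in range(n_vars) if r[i]) for r in rays]
            n_zero = sum(1 for v in vals if v == 0)
            scored.append((len(vals) - n_zero, row, vals))
        scored.sort(key=lambda t: t[0])
        _, row, vals = scored[0]
        pending = [r for _, r, _ in scored[1:]]

        pos = [i for i, v in enumerate(vals) if v > 0]
        neg = [i for i, v in enumerate(vals) if v < 0]
        keep = [i for i, v in enumerate(vals) if v == 0]

        new_rays = [rays[i] for i in keep]
        new_masks = [masks[i] for i in keep]
        for p in pos:
            mp = masks[p]
            for q in neg:
                common = mp & masks[q]
                # adjacency: no third ray's zero-set contains the common one
                adjacent = True
                for k, mk in enumerate(masks):
                    if k != p and k != q and (common & ~mk) == 0:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                a, b = vals[p], -vals[q]
                comb = tuple(b * x + a * y for x, y in zip(rays[p], rays[q]))
                comb = scale_to_coprime_ints(comb)
                new_rays.append(comb)
                new_masks.append(_zero_mask(comb))
        # exact dedup (duplicates would poison later adjacency tests)
        seen: dict[tuple[int, ...], None] = {}
        rays, masks = [], []
        for r, m in zip(new_rays, new_masks):
            if r not in seen:
                seen[r] = None
                rays.append(r)
                masks.append(m)

    # drop the zero ray if it appeared (it cannot, but be safe) and dedup
    out = sorted({r for r, m in zip(rays, masks) if m != full})
    return out
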