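"""Elementary vectors of s-cones, polyhedral cones, and polyhedra.

Elementary vectors (EVs) are the unique conformal generators of a polyhedral
set: support-minimal vectors for s-cones, conformally non-decomposable (cND)
vectors for general cones, and convex-conformally non-decomposable (ccND)
points plus cND recession-cone rays for polyhedra. Every member of the set is
a conformal sum of EVs — a sum without cancellations, i.e. with
sign(term) <= sign(target) componentwise.

Enumeration is exact (rational arithmetic throughout). General cones are
lifted to s-cones by splitting free coordinates and slacking inequality rows
(the standard cND <-> support-minimal correspondence used by EFM tools);
polyhedra are homogenised to cones. Conformal decompositions are computed as
basic feasible solutions of an exact LP, which also yields the cardinality
bounds dim+1 and |supp(x)| + |supp(Ax)| + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from ._dd import extreme_rays_orthant
from ._rational import (
    Mat,
    Vec,
    dot,
    frac,
    mat,
    rank,
    scale_to_coprime_ints,
    sign_leq,
    support,
    vec,
)
from ._simplex import solve_standard_form


class NotPointedError(ValueError):
    """The cone has a nontrivial lineality space; EVs are not enumerated."""


class InfeasiblePolyhedronError(ValueError):
    """The polyhedron is empty (distinct from an empty EV set)."""


class MembershipError(ValueError):
    """A vector is not a member of the cone/polyhedron."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("not a member; violated rows: " + ", ".join(self.violations))


@dataclass(frozen=True)
class SCone:
    """C(S, I) = {x in R^n : x in S, x_I >= 0} with S = ker(equality_matrix)."""

    equality_matrix: Mat
    nonneg_indices: frozenset[int]
    n: int

    def __post_init__(self):
        assert all(0 <= i < self.n for i in self.nonneg_indices)
        assert all(len(r) == self.n for r in self.equality_matrix)


@dataclass(frozen=True)
class PolyCone:
    """C = {x in R^n : ineq_matrix x >= 0, eq_matrix x = 0}."""

    ineq_matrix: Mat
    n: int
    eq_matrix: Mat = ()
    row_labels: tuple[str, ...] = ()

    def contains(self, x: Sequence, atol: Fraction | float = 0) -> bool:
        x = vec(x)
        return all(dot(r, x) >= -atol for r in self.ineq_matrix) and all(
            abs(dot(r, x)) <= atol for r in self.eq_matrix
        )


@dataclass(frozen=True)
class Polyhedron:
    """P = {x in R^n : A x >= b}, rows flagged in eq_mask hold with equality."""

    ineq_matrix: Mat
    rhs: Vec
    row_labels: tuple[str, ...]
    eq_mask: tuple[bool, ...]

    def __post_init__(self):
        m = len(self.ineq_matrix)
        assert len(self.rhs) == m == len(self.row_labels) == len(self.eq_mask)

    @property
    def n(self) -> int:
        return len(self.ineq_matrix[0]) if self.ineq_matrix else 0

    def violations(self, x: Sequence, atol: Fraction | float = 0) -> list[str]:
        x = vec(x)
        out = []
        for row, b, lab, is_eq in zip(
            self.ineq_matrix, self.rhs, self.row_labels, self.eq_mask
        ):
            r = dot(row, x) - b
            if (is_eq and abs(r) > atol) or (not is_eq and r < -atol):
                out.append(lab)
        return out

    def recession_cone(self) -> PolyCone:
        ineq = tuple(r for r, e in zip(self.ineq_matrix, self.eq_mask) if not e)
        eq = tuple(r for r, e in zip(self.ineq_matrix, self.eq_mask) if e)
        labels = tuple(l for l, e in zip(self.row_labels, self.eq_mask) if not e)
        return PolyCone(ineq, self.n, eq, labels)


@dataclass(frozen=True)
class ElementaryVector:
    """One canonical representative of an EV ray (or point).

    For s-cones built on a subspace, an EV whose support avoids all
    sign-constrained coordinates represents a +/- pair; it is reported once
    (first nonzero entry positive) with sign_ambiguous set.
    """

    vector: Vec
    sign_ambiguous: bool = False


@dataclass
class ConformalDecomposition:
    """target = sum of ray terms + convex sum of point terms, conformally."""

    ray_terms: list[tuple[Vec, Fraction]]
    point_terms: list[tuple[Vec, Fraction]] = field(default_factory=list)
    convex: bool = False

    def reconstruct(self, n: int) -> Vec:
        out = [Fraction(0)] * n
        for v, c in self.ray_terms + self.point_terms:
            for i, x in enumerate(v):
                out[i] += c * x
        return tuple(out)

    @property
    def terms(self) -> list[tuple[Vec, Fraction]]:
        return self.ray_terms + self.point_terms


# ---------------------------------------------------------------------------
# lifting machinery


def _layout(n: int, nonneg: frozenset[int]) -> list[tuple[int, int]]:
    """Lifted variable layout: (coordinate, sign); free coordinates split."""
    out: list[tuple[int, int]] = []
    for i in range(n):
        out.append((i, +1))
        if i not in nonneg:
            out.append((i, -1))
    return out


def _expand(row: Sequence[Fraction], layout: list[tuple[int, int]]) -> list[Fraction]:
    return [row[i] * s for i, s in layout]


def _fold(ray: Sequence[int], layout: list[tuple[int, int]], n: int) -> Vec | None:
    """Map a lifted ray back to x; None for x+ o x- artifacts."""
    x = [Fraction(0)] * n
    seen_pos: dict[int, bool] = {}
    for (i, s), val in zip(layout, ray):
        if val:
            if i in seen_pos:
                return None  # both split halves active
            seen_pos[i] = True
            x[i] += s * val
    return tuple(x)


def enumerate_scone_evs(scone: SCone) -> list[ElementaryVector]:
    """All support-minimal vectors of C(S, I), one canonical representative
    per positive-scaling class (+/- pairs of the free part collapsed)."""
    layout = _layout(scone.n, scone.nonneg_indices)
    rows = [_expand(vec(r), layout) for r in scone.equality_matrix]
    rays = extreme_rays_orthant(rows, len(layout))
    out: dict[Vec, ElementaryVector] = {}
    for ray in rays:
        x = _fold(ray, layout, scone.n)
        if x is None:
            continue
        x = tuple(Fraction(v) for v in scale_to_coprime_ints(x))
        flippable = all(x[i] == 0 for i in scone.nonneg_indices)
        if flippable:
            first = next(v for v in x if v != 0)
            if first < 0:
                x = tuple(-v for v in x)
            out[x] = ElementaryVector(x, sign_ambiguous=True)
        else:
            out.setdefault(x, ElementaryVector(x))
    return [out[k] for k in sorted(out)]


def _lineality_dim(cone: PolyCone) -> int:
    rows = list(cone.ineq_matrix) + list(cone.eq_matrix)
    return cone.n - rank(rows) if rows else cone.n


def _unit_row_coord(row: Sequence[Fraction]) -> int | None:
    """Index i if row is a positive multiple of the unit vector e_i."""
    idx = None
    for i, x in enumerate(row):
        if x != 0:
            if idx is not None:
                return None
            idx = i
    return idx if idx is not None and row[idx] > 0 else None


def enumerate_cone_evs(cone: PolyCone) -> list[ElementaryVector]:
    """The unique minimal set of conformal generators of C, canonically
    scaled (coprime integers, positive scaling only).

    Raises NotPointedError for cones with a nontrivial lineality space.
    """
    if _lineality_dim(cone) > 0:
        raise NotPointedError(
            "cone has a nontrivial lineality space; elementary vectors are "
            "only enumerated for pointed cones"
        )
    nonneg = set()
    slacked: list[Vec] = []
    for row in cone.ineq_matrix:
        row = vec(row)
        i = _unit_row_coord(row)
        if i is not None:
            nonneg.add(i)
        else:
            slacked.append(row)
    # exact duplicate removal among slacked rows
    slacked = list(dict.fromkeys(slacked))
    layout = _layout(cone.n, frozenset(nonneg))
    n_lift = len(layout) + len(slacked)
    rows = []
    for row in cone.eq_matrix:
        rows.append(_expand(vec(row), layout) + [Fraction(0)] * len(slacked))
    for k, row in enumerate(slacked):
        slack = [Fraction(0)] * len(slacked)
        slack[k] = Fraction(-1)
        rows.append(_expand(row, layout) + slack)
    rays = extreme_rays_orthant(rows, n_lift)
    out: set[Vec] = set()
    for ray in rays:
        x = _fold(ray[: len(layout)], layout, cone.n)
        if x is None or all(v == 0 for v in x):
            continue
        out.add(tuple(Fraction(v) for v in scale_to_coprime_ints(x)))
    return [ElementaryVector(x) for x in sorted(out)]


def homogenize(poly: Polyhedron) -> PolyCone:
    """Lift P = {Ax >= b} to the cone {(x,t) : Ax - bt >= 0, t >= 0}."""
    ineq, eq, labels = [], [], []
    for row, b, lab, is_eq in zip(
        poly.ineq_matrix, poly.rhs, poly.row_labels, poly.eq_mask
    ):
        lifted = vec(row) + (-frac(b),)
        (eq if is_eq else ineq).append(lifted)
        if not is_eq:
            labels.append(lab)
    t_row = tuple(Fraction(0) for _ in range(poly.n)) + (Fraction(1),)
    ineq.append(t_row)
    labels.append("_homog t")
    return PolyCone(tuple(ineq), poly.n + 1, tuple(eq), tuple(labels))


def enumerate_polyhedron_evs(
    poly: Polyhedron,
) -> tuple[list[Vec], list[ElementaryVector]]:
    """(ccND points of P, cND generators of the recession cone).

    Points are unscaled rational vectors; rays are canonical integer rays.
    Raises InfeasiblePolyhedronError when P is empty.
    """
    cone = homogenize(poly)
    evs = enumerate_cone_evs(cone)
    points: list[Vec] = []
    rays: list[ElementaryVector] = []
    for ev in evs:
        t = ev.vector[-1]
        if t > 0:
            points.append(tuple(x / t for x in ev.vector[:-1]))
        else:
            rays.append(ElementaryVector(ev.vector[:-1]))
    if not points:
        raise InfeasiblePolyhedronError("polyhedron is empty")
    return points, rays


# ---------------------------------------------------------------------------
# conformal non-decomposability and decomposition


def is_conformally_nondecomposable(v: Sequence, cone: PolyCone) -> bool:
    """True iff no two-term sign-compatible decomposition of v into
    non-proportional cone members exists.

    A vector is cND iff it spans the minimal face of the sign-restricted cone
    C ∩ {y : sign(y) <= sign(v)}, decided by an exact rank test on the rows
    active at v plus the coordinate hyperplanes of zero entries.
    """
    v = vec(v)
    if all(x == 0 for x in v):
        raise ValueError("conformal non-decomposability is defined for nonzero vectors")
    if not cone.contains(v):
        raise MembershipError(["cone membership"])
    rows = [vec(r) for r in cone.eq_matrix]
    for r in cone.ineq_matrix:
        r = vec(r)
        if dot(r, v) == 0:
            rows.append(r)
    for i, x in enumerate(v):
        if x == 0:
            rows.append(tuple(Fraction(int(j == i)) for j in range(cone.n)))
    return rank(rows) == cone.n - 1 if rows else cone.n == 1


def is_convex_conformally_nondecomposable(x: Sequence, poly: Polyhedron) -> bool:
    """ccND test for a point of a polyhedron, via the homogenisation."""
    x = vec(x)
    viol = poly.violations(x)
    if viol:
        raise MembershipError(viol)
    return is_conformally_nondecomposable(x + (Fraction(1),), homogenize(poly))


def _candidate_vectors(
    evs: Sequence, target: Vec
) -> list[Vec]:
    """Sign-compatible candidate EVs (both orientations for ambiguous ones)."""
    cands = []
    for ev in evs:
        v = ev.vector if isinstance(ev, ElementaryVector) else vec(ev)
        if sign_leq(v, target):
            cands.append(v)
        if isinstance(ev, ElementaryVector) and ev.sign_ambiguous:
            neg = tuple(-u for u in v)
            if sign_leq(neg, target):
                cands.append(neg)
    return cands


def _nonneg_combination(
    cands: list[Vec], target: Vec, convex_cands: list[Vec] | None = None
) -> tuple[list[Fraction], list[Fraction]] | None:
    """Exact nonnegative coefficients with sum(cands_i * c_i) (+ convex part)
    = target; the convex part's coefficients sum to 1. Returns a basic
    solution (small support) or None."""
    convex_cands = convex_cands or []
    # sign-compatible candidates vanish outside supp(target), so the
    # reconstruction equations only need the support coordinates
    coords = sorted(support(target))
    a_rows = []
    b = []
    for i in coords:
        a_rows.append([c[i] for c in cands] + [p[i] for p in convex_cands])
        b.append(target[i])
    if convex_cands:
        a_rows.append([Fraction(0)] * len(cands) + [Fraction(1)] * len(convex_cands))
        b.append(Fraction(1))
    sol = solve_standard_form(a_rows, b)
    if sol is None:
        return None
    return list(sol[: len(cands)]), list(sol[len(cands) :])


def conformal_decompose(
    target: Sequence,
    geometry: PolyCone | Polyhedron | SCone,
    evs,
) -> ConformalDecomposition:
    """Decompose a member of a cone/polyhedron over precomputed EVs.

    For cones (and s-cones) returns ray terms with nonnegative coefficients;
    for polyhedra additionally point terms with convex coefficients. The
    reconstruction is exact and every term is sign-compatible with the target.
    """
    target = vec(target)
    if isinstance(geometry, Polyhedron):
        viol = geometry.violations(target)
        if viol:
            raise MembershipError(viol)
        point_evs, ray_evs = evs
        rays = _candidate_vectors(ray_evs, target)
        points = _candidate_vectors(point_evs, target)
        res = _nonneg_combination(rays, target, points)
        if res is None:  # cannot happen for a verified member with full EV set
            raise RuntimeError("conformal decomposition LP infeasible")
        rc, pc = res
        return ConformalDecomposition(
            ray_terms=[(v, c) for v, c in zip(rays, rc) if c != 0],
            point_terms=[(v, c) for v, c in zip(points, pc) if c != 0],
            convex=True,
        )
    if isinstance(geometry, SCone):
        cone = PolyCone(
            tuple(
                tuple(Fraction(int(j == i)) for j in range(geometry.n))
                for i in sorted(geometry.nonneg_indices)
            ),
            geometry.n,
            eq_matrix=mat(geometry.equality_matrix),
        )
    else:
        cone = geometry
    if not cone.contains(target):
        raise MembershipError(["cone membership"])
    cands = _candidate_vectors(evs, target)
    res = _nonneg_combination(cands, target)
    if res is None:
        raise RuntimeError("conformal decomposition LP infeasible")
    rc, _ = res
    return ConformalDecomposition(
        ray_terms=[(v, c) for v, c in zip(cands, rc) if c != 0]
    )
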