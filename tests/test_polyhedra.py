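"""Elementary-vector enumeration and conformal decomposition, checked
against worked examples and independent brute-force oracles."""

import random
from fractions import Fraction as F

import pytest

from egrowth._rational import dot, mat, sign_leq, support, vec
from egrowth.polyhedra import (
    InfeasiblePolyhedronError,
    MembershipError,
    NotPointedError,
    PolyCone,
    Polyhedron,
    SCone,
    conformal_decompose,
    enumerate_cone_evs,
    enumerate_polyhedron_evs,
    enumerate_scone_evs,
    is_conformally_nondecomposable,
    is_convex_conformally_nondecomposable,
)

from _oracles import (
    cone_evs_bruteforce,
    polytope_vertices_bruteforce,
    scone_evs_bruteforce,
)


def ivec(ev):
    return tuple(int(x) for x in ev.vector)


# ---------------------------------------------------------------------------
# worked examples


class TestSConeExamples:
    def test_branching_network(self):
        # one internal species, one uptake, two excretions; two SM vectors
        sc = SCone(mat([[1, -1, -1]]), frozenset({0, 1, 2}), 3)
        assert {ivec(e) for e in enumerate_scone_evs(sc)} == {
            (1, 1, 0),
            (1, 0, 1),
        }

    def test_half_line(self):
        sc = SCone((), frozenset({0}), 1)
        assert [ivec(e) for e in enumerate_scone_evs(sc)] == [(1,)]

    def test_line_collapses_to_signed_representative(self):
        evs = enumerate_scone_evs(SCone((), frozenset(), 1))
        assert len(evs) == 1 and evs[0].sign_ambiguous
        assert ivec(evs[0]) == (1,)

    def test_trivial_cone_is_empty(self):
        # ker of the identity is {0}
        sc = SCone(mat([[1, 0], [0, 1]]), frozenset({0, 1}), 2)
        assert enumerate_scone_evs(sc) == []


FIG7_CONE = PolyCone(
    mat([[1, -1, -1], [0, 1, 0], [0, 0, 1], [1, 0, 0], [0, 1, 0], [0, 0, 1]]), 3
)


class TestConeExamples:
    def test_minimal_growth_cone_three_generators(self):
        # growth cone of the 3-species toy model: three cND generators,
        # only the first of which is support-minimal
        assert {ivec(e) for e in enumerate_cone_evs(FIG7_CONE)} == {
            (1, 0, 0),
            (1, 1, 0),
            (1, 0, 1),
        }

    def test_quadrant(self):
        cone = PolyCone(mat([[1, 0], [0, 1]]), 2)
        assert {ivec(e) for e in enumerate_cone_evs(cone)} == {(1, 0), (0, 1)}

    def test_wedge_has_non_extreme_generator(self):
        # cone spanned by (1,1) and (1,-1): the cND vectors include (1,0),
        # which is not an extreme ray — conformal generators per orthant
        cone = PolyCone(mat([[1, 1], [1, -1]]), 2)
        assert {ivec(e) for e in enumerate_cone_evs(cone)} == {
            (1, 1),
            (1, -1),
            (1, 0),
        }

    def test_nonpointed_cone_raises(self):
        with pytest.raises(NotPointedError):
            enumerate_cone_evs(PolyCone(mat([[1, 0]]), 2))


class TestCndTest:
    @pytest.mark.parametrize(
        "v, expected",
        [((1, 1, 0), True), ((1, 0, 1), True), ((1, 0, 0), True), ((2, 1, 1), False)],
    )
    def test_fig7_members(self, v, expected):
        assert is_conformally_nondecomposable(v, FIG7_CONE) is expected

    def test_quadrant_diagonal_decomposes(self):
        cone = PolyCone(mat([[1, 0], [0, 1]]), 2)
        assert not is_conformally_nondecomposable((1, 1), cone)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            is_conformally_nondecomposable((0, 0, 0), FIG7_CONE)

    def test_nonmember_rejected(self):
        with pytest.raises(MembershipError):
            is_conformally_nondecomposable((-1, 0, 0), FIG7_CONE)


class TestPolyhedronExamples:
    def test_interval_endpoints(self):
        p = Polyhedron(mat([[1], [-1]]), vec([1, -2]), ("lo", "hi"), (False, False))
        points, rays = enumerate_polyhedron_evs(p)
        assert sorted(points) == [(F(1),), (F(2),)]
        assert rays == []

    def test_half_line(self):
        p = Polyhedron(mat([[1]]), vec([1]), ("lo",), (False,))
        points, rays = enumerate_polyhedron_evs(p)
        assert points == [(F(1),)]
        assert [tuple(int(x) for x in r.vector) for r in rays] == [(1,)]

    def test_infeasible_raises(self):
        p = Polyhedron(mat([[1], [-1]]), vec([2, -1]), ("lo", "hi"), (False, False))
        with pytest.raises(InfeasiblePolyhedronError):
            enumerate_polyhedron_evs(p)

    def test_homogenization_consistency_on_cone(self):
        # a polyhedron with b = 0 is a cone: ray EVs match the cone EVs and
        # the only ccND point is the apex 0
        rows = FIG7_CONE.ineq_matrix
        p = Polyhedron(
            rows, vec([0] * len(rows)), tuple(map(str, range(len(rows)))),
            (False,) * len(rows),
        )
        points, rays = enumerate_polyhedron_evs(p)
        assert points == [(F(0),) * 3]
        assert {tuple(int(x) for x in r.vector) for r in rays} == {
            ivec(e) for e in enumerate_cone_evs(FIG7_CONE)
        }


# ---------------------------------------------------------------------------
# randomised oracle comparisons


def random_matrix(rng, n_rows, n_cols, lo=-3, hi=3):
    return mat(
        [[rng.randint(lo, hi) for _ in range(n_cols)] for _ in range(n_rows)]
    )


@pytest.mark.parametrize("seed", range(6))
def test_scone_enumeration_matches_support_pattern_oracle(seed):
    rng = random.Random(seed)
    eq = random_matrix(rng, 4, 7)
    sc = SCone(eq, frozenset(range(7)), 7)
    got = {ivec(e) for e in enumerate_scone_evs(sc)}
    assert got == scone_evs_bruteforce(eq, 7, frozenset(range(7)))


@pytest.mark.parametrize("seed", range(8))
def test_cone_enumeration_matches_orthant_oracle_and_cnd(seed):
    rng = random.Random(100 + seed)
    n = rng.choice([3, 4])
    while True:
        rows = random_matrix(rng, rng.randint(n, n + 3), n)
        cone = PolyCone(rows, n)
        try:
            evs = enumerate_cone_evs(cone)
            break
        except NotPointedError:
            continue
    got = {ivec(e) for e in evs}
    assert got == cone_evs_bruteforce(rows, n)
    for e in evs:
        assert is_conformally_nondecomposable(e.vector, cone)
    # sums of two non-proportional EVs in a common orthant are decomposable
    for a in evs[:3]:
        for b in evs[:3]:
            if a is b:
                continue
            s = tuple(x + y for x, y in zip(a.vector, b.vector))
            if sign_leq(a.vector, s) and sign_leq(b.vector, s):
                assert not is_conformally_nondecomposable(s, cone)


@pytest.mark.parametrize("seed", range(5))
def test_polytope_points_match_vertex_oracle(seed):
    # bounded polytopes in the nonnegative orthant of R^3: ccND points are
    # exactly the vertices there
    rng = random.Random(200 + seed)
    n = 3
    rows = [vec([int(j == i) for j in range(n)]) for i in range(n)]
    b = [F(0)] * n
    for _ in range(3):
        rows.append(vec([rng.randint(-2, 2) for _ in range(n)]))
        b.append(F(rng.randint(-4, -1)))
    rows.append(vec([-1] * n))  # bounding simplex face
    b.append(F(-rng.randint(3, 6)))
    poly = Polyhedron(
        tuple(rows), tuple(b), tuple(map(str, range(len(rows)))),
        (False,) * len(rows),
    )
    try:
        points, rays = enumerate_polyhedron_evs(poly)
    except InfeasiblePolyhedronError:
        assert polytope_vertices_bruteforce(rows, b, n) == set()
        return
    assert rays == []  # bounded
    assert set(points) == polytope_vertices_bruteforce(rows, b, n)
    for p in points:
        assert is_convex_conformally_nondecomposable(p, poly)


def test_scone_cone_specialization_agree():
    # {Nv = 0, v >= 0} enumerated as an s-cone and as a general cone
    rng = random.Random(7)
    eq = random_matrix(rng, 3, 6)
    sc = SCone(eq, frozenset(range(6)), 6)
    rows = list(eq) + [tuple(-x for x in r) for r in eq]
    rows += [vec([int(j == i) for j in range(6)]) for i in range(6)]
    cone = PolyCone(mat(rows), 6)
    assert {ivec(e) for e in enumerate_scone_evs(sc)} == {
        ivec(e) for e in enumerate_cone_evs(cone)
    }


# ---------------------------------------------------------------------------
# conformal decomposition


class TestConformalDecomposition:
    def test_ev_decomposes_as_itself(self):
        evs = enumerate_cone_evs(FIG7_CONE)
        target = evs[0].vector
        dec = conformal_decompose(target, FIG7_CONE, evs)
        assert len(dec.ray_terms) == 1
        v, c = dec.ray_terms[0]
        assert tuple(c * x for x in v) == target

    def test_explicit_sum(self):
        evs = enumerate_cone_evs(FIG7_CONE)
        dec = conformal_decompose(vec([3, 1, 1]), FIG7_CONE, evs)
        assert dec.reconstruct(3) == vec([3, 1, 1])
        assert sorted(c for _, c in dec.ray_terms) == [F(1), F(1), F(1)]

    def test_membership_error_reports_rows(self):
        p = Polyhedron(mat([[1], [-1]]), vec([1, -2]), ("lo", "hi"), (False, False))
        with pytest.raises(MembershipError) as exc:
            conformal_decompose(vec([3]), p, enumerate_polyhedron_evs(p))
        assert "hi" in exc.value.violations

    @pytest.mark.parametrize("seed", range(5))
    def test_random_members_reconstruct_exactly(self, seed):
        rng = random.Random(300 + seed)
        n = rng.choice([3, 4])
        while True:
            rows = random_matrix(rng, rng.randint(n, n + 2), n)
            cone = PolyCone(rows, n)
            try:
                evs = enumerate_cone_evs(cone)
            except NotPointedError:
                continue
            if evs:
                break
        for _ in range(20):
            coeffs = [F(rng.randint(0, 5)) for _ in evs]
            target = tuple(
                sum((c * e.vector[i] for c, e in zip(coeffs, evs)), F(0))
                for i in range(n)
            )
            if all(x == 0 for x in target):
                continue
            dec = conformal_decompose(target, cone, evs)
            assert dec.reconstruct(n) == target
            for v, c in dec.ray_terms:
                assert c > 0 and sign_leq(v, target)
            ax = tuple(dot(r, target) for r in rows)
            bound = min(n, len(support(target))) + len(support(ax)) + 1
            assert len(dec.ray_terms) <= min(
                len(support(target)), bound
            )

    def test_polyhedron_decomposition_is_convex(self):
        p = Polyhedron(mat([[1], [-1]]), vec([1, -2]), ("lo", "hi"), (False, False))
        evs = enumerate_polyhedron_evs(p)
        dec = conformal_decompose(vec([F(3, 2)]), p, evs)
        assert dec.convex
        assert sum(c for _, c in dec.point_terms) == 1
        assert dec.reconstruct(1) == (F(3, 2),)


def test_exact_simplex_agrees_with_scipy_linprog():
    """Feasibility verdicts of the exact simplex match scipy's LP solver."""
    import numpy as np
    from scipy.optimize import linprog

    from egrowth._simplex import feasible_point

    rng = random.Random(42)
    for _ in range(25):
        n, m = 4, 3
        a = [[rng.randint(-3, 3) for _ in range(n)] for _ in range(m)]
        b = [rng.randint(-2, 2) for _ in range(m)]
        exact = feasible_point(
            n=n, ineq_rows=[(vec(r), F(bb)) for r, bb in zip(a, b)]
        )
        res = linprog(
            c=[0.0] * n,
            A_ub=(-np.array(a, dtype=float)),
            b_ub=(-np.array(b, dtype=float)),
            bounds=[(0, None)] * n,
        )
        assert (exact is not None) == res.success
        if exact is not None:
            assert all(
                sum(r[i] * exact[i] for i in range(n)) >= bb
                for r, bb in zip(a, b)
            )
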