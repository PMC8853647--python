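"""The polyhedral layer on its own: elementary vectors and conformal sums.

Elementary vectors generalise elementary flux modes: support-minimal vectors
for flux cones (s-cones), conformally non-decomposable vectors for general
cones, and convex-conformally non-decomposable points for polyhedra.
"""

from egrowth import (
    PolyCone,
    SCone,
    conformal_decompose,
    enumerate_cone_evs,
    enumerate_scone_evs,
    is_conformally_nondecomposable,
)
from egrowth._rational import mat, vec

# a branching flux cone: S -> X, X -> P1, X -> P2 (all irreversible)
scone = SCone(mat([[1, -1, -1]]), frozenset({0, 1, 2}), 3)
print("flux cone EVs (classical EFMs):",
      [tuple(map(int, e.vector)) for e in enumerate_scone_evs(scone)])

# a growth cone: production allowed (Nv >= 0), not forced to zero
cone = PolyCone(
    mat([[1, -1, -1], [0, 1, 0], [0, 0, 1],
         [1, 0, 0], [0, 1, 0], [0, 0, 1]]), 3
)
evs = enumerate_cone_evs(cone)
print("growth cone EVs (cND generators):",
      [tuple(map(int, e.vector)) for e in evs])
print("(2,1,1) conformally non-decomposable?",
      is_conformally_nondecomposable(vec([2, 1, 1]), cone))

dec = conformal_decompose(vec([3, 1, 1]), cone, evs)
terms = " + ".join(f"{c}*{tuple(map(int, v))}" for v, c in dec.ray_terms)
print("conformal sum: (3,1,1) =", terms)

print(
    "\nThe growth cone needs three generators although it is 3-dimensional:"
    "\nconformal (cancellation-free) generation is finer than conic spanning,"
    "\nwhich is exactly why EGMs are not support-minimal in general."
)
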