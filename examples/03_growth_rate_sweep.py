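"""Sweep growth rate: EGV families, the critical and maximum growth rates.

EGV families (identified by their inactive-constraint signatures) are tracked
across a growth-rate grid; bisection locates mu_crit (where the 24 regime-L
families merge into 10) and mu_max (where the growth polyhedron empties).
"""

from collections import Counter

from egrowth import (
    CapacityParams,
    build_self_fabricating_model,
    capacity_constraints,
    sweep_mu,
)

model = build_self_fabricating_model()
params = CapacityParams.defaults()
sweep = sweep_mu(model, lambda mu: capacity_constraints(model, params, mu))

print(f"mu_crit = {float(sweep.mu_crit):.4f}/h   mu_max = {float(sweep.mu_max):.4f}/h")
print(f"{len(sweep.families)} EGV families across the sweep")
print("persistence:", dict(Counter(sweep.regime(f) for f in sweep.families.values())))
print("uptake classes:", dict(Counter(f.uptake_class for f in sweep.families.values())))
print("ribosome classes:", dict(Counter(f.ribosome_class for f in sweep.families.values())))
merges = Counter(tuple(sorted(t)) for t in sweep.merge_map.values())
for target, n in merges.items():
    print(f"{n} regime-L families merge into the EGV with inactive {target}")

print(
    "\nBelow mu_crit the cell can over-express either importer; above it the"
    "\ntwo importer-excess strategies are the only ones left, and at mu_max"
    "\n(~ the ribosome's self-replication limit k_el/n_R) everything merges."
)
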