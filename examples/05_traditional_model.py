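"""Collapse the comprehensive model to a traditional fixed-biomass model.

The metabolic submatrix plus one biomass column (the max-growth composition,
with macromolecules replaced by their amino-acid content) yields a single EFM
and, under capacity bounds, a single EFV: a traditional model is feasible but
carries no information about alternative biomass compositions.
"""

from fractions import Fraction as F

from egrowth import (
    CapacityParams,
    build_self_fabricating_model,
    build_traditional_model,
    capacity_constraints,
    enumerate_egvs,
    state_of,
    total_amino_acid_content,
)
from egrowth.fixtures import max_growth_flux_bounds, traditional_efms, traditional_efvs

model = build_self_fabricating_model()
params = CapacityParams.defaults()
mu = F(1262, 1000)  # just below the maximum growth rate
res = enumerate_egvs(model, capacity_constraints(model, params, mu), mu)
ref = state_of(model, res.records[0].flux)
print(f"reference composition at mu = {float(mu)}/h; "
      f"x_AA^tot = {float(total_amino_acid_content(model, ref.concentrations)):.3e} mol/g")

trad = build_traditional_model(model, ref)
print("traditional model:", trad.species, "->", trad.reactions)

efms = traditional_efms(trad)
points, rays = traditional_efvs(
    trad, max_growth_flux_bounds(model, ref, params.kcat)
)
print(f"EFMs: {len(efms)}   EFVs under capacity bounds: {len(points)}")

print(
    "\nOne EFM / one EFV versus 11 EGMs and 24 (or 10) EGVs in the"
    "\ncomprehensive model: fixing biomass composition collapses the entire"
    "\nphenotype space to a single pathway."
)
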