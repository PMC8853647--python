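# egrowth — elementary growth modes and vectors for self-fabricating cells

`egrowth` is a Python library (with a thin CLI) for the unbiased analysis of
**next-generation metabolic models**: models in which the synthesis of every
macromolecule — enzymes, importers, the ribosome — is an explicit reaction,
so that biomass composition is a *prediction* rather than a fixed input. It
is aimed at researchers in constraint-based modelling and resource
allocation who want the analogue of elementary-flux-mode analysis for such
self-fabricating models.

## The objects it computes

A growth model couples fluxes `v` (mol g⁻¹ h⁻¹) to concentrations
`x` (mol g⁻¹) through the stoichiometric matrix `N` and the molar masses
`ω` (g mol⁻¹). At balanced growth

```
N v = μ x ≥ 0,   v_I ≥ 0,   ωᵀ x = 1,   μ = ωᵀ N v ,
```

so the feasible fluxes form the **growth cone**
`C_g = {v : Nv ≥ 0, v_I ≥ 0}` — a *general* polyhedral cone, unlike the
classical flux cone `{Nv = 0, v_I ≥ 0}`. Its unique conformal generators
(sums without cancellations, `sign(e) ≤ sign(v)` per term) are the
**elementary growth modes (EGMs)**: conformally non-decomposable, but not
support-minimal in general. Linear capacity and membrane constraints
`Ax + Bv ≥ b` at fixed growth rate μ turn the cone into the **growth
polyhedron**

```
P_g(μ) = {v : Nv ≥ 0, v_I ≥ 0, ωᵀNv = μ, (AN + μB)v ≥ μb},
```

whose generators are the **elementary growth vectors (EGVs)**:
convex-conformally non-decomposable points plus conformally
non-decomposable recession-cone rays. Every feasible flux — and every
feasible biomass composition `x(v) = Nv/μ` — is a convex, conformal mixture
of EGVs. EGVs are characterised by their *inactive* (strictly slack)
inequality constraints rather than by their supports.

All enumeration runs in **exact rational arithmetic** (a built-in double
description core plus an exact simplex for feasibility and decomposition
LPs), so counts, signatures and decompositions are exact, not numerical.

The package also classifies **autocatalysis** (basically catalytic /
catalytically closed / autocatalytic growth modes, minimal autocatalytic
reaction sets) and **kinetic consistency**, and ships three built-in models:
an 11-species self-fabricating cell (glucose and ammonium uptake, amino-acid
and lipid synthesis, expression of all enzymes and the ribosome), a minimal
two-pathway model, and a constructor that collapses any comprehensive model
to a traditional fixed-biomass model.

## Worked example

```python
from fractions import Fraction as F
from egrowth import (build_self_fabricating_model, CapacityParams,
                     capacity_constraints, enumerate_egms, enumerate_egvs,
                     sweep_mu)

model = build_self_fabricating_model()
params = CapacityParams.defaults()

egms = enumerate_egms(model, normalize_mu=1)
print(len(egms))                      # 11 — one EGM per molecular species

res = enumerate_egvs(model, capacity_constraints(model, params, F(1, 2)), F(1, 2))
print(len(res.records))               # 24 point EGVs at mu = 0.5/h

sweep = sweep_mu(model, lambda mu: capacity_constraints(model, params, mu))
print(round(float(sweep.mu_crit), 2), # 1.21 — 24 EGV families merge to 10
      round(float(sweep.mu_max), 2))  # 1.26 — growth polyhedron empties
```

The 11 EGMs each produce exactly one species (the stoichiometric matrix is
square). At any growth rate below `mu_crit` there are 24 EGVs, each with
full support and exactly two inactive constraints; between `mu_crit` and
`mu_max` ten remain. `mu_max` sits just below the ribosome's
self-replication limit `k_el/n_R ≈ 1.27 h⁻¹` — the membrane lipid mass
claims the difference. Sweeping μ also classifies the EGV families by
uptake/storage behaviour (low-ammonium families store carbon; the
high-ammonium families approach an uptake share of 0.87 as μ → 0) and by
ribosome content (a constant class at mass fraction ≈ 0.9, a
proportional-to-μ class, and a nonlinear class).

The scripts in `examples/` run one capability each and print these numbers
with a short interpretation; the CLI exposes the same operations
(`egrowth egm self-fabricating`, `egrowth sweep self-fabricating`, ...).

## Layout

- `egrowth.polyhedra` — elementary vectors of s-cones, cones, polyhedra;
  conformal decomposition; (c)cND tests (exact arithmetic).
- `egrowth.model`, `egrowth.fixtures` — growth models, validation, mass
  derivation, built-in models.
- `egrowth.egm`, `egrowth.constraints` — growth cones/EGMs; constraints,
  growth polyhedra, EGVs, growth-rate sweeps and classification.
- `egrowth.autocat` — BC/CC/AC classification, MAC sets, kinetic consistency.
- `egrowth.io`, `egrowth.cli` — JSON/TSV/CSV formats, random model
  generator, command-line interface.

See `docs/methods.md` for the model assumptions, parameter choices, and
numerical conventions.
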