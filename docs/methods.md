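# Methods

## The growth model

A growth model is a tuple (Mol, Rxn, N, ω, I, Cat): molecular species with
molar masses ω > 0 (g mol⁻¹), reactions with exact rational stoichiometry N
(species × reactions), an irreversible subset I, and a partial catalyst map
Cat: reaction → species. Concentrations x are per gram dry weight
(mol g⁻¹), fluxes v per gram dry weight and hour. Balanced exponential
growth at rate μ (h⁻¹) means every species is synthesised in proportion to
its abundance: Nv = μx with the dry-mass normalisation ωᵀx = 1, hence
μ = ωᵀNv. Mass conservation of internal reactions (ωᵀN_int = 0) makes μ a
function of the exchange fluxes alone; `growth_rate` asserts this identity
on every call. Validation additionally rejects semipositive conservation
laws (y ≥ 0, y ≠ 0, Nᵀy = 0, decided by an exact LP with the normalisation
Σy = 1): a conserved pool can neither be diluted nor duplicated, so no such
model can grow.

Exchange reactions are detected as the columns that violate ωᵀN_col = 0;
when a model file declares the partition explicitly, the declaration wins
and validation flags any internal column that fails mass balance. Molar
masses given only for exchanged nutrients are completed by solving
ωᵀN_int = 0 exactly; the solve fails loudly if the internal network leaves a
mass undetermined or forces a nonpositive one.

## Elementary vectors

The polyhedral layer treats three geometries, all over exact rationals:

* **s-cones** {x ∈ ker E, x_I ≥ 0}: elementary vectors are the
  support-minimal members (classical EFMs when E = N).
* **general cones** {x : Ax ≥ 0}: elementary vectors are the conformally
  non-decomposable (cND) members — x admits no decomposition x¹ + x² into
  non-proportional members with sign(xⁱ) ≤ sign(x). These are exactly the
  extreme rays of C ∩ O over all closed orthants O, and can outnumber the
  extreme rays of C.
* **polyhedra** {x : Ax ≥ b}: convex-conformally non-decomposable (ccND)
  points plus cND rays of the recession cone {Ax ≥ 0}.

Enumeration reduces everything to one primitive: extreme rays of
{v ≥ 0 : Mv = 0}, computed by the incremental double description method
(unit rays of the orthant, one hyperplane at a time, combinatorial
adjacency test on coordinate zero-sets stored as bitmasks, rays kept as
coprime integer vectors). General cones are lifted by splitting free
coordinates into positive/negative parts and slacking inequality rows —
the standard correspondence between cND vectors and support-minimal vectors
of the lift; split artifacts (x⁺∘x⁻ ≠ 0) are discarded. Rows that are
positive multiples of unit vectors are recognised as sign constraints and
not slacked, and exact duplicate rows are dropped; both reductions shrink
the lift without changing the result. Polyhedra are homogenised to
{(x, t) : Ax − bt ≥ 0, t ≥ 0}; lifted EVs with t > 0 are normalised to
t = 1 (ccND points, reported unscaled), those with t = 0 are recession-cone
rays (reported as coprime integer vectors). An empty point set means the
polyhedron is infeasible and raises a dedicated error; the EGV layer
converts it into a first-class infeasibility result because the μ_max
bisection consumes it.

Cones with a nontrivial lineality space raise a diagnostic instead of
enumerating: growth cones are pointed in practice (irreversibility), and
elementary vectors modulo lineality are not defined here. Equality rows are
kept as equalities in the backend (never split into inequality pairs), so
active-set signatures are unambiguous. The cND test is an exact rank test:
v is cND iff the rows active at v, together with the coordinate hyperplanes
of its zero entries, have rank n − 1 (v spans the minimal face of the
sign-restricted cone). The ccND test applies the same criterion to (x, 1)
in the homogenisation.

Conformal decomposition is computed as a basic feasible solution of an
exact LP (phase-1 simplex with Bland's rule, all-Fraction tableau): target =
Σ λ_e e over the sign-compatible EVs, restricted to the support coordinates
of the target, plus a convexity row for point terms. A basic solution has
at most as many nonzero terms as equation rows, which yields the
|supp(x)|-type cardinality bounds directly; reconstruction is exact by
construction. Sign-ambiguous s-cone EVs (support disjoint from the
sign-constrained coordinates) are reported once with the first nonzero
entry positive — a reporting convention, nothing more — and both
orientations enter decompositions as candidates.

Float inputs are accepted (converted exactly) and membership checks take an
optional absolute tolerance (1e-9 is a sensible choice); enumeration itself
is always exact, because ray enumeration is numerically brittle and the
case-study claims are counting claims.

## The self-fabricating cell

The built-in cell takes up glucose (G, 180 g mol⁻¹) and ammonium
(N, 18 g mol⁻¹) through importers IG/IN, forms amino acids
(AA: G + N → AA, hence 198 g mol⁻¹) via enzyme EAA, lipid droplets
(LD: 7 G → LD) via ELD, membrane lipids (L: LD → L) via EL, and polymerises
amino acids into the importers (646 AA each), the enzymes (325 AA each) and
the ribosome itself (22 608 AA, counting RNA as amino-acid equivalents).
All 11 reactions are irreversible and catalysed; the stoichiometric matrix
is square, which is why each of the 11 EGMs produces exactly one species.

Capacity and membrane constraints, in canonical units (h, mol, g, m):

* importer/enzyme capacity v ≤ k_cat·x_cat with k_cat = 79 s⁻¹ = 284 400 h⁻¹;
* ribosome capacity Σᵢ nᵢwᵢ ≤ k_el·x_R with k_el = 8 AA s⁻¹ = 28 800 AA h⁻¹
  (nᵢ read off the AA row of N, so the row adapts to any model);
* membrane area equality A_L·x_L + A_I·(x_IG + x_IN) = r(μ)/(ρN_A) with
  A_L = 0.5 nm², A_I = 48 nm², ρ = 290 g L⁻¹ = 2.9·10⁵ g m⁻³,
  N_A = 6.02214076·10²³ mol⁻¹, and surface-to-volume ratio
  r(μ) = (9.3 − 2.8·μ[h]) μm⁻¹ (an inverse length, as dimensional analysis
  of the equality requires; both sides are m² mol g⁻¹);
* minimum lipid area fraction (1 − α)A_L·x_L ≥ α·A_I·(x_IG + x_IN), α = 0.5.

r(μ) > 0 restricts μ < 9.3/2.8 ≈ 3.32 h⁻¹; the constraint builder rejects
growth rates outside that range. All parameters are stored as exact
rationals, so P_g(μ) is exact for rational μ.

Two structural consequences anchor the numbers. At the ribosome's
self-replication limit, Σnᵢwᵢ = k_el·x_R with all mass in protein gives
μ ≤ k_el/n_R ≈ 1.274 h⁻¹; the computed μ_max ≈ 1.264 h⁻¹ is slightly lower
because the membrane equality forces a lipid mass share of several percent.
The same lipid share explains why the balanced-uptake EGVs sit at
γ_IN ≈ 0.081–0.087 rather than exactly at the analytic equal-uptake value
ω_N/(ω_G + ω_N) = 1/11 ≈ 0.091: membrane carbon consumes glucose without
ammonium.

## EGV signatures, sweeps and classes

An EGV is identified by its inactive-constraint signature. Reported
signatures are restricted to the informative rows: mass-balance rows of
species that some reaction consumes (G, LD, N, AA here) plus the inequality
constraint rows (six capacities and the lipid-fraction bound — 11 rows in
total). Irreversibility rows and mass-balance rows of never-consumed
species are slack for every full-support EGV and carry no information; the
full slack set is still stored on each record. With this convention every
EGV of the case study has exactly two inactive constraints, and the
signature map is injective and stable within a regime.

`sweep_mu` scans a μ grid (default 0.05 h⁻¹ steps from 0.05), locates μ_max
by bisection on LP feasibility and μ_crit by bisection on the point-EGV
count, both to 10⁻⁴ h⁻¹, and keys families by signature. Merge events are
resolved by flux proximity at μ_crit ± 10⁻⁴: each regime-L-only family is
matched to the nearest regime-H EGV; in the case study two groups of eight
merge into the two H-only EGVs. The grid and tolerances are package
defaults chosen so the full sweep (≈ 35 enumerations, each a fraction of a
second at this model size) finishes in a few seconds; enumeration cost
grows combinatorially with network size, and genome-scale models are out of
scope.

Families are classified twice:

* **Uptake/storage** (classes 1/2/3 × a/b): by γ_IN at the family's lowest
  sampled μ — class 1 below half the balanced value ω_N/(ω_G+ω_N), class 2
  above 1/2, class 3 in between; suffix a if the family exists on both
  sides of μ_crit, b otherwise. Low ammonium uptake coincides with high
  carbon storage s_C = ω_G x_G + ω_LD x_LD + ω_L x_L; s_C is non-increasing
  in μ throughout regime L for every family, while in regime H the membrane
  term ω_L x_L can rise again as μ_max is approached (at μ_max there is no
  storage except membrane lipids).
* **Ribosome content** (classes I/II/III): class III if ω_R x_R is almost
  constant over the validity interval (range ≤ 0.1 — the observed constant
  class varies by ≈ 0.05 around 0.9, the next-flattest family by ≈ 0.8);
  class II if almost proportional to μ (best through-origin fit with
  residual ≤ 0.05); class I otherwise. These thresholds are package
  conventions for an intrinsically qualitative distinction; on the case
  study they give 12 nonlinear, 9 proportional and 5 constant families,
  with clear margins between the groups.

The low-μ limit of γ_IN for the high-ammonium families is estimated by
linear extrapolation from μ = 0.02 and 0.01 h⁻¹ (the trajectories are
nearly affine there); it converges to ≈ 0.87 rather than 1 because the
membrane equality forces a minimum importer-plus-lipid investment.

## Autocatalysis

BC/CC/AC follow the coarse-grained definitions: BC = some active reaction
is catalytic; CC = every catalyst of an active catalytic reaction is
produced, tested as the exact condition (Nv)_s > 0 (production, which
implies a positive associated concentration when μ > 0); AC = BC ∧ CC.
Kinetic consistency demands (Nv)_s > 0 for *every* species with a nonzero
stoichiometric entry in an active reaction. MAC sets are found by searching
the union lattice of EGM supports (every growth mode's support is a union
of EGM supports) in order of increasing size with superset pruning;
AC-feasibility of a candidate support is one exact LP — v fixed to zero off
the support, v ≥ 1 on it, Nv ≥ 0, and (Nv)_cat ≥ 1 for each required
catalyst (strictness via scaling, since the feasible set is a cone). The
lattice search is exponential in the number of EGMs and intended for
coarse-grained models of this size.

## Traditional-model comparison

`build_traditional_model` keeps the metabolite rows and metabolic columns
and appends a biomass column consuming G, N, AA, LD, L in proportion to a
reference composition, with macromolecules replaced by their total
amino-acid content x_AA^tot = n_I(x_IG+x_IN) + n_E(x_EAA+x_ELD+x_EL) +
n_R·x_R + x_AA. The column is scaled by x̄ = the total biomass-precursor
concentration of the reference state, making its entries dimensionless
with unit mass (ωᵀ·column·x̄ = −1 g/g). The resulting flux cone has a
single EFM; adding capacity bounds v_r ≤ k_cat·x_cat at the reference
composition yields a single nonzero EFV (the zero flux, a trivially ccND
member of any flux polyhedron containing it, is reported by the generic
layer but excluded from the EFV count). The comparison isolates what fixing
biomass composition destroys: all information about alternative
allocations.

## The minimal two-pathway model and random models

The minimal model (AA, E1, E2, R; two substrate-implicit uptake routes
catalysed by E1/E2, unit-coefficient synthesis of E1, E2, R from AA by the
ribosome, all masses 1 by balance from ω_AA = 1) exercises the claims that
are parameter-free: in full flux space the growth cone has 8 EGMs (each
uptake route duplicates each producer), collapsing to 4 — one per species —
after scaling to μ = 1 and projection onto the synthesis fluxes; the MAC
sets project to {w₁, w_R} and {w₂, w_R}, one minimal self-fabricating
pathway per substrate.

`generate_random_model` builds property-test inputs that validate by
construction: every metabolite imported (so no semipositive left-kernel
vector exists), internal conversions mass-balanced by solving the last
coefficient, macromolecule masses derived from their synthesis
stoichiometry, catalysts drawn among the macromolecules; deterministic per
seed, with a bounded regenerate-on-failure loop as a safety net. It
emulates the *structure* of coarse-grained growth models, not biological
parameter distributions: passing property tests on these inputs
demonstrates algebraic correctness (validation, exactness, conformal
reconstruction), not predictive realism on real networks.

## Known limitations

Enumeration is exact but exponential: this is a desk-scale research tool,
not a genome-scale one. Thermodynamic feasibility, detailed (mechanistic)
catalysis models, and kinetic (equality-constrained) growth polytopes
beyond generic equality-row support are out of scope. The ribosome-class
thresholds and the merge-matching heuristic are conventions; both are
documented above and easy to override by consuming the per-family
trajectories directly.
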