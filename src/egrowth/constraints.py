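"""Capacity/membrane constraints, growth polyhedra, and elementary growth
vectors (EGVs).

Beyond stoichiometry, a constraint-based growth model carries linear
constraints A x + B v >= b coupling concentrations and fluxes: catalytic
capacity (a flux cannot exceed k_cat times the concentration of its enzyme;
total protein synthesis cannot exceed the ribosome's elongation capacity) and
membrane geometry (lipids and importers must tile the cell surface, with a
minimum lipid fraction). At fixed growth rate mu the concentrations are
x = Nv / mu, so the feasible fluxes form a polyhedron

    P_g(mu) = {v : Nv >= 0, v_I >= 0, omega^T N v = mu, (A N + mu B) v >= mu b}.

Its elementary vectors — convex-conformally non-decomposable growth vectors
plus conformally non-decomposable recession-cone rays — are the EGVs. EGVs
are characterised not by their supports (they typically have full support)
but by which inequality constraints they leave *inactive* (strictly slack).

All quantities are exact rationals; growth rates should be passed as
Fractions or strings ("1/2", "0.05") to keep enumeration exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

from ._rational import Vec, dot, frac, mat_vec, vec
from ._simplex import feasible_point
from .model import GrowthModel
from .polyhedra import (
    ConformalDecomposition,
    InfeasiblePolyhedronError,
    Polyhedron,
    conformal_decompose,
    enumerate_polyhedron_evs,
)

AVOGADRO = Fraction(602214076) * 10**15  # 6.02214076e23 / mol


@dataclass(frozen=True)
class ConstraintRow:
    label: str
    relation: str  # ">=" or "=="
    conc: Mapping[str, Fraction]  # coefficients on species (A row)
    flux: Mapping[str, Fraction]  # coefficients on reactions (B row)
    rhs: Fraction


@dataclass(frozen=True)
class ConstraintSet:
    """Rows of A x + B v {>=,==} b with human-readable labels."""

    rows: tuple[ConstraintRow, ...]

    def __post_init__(self):
        labels = [r.label for r in self.rows]
        assert len(set(labels)) == len(labels), "constraint labels must be unique"

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rows)


@dataclass(frozen=True)
class CapacityParams:
    """Physical parameters of the capacity and membrane constraints.

    Canonical units: time h, amount mol, mass g, length m. The surface-to-
    volume ratio is the affine function r(mu) = s2v_intercept - s2v_slope*mu.
    """

    kcat: Fraction  # importer/enzyme turnover, 1/h
    kel: Fraction  # ribosome elongation rate, AA/h
    area_L: Fraction  # membrane area per lipid, m^2
    area_I: Fraction  # membrane area per importer, m^2
    s2v_intercept: Fraction  # 1/m
    s2v_slope: Fraction  # 1/m per (1/h)
    density: Fraction  # cell density, g/m^3
    alpha: Fraction  # minimum lipid area fraction
    avogadro: Fraction = AVOGADRO

    def __post_init__(self):
        assert 0 < self.alpha < 1
        assert min(self.kcat, self.kel, self.area_L, self.area_I, self.density) > 0

    @classmethod
    def defaults(cls) -> "CapacityParams":
        """Measured values: k_cat = 79/s, k_el = 8 AA/s, A_L = 0.5 nm^2,
        A_I = 48 nm^2, r(mu) = (9.3 - 2.8 mu[h]) / um, rho = 290 g/L."""
        return cls(
            kcat=Fraction(79 * 3600),
            kel=Fraction(8 * 3600),
            area_L=Fraction(1, 2 * 10**18),
            area_I=Fraction(48, 10**18),
            s2v_intercept=Fraction(93, 10) * 10**6,
            s2v_slope=Fraction(28, 10) * 10**6,
            density=Fraction(290) * 10**3,
            alpha=Fraction(1, 2),
        )

    def surface_to_volume(self, mu: Fraction) -> Fraction:
        return self.s2v_intercept - self.s2v_slope * mu


def capacity_constraints(
    model: GrowthModel, params: CapacityParams, mu
) -> ConstraintSet:
    """Capacity and membrane constraints of the self-fabricating cell.

    Five catalytic capacities k_cat x_cat - v >= 0, one ribosome capacity
    k_el x_R - sum_i n_i w_i >= 0, the membrane area equality
    A_L x_L + A_I (x_IG + x_IN) = r(mu) / (rho N_A), and the minimum lipid
    area fraction (1-alpha) A_L x_L - alpha A_I (x_IG + x_IN) >= 0.
    """
    mu = frac(mu)
    r_mu = params.surface_to_volume(mu)
    if r_mu <= 0:
        raise ValueError(f"surface-to-volume ratio nonpositive at mu = {mu}")
    rows: list[ConstraintRow] = []
    for rxn, cat in (
        ("r_IG", "IG"),
        ("r_IN", "IN"),
        ("r_EAA", "EAA"),
        ("r_ELD", "ELD"),
        ("r_EL", "EL"),
    ):
        rows.append(
            ConstraintRow(
                label=f"cap {cat}",
                relation=">=",
                conc={cat: params.kcat},
                flux={rxn: Fraction(-1)},
                rhs=Fraction(0),
            )
        )
    # ribosome capacity: amino acids polymerised per unit time vs k_el x_R;
    # n_i is the AA consumption of each synthesis reaction
    aa = model.species_index("AA")
    flux_coeffs = {}
    for j, rxn in enumerate(model.reactions):
        n_aa = -model.stoich[aa][j]
        if n_aa > 0:
            flux_coeffs[rxn] = -n_aa
    rows.append(
        ConstraintRow(
            label="cap R",
            relation=">=",
            conc={"R": params.kel},
            flux=flux_coeffs,
            rhs=Fraction(0),
        )
    )
    rows.append(
        ConstraintRow(
            label="memb area",
            relation="==",
            conc={
                "L": params.area_L,
                "IG": params.area_I,
                "IN": params.area_I,
            },
            flux={},
            rhs=r_mu / (params.density * params.avogadro),
        )
    )
    rows.append(
        ConstraintRow(
            label="memb L",
            relation=">=",
            conc={
                "L": (1 - params.alpha) * params.area_L,
                "IG": -params.alpha * params.area_I,
                "IN": -params.alpha * params.area_I,
            },
            flux={},
            rhs=Fraction(0),
        )
    )
    return ConstraintSet(tuple(rows))


def growth_polyhedron(model: GrowthModel, cs: ConstraintSet, mu) -> Polyhedron:
    """P_g(mu) in flux space: x = Nv/mu eliminated from every A x + B v row."""
    mu = frac(mu)
    if mu <= 0:
        raise ValueError("growth polyhedron requires mu > 0")
    n = model.n_reactions
    rows, rhs, labels, eq_mask = [], [], [], []
    for i, s in enumerate(model.species):
        rows.append(vec(model.stoich[i]))
        rhs.append(Fraction(0))
        labels.append(f"mb {s}")
        eq_mask.append(False)
    for j, r in enumerate(model.reactions):
        if r in model.irreversible:
            rows.append(tuple(Fraction(int(k == j)) for k in range(n)))
            rhs.append(Fraction(0))
            labels.append(f"irr {r}")
            eq_mask.append(False)
    # dry-mass normalisation omega^T N v = mu
    rows.append(
        tuple(
            dot(model.molar_masses, model.column(j)) for j in range(n)
        )
    )
    rhs.append(mu)
    labels.append("dry mass")
    eq_mask.append(True)
    for crow in cs.rows:
        a = [crow.conc.get(s, Fraction(0)) for s in model.species]
        combined = [
            dot(a, model.column(j)) + mu * crow.flux.get(r, Fraction(0))
            for j, r in enumerate(model.reactions)
        ]
        rows.append(tuple(combined))
        rhs.append(mu * crow.rhs)
        labels.append(crow.label)
        eq_mask.append(crow.relation == "==")
    return Polyhedron(tuple(rows), tuple(rhs), tuple(labels), tuple(eq_mask))


def signature_constraints(model: GrowthModel, cs: ConstraintSet) -> tuple[str, ...]:
    """Inequality labels that characterise EGVs.

    Mass-balance rows of species consumed by at least one reaction, plus the
    inequality rows of the additional constraints. Irreversibility rows and
    mass-balance rows of never-consumed species are slack for every
    full-support growth vector and carry no information.
    """
    consumed = [
        s
        for i, s in enumerate(model.species)
        if any(c < 0 for c in model.stoich[i])
    ]
    out = [f"mb {s}" for s in consumed]
    out += [r.label for r in cs.rows if r.relation == ">="]
    return tuple(out)


@dataclass(frozen=True)
class GrowthVectorRecord:
    """A point EGV of P_g(mu) with derived quantities."""

    flux: Vec
    growth_rate: Fraction
    concentrations_assoc: Vec
    inactive_all: frozenset[str]  # every strictly slack inequality label
    inactive_signature: frozenset[str]  # restricted to signature_constraints
    mass_fractions: Vec

    def gamma(self, model: GrowthModel, reaction: str) -> Fraction:
        """Uptake fraction: mass imported by `reaction` per unit growth."""
        j = model.reaction_index(reaction)
        col_mass = dot(model.molar_masses, model.column(j))
        return col_mass * self.flux[j] / self.growth_rate

    def mass_fraction(self, model: GrowthModel, species: str) -> Fraction:
        return self.mass_fractions[model.species_index(species)]

    def carbon_storage(
        self, model: GrowthModel, species: Sequence[str] = ("G", "LD", "L")
    ) -> Fraction:
        """s_C: mass fraction stored in glucose and lipids."""
        return sum(
            (self.mass_fraction(model, s) for s in species), Fraction(0)
        )


@dataclass
class EGVResult:
    """EGV enumeration at one growth rate; infeasibility is a result, not an
    exception (the feasibility boundary is located by bisection)."""

    mu: Fraction
    feasible: bool
    records: list[GrowthVectorRecord] = field(default_factory=list)
    ray_fluxes: list[Vec] = field(default_factory=list)

    @property
    def signatures(self) -> set[frozenset[str]]:
        return {r.inactive_signature for r in self.records}


def _make_record(
    model: GrowthModel, poly: Polyhedron, sig_labels: tuple[str, ...], mu: Fraction, v: Vec
) -> GrowthVectorRecord:
    nv = mat_vec(model.stoich, v)
    x = tuple(c / mu for c in nv)
    inactive = set()
    for row, b, lab, is_eq in zip(poly.ineq_matrix, poly.rhs, poly.row_labels, poly.eq_mask):
        if not is_eq and dot(row, v) > b:
            inactive.add(lab)
    mf = tuple(m * c for m, c in zip(model.molar_masses, x))
    return GrowthVectorRecord(
        flux=v,
        growth_rate=mu,
        concentrations_assoc=x,
        inactive_all=frozenset(inactive),
        inactive_signature=frozenset(inactive) & frozenset(sig_labels),
        mass_fractions=mf,
    )


def enumerate_egvs(model: GrowthModel, cs: ConstraintSet, mu) -> EGVResult:
    """Point EGVs of P_g(mu) plus cND rays of its recession cone."""
    mu = frac(mu)
    poly = growth_polyhedron(model, cs, mu)
    sig = signature_constraints(model, cs)
    try:
        points, rays = enumerate_polyhedron_evs(poly)
    except InfeasiblePolyhedronError:
        return EGVResult(mu=mu, feasible=False)
    records = [_make_record(model, poly, sig, mu, p) for p in points]
    records.sort(key=lambda r: r.flux)
    return EGVResult(
        mu=mu,
        feasible=True,
        records=records,
        ray_fluxes=[ev.vector for ev in rays],
    )


def decompose_growth_vector(
    model: GrowthModel, cs: ConstraintSet, mu, v: Sequence,
    egvs: EGVResult | None = None,
) -> ConformalDecomposition:
    """Convex-conformal decomposition of a growth vector over the EGVs.

    The point coefficients are convex and the associated concentrations mix
    linearly: x(v) = sum lambda_e x(e)."""
    mu = frac(mu)
    v = vec(v)
    poly = growth_polyhedron(model, cs, mu)
    res = enumerate_egvs(model, cs, mu) if egvs is None else egvs
    if not res.feasible:
        raise InfeasiblePolyhedronError(f"P_g({mu}) is empty")
    return conformal_decompose(
        v, poly, ([r.flux for r in res.records], res.ray_fluxes)
    )


# ---------------------------------------------------------------------------
# growth-rate sweeps


@dataclass
class EGVFamily:
    """One EGV tracked across growth rates by its inactive signature."""

    signature: frozenset[str]
    samples: dict[Fraction, GrowthVectorRecord] = field(default_factory=dict)
    uptake_class: str | None = None
    ribosome_class: str | None = None

    @property
    def mus(self) -> list[Fraction]:
        return sorted(self.samples)

    @property
    def mu_interval(self) -> tuple[Fraction, Fraction]:
        ms = self.mus
        return ms[0], ms[-1]


@dataclass
class MuSweepResult:
    """EGV families across a growth-rate grid, with the regime boundaries."""

    grid: list[Fraction]
    results: dict[Fraction, EGVResult]
    families: dict[frozenset[str], EGVFamily]
    mu_crit: Fraction | None  # boundary where the point-EGV count changes
    mu_max: Fraction | None  # feasibility boundary (None if none in range)
    merge_map: dict[frozenset[str], frozenset[str]]  # L-only family -> H family

    def regime(self, fam: EGVFamily) -> str:
        """'all' if the family exists on both sides of mu_crit, else 'L'/'H'."""
        if self.mu_crit is None:
            return "all"
        lo, hi = fam.mu_interval
        below, above = lo < self.mu_crit, hi > self.mu_crit
        if below and above:
            return "all"
        return "L" if below else "H"


def sweep_mu(
    model: GrowthModel,
    cs_builder: Callable[[Fraction], ConstraintSet],
    mu_min=Fraction(1, 20),
    mu_hi=Fraction(2),
    step=Fraction(1, 20),
    tol=Fraction(1, 10000),
) -> MuSweepResult:
    """Enumerate EGVs across a growth-rate grid and locate the boundaries.

    mu_max (feasibility boundary) and mu_crit (point-EGV count change) are
    refined by bisection to `tol`. Families are identified by their inactive
    signatures; at mu_crit, vanishing regime-L families are matched to the
    regime-H EGV they merge into by flux proximity just across the boundary.
    """
    mu_min, mu_hi, step, tol = map(frac, (mu_min, mu_hi, step, tol))

    def feasible(mu: Fraction) -> bool:
        return polyhedron_feasible(model, cs_builder(mu), mu)

    def egvs_at(mu: Fraction) -> EGVResult:
        return enumerate_egvs(model, cs_builder(mu), mu)

    # feasibility scan and mu_max bisection
    grid = []
    mu = mu_min
    first_infeasible = None
    while mu <= mu_hi:
        if feasible(mu):
            grid.append(mu)
        else:
            first_infeasible = mu
            break
        mu += step
    if not grid:
        raise ValueError("no feasible growth rate in the scanned range")
    mu_max = None
    if first_infeasible is not None:
        lo, hi = grid[-1], first_infeasible
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if feasible(mid):
                lo = mid
            else:
                hi = mid
        mu_max = (lo + hi) / 2

    results = {mu: egvs_at(mu) for mu in grid}
    counts = {mu: len(results[mu].records) for mu in grid}

    # refine every count transition on the grid
    crits: list[Fraction] = []
    for a, b in zip(grid, grid[1:]):
        if counts[a] != counts[b]:
            lo, hi = a, b
            n_lo = counts[a]
            while hi - lo > tol:
                mid = (lo + hi) / 2
                if len(egvs_at(mid).records) == n_lo:
                    lo = mid
                else:
                    hi = mid
            crits.append((lo + hi) / 2)
    mu_crit = crits[0] if crits else None

    families: dict[frozenset[str], EGVFamily] = {}
    for mu in grid:
        for rec in results[mu].records:
            fam = families.setdefault(
                rec.inactive_signature, EGVFamily(rec.inactive_signature)
            )
            fam.samples[mu] = rec

    merge_map: dict[frozenset[str], frozenset[str]] = {}
    if mu_crit is not None:
        below = egvs_at(mu_crit - tol)
        above = egvs_at(mu_crit + tol)
        if below.feasible and above.feasible:
            above_sigs = {r.inactive_signature: r for r in above.records}
            for rec in below.records:
                if rec.inactive_signature in above_sigs:
                    continue
                # nearest regime-H EGV in flux space
                best = min(
                    above.records,
                    key=lambda h: sum(
                        (float(a - b)) ** 2 for a, b in zip(h.flux, rec.flux)
                    ),
                )
                merge_map[rec.inactive_signature] = best.inactive_signature
            for sig, rec in above_sigs.items():
                fam = families.setdefault(sig, EGVFamily(sig))
                fam.samples.setdefault(above.mu, rec)

    sweep = MuSweepResult(grid, results, families, mu_crit, mu_max, merge_map)
    classify_egvs(model, sweep)
    return sweep


def classify_egvs(model: GrowthModel, sweep: MuSweepResult) -> None:
    """Assign uptake/storage and ribosome-content classes to each family.

    Uptake: class 1 (low ammonium, gamma_IN below half the balanced value
    omega_N/(omega_G+omega_N)), class 2 (high ammonium, gamma_IN > 1/2),
    class 3 (near-balanced), evaluated at the family's lowest sampled growth
    rate; suffix 'a' for families existing at all growth rates, 'b'
    otherwise. Ribosome content: class III if omega_R x_R is (almost)
    constant over the validity interval (range <= 0.1), class II if (almost)
    proportional to growth rate (best origin-fit residual <= 0.05), class I
    (nonlinear) otherwise.
    """
    balanced = model.mass("N") / (model.mass("G") + model.mass("N"))
    has_rib = "R" in model.species
    for fam in sweep.families.values():
        mus = fam.mus
        rec0 = fam.samples[mus[0]]
        g = rec0.gamma(model, "r_IN") if "r_IN" in model.reactions else None
        if g is None:
            fam.uptake_class = None
        else:
            if g < balanced / 2:
                num = "1"
            elif g > Fraction(1, 2):
                num = "2"
            else:
                num = "3"
            suffix = "a" if sweep.regime(fam) == "all" else "b"
            fam.uptake_class = num + suffix
        if not has_rib:
            continue
        w = [float(fam.samples[mu].mass_fraction(model, "R")) for mu in mus]
        f_mus = [float(mu) for mu in mus]
        if max(w) - min(w) <= 0.1:
            fam.ribosome_class = "III"
        else:
            c = sum(a * b for a, b in zip(w, f_mus)) / sum(m * m for m in f_mus)
            resid = max(abs(a - c * b) for a, b in zip(w, f_mus))
            fam.ribosome_class = "II" if resid <= 0.05 else "I"


def polyhedron_feasible(model: GrowthModel, cs: ConstraintSet, mu) -> bool:
    """Exact LP feasibility of P_g(mu) (cheap; used by the mu_max bisection)."""
    mu = frac(mu)
    poly = growth_polyhedron(model, cs, mu)
    eq_rows, ineq_rows = [], []
    for row, b, is_eq in zip(poly.ineq_matrix, poly.rhs, poly.eq_mask):
        (eq_rows if is_eq else ineq_rows).append((row, b))
    x = feasible_point(
        n=poly.n, eq_rows=eq_rows, ineq_rows=ineq_rows,
        nonneg=[r in model.irreversible for r in model.reactions],
    )
    return x is not None
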