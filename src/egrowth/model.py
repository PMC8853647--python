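"""Growth models: species, exact stoichiometry, molar masses, catalysts.

A growth model describes a self-fabricating cell: the stoichiometric matrix N
couples fluxes v (mol g^-1 h^-1) to the production of *all* molecular species
— metabolites and the macromolecules (enzymes, ribosome) that catalyse the
reactions. At balanced growth, Nv = mu x with growth rate mu = omega^T N v
(omega = molar masses, g mol^-1) and the dry-mass normalisation omega^T x = 1.

Internal reactions conserve mass (omega^T N_int = 0); a valid growth model
has no semipositive conservation law (otherwise the conserved pool could not
be duplicated and sustained growth would be impossible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from ._rational import Mat, Vec, dot, frac, mat_vec, solve, vec
from ._simplex import feasible_point


class GrowthRateZeroError(ValueError):
    """The flux is a flux mode (mu = 0); no associated concentrations exist."""


@dataclass(frozen=True)
class GrowthModel:
    """An exact-arithmetic growth model.

    stoich is species x reactions; irreversible and exchange are reaction-id
    sets; catalysts maps a reaction id to the species id catalysing it.
    """

    species: tuple[str, ...]
    molar_masses: Vec  # g/mol, aligned with species
    reactions: tuple[str, ...]
    stoich: Mat  # species x reactions
    irreversible: frozenset[str]
    catalysts: Mapping[str, str]
    exchange: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        assert len(self.molar_masses) == len(self.species)
        assert len(self.stoich) == len(self.species)
        assert all(len(r) == len(self.reactions) for r in self.stoich)
        if self.exchange is None:
            # a reaction exchanges mass with the environment iff its column
            # is not mass-balanced
            exc = frozenset(
                r
                for j, r in enumerate(self.reactions)
                if dot(self.molar_masses, self.column(j)) != 0
            )
            object.__setattr__(self, "exchange", exc)

    # -- indexing helpers --------------------------------------------------
    def species_index(self, s: str) -> int:
        return self.species.index(s)

    def reaction_index(self, r: str) -> int:
        return self.reactions.index(r)

    def column(self, j: int) -> Vec:
        return tuple(row[j] for row in self.stoich)

    def mass(self, s: str) -> Fraction:
        return self.molar_masses[self.species_index(s)]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


@dataclass(frozen=True)
class GrowthState:
    """A feasible balanced-growth state: flux, growth rate, composition.

    Mass fractions need the molar masses; use mass_fractions(model, x)."""

    flux: Vec
    growth_rate: Fraction
    concentrations: Vec  # mol/g, = Nv/mu


@dataclass
class ValidationReport:
    passed: bool
    failures: list[str]


def validate_model(model: GrowthModel) -> ValidationReport:
    """Check the structural assumptions of a growth model.

    (a) internal reactions conserve mass exactly; (b) there is no semipositive
    conservation law (y >= 0, y != 0 with N^T y = 0), decided by an exact LP;
    (c) every catalyst is a declared species.
    """
    failures: list[str] = []
    for j, r in enumerate(model.reactions):
        if r in model.exchange:
            continue
        resid = dot(model.molar_masses, model.column(j))
        if resid != 0:
            failures.append(
                f"internal reaction {r} violates mass conservation "
                f"(omega^T N column = {resid})"
            )
    # semipositive left-kernel vector: N^T y = 0, sum y = 1, y >= 0
    nt_rows = [
        (model.column(j), Fraction(0)) for j in range(model.n_reactions)
    ]
    norm = ((tuple(Fraction(1) for _ in model.species)), Fraction(1))
    y = feasible_point(n=model.n_species, eq_rows=list(nt_rows) + [norm])
    if y is not None:
        sup = [s for s, v in zip(model.species, y) if v != 0]
        failures.append(f"semipositive conservation law over species {sup}")
    for r, cat in model.catalysts.items():
        if r not in model.reactions:
            failures.append(f"catalyst map names unknown reaction {r}")
        if cat not in model.species:
            failures.append(f"catalyst {cat} of reaction {r} is not a species")
    if any(m <= 0 for m in model.molar_masses):
        failures.append("molar masses must be positive")
    return ValidationReport(passed=not failures, failures=failures)


def derive_masses(
    species: Sequence[str],
    reactions: Sequence[str],
    stoich: Mat,
    known: Mapping[str, object],
    exchange: Sequence[str],
) -> Vec:
    """Complete molar masses from mass balance of the internal reactions.

    Unknown masses are solved from omega^T N_int = 0 given the masses of the
    exchanged metabolites. Raises ValueError if the internal network leaves a
    mass undetermined, or determines a nonpositive one.
    """
    n = len(species)
    known_f = {s: frac(m) for s, m in known.items()}
    unknown = [s for s in species if s not in known_f]
    idx = {s: i for i, s in enumerate(unknown)}
    rows, rhs = [], []
    for j, r in enumerate(reactions):
        if r in exchange:
            continue
        col = tuple(row[j] for row in stoich)
        row = [Fraction(0)] * len(unknown)
        b = Fraction(0)
        for i, s in enumerate(species):
            if col[i] == 0:
                continue
            if s in known_f:
                b -= known_f[s] * col[i]
            else:
                row[idx[s]] = col[i]
        rows.append(row)
        rhs.append(b)
    from ._rational import rank as _rank

    if unknown:
        if _rank(rows) < len(unknown):
            raise ValueError("mass balance leaves molar masses undetermined")
        sol = solve(rows, rhs)
        if sol is None:
            raise ValueError("mass balance of internal reactions is inconsistent")
        for s, m in zip(unknown, sol):
            if m <= 0:
                raise ValueError(f"derived molar mass of {s} is not positive ({m})")
        known_f.update(dict(zip(unknown, sol)))
    return tuple(known_f[s] for s in species)


def growth_rate(model: GrowthModel, v: Sequence) -> Fraction:
    """mu(v) = omega^T N v, cross-checked against the exchange-only form."""
    v = vec(v)
    nv = mat_vec(model.stoich, v)
    mu = dot(model.molar_masses, nv)
    mu_exc = sum(
        (
            dot(model.molar_masses, model.column(j)) * v[j]
            for j, r in enumerate(model.reactions)
            if r in model.exchange
        ),
        Fraction(0),
    )
    assert mu == mu_exc, "exchange-only growth rate disagrees (model invalid?)"
    return mu


def associated_concentrations(model: GrowthModel, v: Sequence) -> Vec:
    """x(v) = Nv / mu(v); scale-invariant in v. Requires mu(v) > 0."""
    v = vec(v)
    mu = growth_rate(model, v)
    if mu == 0:
        raise GrowthRateZeroError(
            "flux mode (Nv = 0): no associated concentrations"
        )
    nv = mat_vec(model.stoich, v)
    return tuple(x / mu for x in nv)


def mass_fractions(model: GrowthModel, x: Sequence) -> Vec:
    x = vec(x)
    return tuple(m * c for m, c in zip(model.molar_masses, x))


def state_of(model: GrowthModel, v: Sequence) -> GrowthState:
    v = vec(v)
    mu = growth_rate(model, v)
    return GrowthState(v, mu, associated_concentrations(model, v))
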