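"""Built-in growth models.

* the 11-species / 11-reaction self-fabricating cell (glucose + ammonium
  uptake, amino-acid and lipid synthesis, expression of all five enzymes and
  the ribosome itself);
* a minimal 4-species model with two alternative uptake pathways;
* a traditional-model constructor that collapses a comprehensive model to its
  metabolic part plus a fixed biomass column.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping, Sequence

from ._rational import Vec, frac, vec
from .model import GrowthModel, GrowthState, derive_masses

# stoichiometric coefficients of the self-fabricating cell
N_L = 7  # glucose units per lipid
N_I = 646  # amino acids per importer
N_E = 325  # amino acids per enzyme
N_R = 22608  # amino acids per ribosome (x3 for RNA content)
OMEGA_G = Fraction(180)  # g/mol glucose
OMEGA_N = Fraction(18)  # g/mol ammonium


def _model_from_reactions(
    species: Sequence[str],
    reactions: dict[str, dict[str, object]],
    known_masses: dict[str, object],
    catalysts: dict[str, str],
    irreversible: Sequence[str] | None = None,
) -> GrowthModel:
    rxn_ids = tuple(reactions)
    stoich = tuple(
        tuple(frac(reactions[r].get(s, 0)) for r in rxn_ids) for s in species
    )
    # exchange reactions are those that cannot be mass balanced with any
    # positive masses; here we mark them explicitly by convention: a reaction
    # is exchange iff its column is not balanced by the derived masses
    exchange = tuple(
        r for r in rxn_ids if reactions[r].get("__exchange__", False)
    )
    clean = {
        r: {s: c for s, c in d.items() if s != "__exchange__"}
        for r, d in reactions.items()
    }
    stoich = tuple(
        tuple(frac(clean[r].get(s, 0)) for r in rxn_ids) for s in species
    )
    masses = derive_masses(species, rxn_ids, stoich, known_masses, exchange)
    return GrowthModel(
        species=tuple(species),
        molar_masses=masses,
        reactions=rxn_ids,
        stoich=stoich,
        irreversible=frozenset(rxn_ids if irreversible is None else irreversible),
        catalysts=dict(catalysts),
    )


def build_self_fabricating_model() -> GrowthModel:
    """The 11x11 self-fabricating cell model.

    Importers IG/IN take up glucose (G) and ammonium (N); enzymes EAA, ELD,
    EL synthesise amino acids (AA), lipid droplets (LD) and membrane lipids
    (L); the ribosome R polymerises amino acids into the importers, the
    enzymes and itself. All reactions are irreversible and catalytic. Only
    the masses of the exchanged nutrients are given; all other molar masses
    follow from mass balance (e.g. omega_AA = 180 + 18 = 198 g/mol).
    """
    species = ("G", "N", "AA", "LD", "L", "IG", "IN", "EAA", "ELD", "EL", "R")
    reactions = {
        "r_IG": {"G": 1, "__exchange__": True},
        "r_IN": {"N": 1, "__exchange__": True},
        "r_EAA": {"G": -1, "N": -1, "AA": 1},
        "r_ELD": {"G": -N_L, "LD": 1},
        "r_EL": {"LD": -1, "L": 1},
        "s_IG": {"AA": -N_I, "IG": 1},
        "s_IN": {"AA": -N_I, "IN": 1},
        "s_EAA": {"AA": -N_E, "EAA": 1},
        "s_ELD": {"AA": -N_E, "ELD": 1},
        "s_EL": {"AA": -N_E, "EL": 1},
        "s_R": {"AA": -N_R, "R": 1},
    }
    catalysts = {
        "r_IG": "IG",
        "r_IN": "IN",
        "r_EAA": "EAA",
        "r_ELD": "ELD",
        "r_EL": "EL",
        "s_IG": "R",
        "s_IN": "R",
        "s_EAA": "R",
        "s_ELD": "R",
        "s_EL": "R",
        "s_R": "R",
    }
    return _model_from_reactions(
        species, reactions, {"G": OMEGA_G, "N": OMEGA_N}, catalysts
    )


def build_minimal_model() -> GrowthModel:
    """A minimal growth model with two alternative uptake pathways.

    Species {AA, E1, E2, R}; the enzymes E1 and E2 each catalyse an uptake
    route producing amino acids (substrates implicit), and the ribosome R
    synthesises E1, E2 and itself from amino acids. Unit stoichiometric
    coefficients; masses follow from mass balance with omega_AA = 1 (the
    claims tested on this model — elementary-mode identities and minimal
    autocatalytic sets — are parameter-free).
    """
    species = ("AA", "E1", "E2", "R")
    reactions = {
        "v1": {"AA": 1, "__exchange__": True},
        "v2": {"AA": 1, "__exchange__": True},
        "w1": {"AA": -1, "E1": 1},
        "w2": {"AA": -1, "E2": 1},
        "w_R": {"AA": -1, "R": 1},
    }
    catalysts = {"v1": "E1", "v2": "E2", "w1": "R", "w2": "R", "w_R": "R"}
    return _model_from_reactions(species, reactions, {"AA": 1}, catalysts)


METABOLITES = ("G", "N", "AA", "LD", "L")


def total_amino_acid_content(model: GrowthModel, x: Sequence) -> Fraction:
    """x_AA^tot = n_I(x_IG + x_IN) + n_E(x_EAA + x_ELD + x_EL) + n_R x_R + x_AA.

    The amino-acid content of all macromolecules plus the free pool; this is
    the quantity a traditional model tracks instead of individual proteins.
    """
    x = vec(x)
    gi = model.species_index
    return (
        N_I * (x[gi("IG")] + x[gi("IN")])
        + N_E * (x[gi("EAA")] + x[gi("ELD")] + x[gi("EL")])
        + N_R * x[gi("R")]
        + x[gi("AA")]
    )


def traditional_efms(traditional: GrowthModel) -> list[Vec]:
    """EFMs of the traditional flux cone {v : Nv = 0, v >= 0}."""
    from .polyhedra import SCone, enumerate_scone_evs

    n = traditional.n_reactions
    nonneg = frozenset(
        traditional.reaction_index(r) for r in traditional.irreversible
    )
    sc = SCone(traditional.stoich, nonneg, n)
    return [ev.vector for ev in enumerate_scone_evs(sc)]


def traditional_efvs(
    traditional: GrowthModel, flux_bounds: Mapping[str, Fraction]
) -> tuple[list[Vec], list[Vec]]:
    """Nonzero EFVs of the flux polyhedron {Nv = 0, v >= 0, v_r <= bound_r}.

    Returns (points, rays). The zero flux is always a trivial member of the
    polyhedron and is not reported."""
    from .polyhedra import Polyhedron, enumerate_polyhedron_evs

    n = traditional.n_reactions
    rows, rhs, labels, eq_mask = [], [], [], []
    for i, s in enumerate(traditional.species):
        rows.append(vec(traditional.stoich[i]))
        rhs.append(Fraction(0))
        labels.append(f"mb {s}")
        eq_mask.append(True)
    for j, r in enumerate(traditional.reactions):
        unit = tuple(Fraction(int(k == j)) for k in range(n))
        if r in traditional.irreversible:
            rows.append(unit)
            rhs.append(Fraction(0))
            labels.append(f"irr {r}")
            eq_mask.append(False)
        if r in flux_bounds:
            rows.append(tuple(-x for x in unit))
            rhs.append(-frac(flux_bounds[r]))
            labels.append(f"cap {r}")
            eq_mask.append(False)
    poly = Polyhedron(tuple(rows), tuple(rhs), tuple(labels), tuple(eq_mask))
    points, rays = enumerate_polyhedron_evs(poly)
    nonzero = [p for p in points if any(x != 0 for x in p)]
    return nonzero, [ev.vector for ev in rays]


def max_growth_flux_bounds(
    comprehensive: GrowthModel, biomass_state: GrowthState, kcat
) -> dict[str, Fraction]:
    """Capacity bounds v_r <= k_cat x_cat(r) at the reference composition,
    for the catalysed metabolic reactions of the traditional model."""
    kcat = frac(kcat)
    x = biomass_state.concentrations
    out = {}
    for r in ("r_IG", "r_IN", "r_EAA", "r_ELD", "r_EL"):
        cat = comprehensive.catalysts[r]
        out[r] = kcat * x[comprehensive.species_index(cat)]
    return out


def build_traditional_model(
    comprehensive: GrowthModel, biomass_state: GrowthState
) -> GrowthModel:
    """Collapse a comprehensive model to a traditional one (fixed biomass).

    Keeps the metabolic submatrix (metabolite rows x import/enzymatic
    reactions) and appends a biomass column that consumes G, N, AA, LD and L
    in proportion to the reference state's composition, with the
    macromolecules replaced by their total amino-acid content. The column is
    scaled by the total biomass-precursor concentration x_bar so its entries
    are dimensionless and carry unit mass.
    """
    if biomass_state.growth_rate <= 0:
        raise ValueError("biomass reference state must have positive growth rate")
    x = biomass_state.concentrations
    gi = comprehensive.species_index
    eff = {
        "G": x[gi("G")],
        "N": x[gi("N")],
        "AA": total_amino_acid_content(comprehensive, x),
        "LD": x[gi("LD")],
        "L": x[gi("L")],
    }
    x_bar = sum(eff.values(), Fraction(0))
    metabolic_rxns = ("r_IG", "r_IN", "r_EAA", "r_ELD", "r_EL")
    reactions: dict[str, dict[str, object]] = {}
    for r in metabolic_rxns:
        j = comprehensive.reaction_index(r)
        col = comprehensive.column(j)
        d: dict[str, object] = {
            s: col[gi(s)] for s in METABOLITES if col[gi(s)] != 0
        }
        if r in comprehensive.exchange:
            d["__exchange__"] = True
        reactions[r] = d
    reactions["v_BM"] = {
        **{s: -c / x_bar for s, c in eff.items() if c != 0},
        "__exchange__": True,
    }
    masses = {s: comprehensive.mass(s) for s in METABOLITES}
    return _model_from_reactions(METABOLITES, reactions, masses, catalysts={})
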