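"""Network autocatalysis and kinetic consistency for coarse-grained models.

In a coarse-grained model each catalytic reaction names its catalyst
explicitly. A growth mode v is *basically catalytic* (BC) if some active
reaction is catalytic, *catalytically closed* (CC) if every active catalytic
reaction's catalyst is produced ((Nv)_s > 0), and *autocatalytic* (AC) if
both. A reaction subset is AC if it is the support of some AC growth mode,
and minimally autocatalytic (MAC) if inclusion-minimal among AC sets — the
minimal self-fabricating pathways of the network.

Kinetic consistency is stricter: every species touched by an active reaction
must be produced, so that the mode could be realised by mass-action-like
kinetics with all required concentrations nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from ._rational import mat_vec, vec
from ._simplex import feasible_point
from .egm import GrowthModeRecord, enumerate_egms, growth_cone
from .model import GrowthModel
from .polyhedra import MembershipError


@dataclass(frozen=True)
class AutocatalysisReport:
    basically_catalytic: bool
    catalytically_closed: bool
    kinetically_consistent: bool
    violating_reactions: tuple[str, ...]  # active catalytic, catalyst not produced
    unsupplied_species: tuple[str, ...]  # involved in active reactions, not produced

    @property
    def autocatalytic(self) -> bool:
        return self.basically_catalytic and self.catalytically_closed


def classify_gm(model: GrowthModel, v: Sequence) -> AutocatalysisReport:
    """BC/CC/AC and kinetic-consistency classification of a growth mode."""
    v = vec(v)
    if not growth_cone(model).contains(v):
        raise MembershipError(["growth cone membership"])
    nv = mat_vec(model.stoich, v)
    produced = {s for s, c in zip(model.species, nv) if c > 0}
    active = [r for r, x in zip(model.reactions, v) if x != 0]
    active_cat = [r for r in active if r in model.catalysts]
    violating = tuple(
        r for r in active_cat if model.catalysts[r] not in produced
    )
    involved = {
        s
        for j, r in enumerate(model.reactions)
        if v[j] != 0
        for i, s in enumerate(model.species)
        if model.stoich[i][j] != 0
    }
    unsupplied = tuple(sorted(involved - produced))
    return AutocatalysisReport(
        basically_catalytic=bool(active_cat),
        catalytically_closed=not violating,
        kinetically_consistent=not unsupplied,
        violating_reactions=violating,
        unsupplied_species=unsupplied,
    )


def ac_support_feasible(model: GrowthModel, support: Sequence[str]) -> bool:
    """Is there an AC growth mode with exactly this support?

    Decided by an exact LP on the cone: v_r = 0 off the support, v_r >= 1 on
    it (strict positivity, scaled), Nv >= 0, and (Nv)_cat >= 1 for the
    catalyst of every catalytic reaction in the support.
    """
    sup = set(support)
    if not sup & set(model.catalysts):
        return False  # not even basically catalytic
    n = model.n_reactions
    ineq = []
    eq = []
    for i in range(model.n_species):
        ineq.append((vec(model.stoich[i]), Fraction(0)))
    cats_needed = {
        model.catalysts[r] for r in sup if r in model.catalysts
    }
    for s in cats_needed:
        ineq.append((vec(model.stoich[model.species_index(s)]), Fraction(1)))
    for j, r in enumerate(model.reactions):
        unit = tuple(Fraction(int(k == j)) for k in range(n))
        if r in sup:
            ineq.append((unit, Fraction(1)))
        else:
            eq.append((unit, Fraction(0)))
    nonneg = [r in model.irreversible for r in model.reactions]
    return (
        feasible_point(n=n, eq_rows=eq, ineq_rows=ineq, nonneg=nonneg)
        is not None
    )


def enumerate_mac_sets(
    model: GrowthModel, egms: Sequence[GrowthModeRecord] | None = None
) -> list[frozenset[str]]:
    """All minimally autocatalytic reaction subsets.

    Every growth mode is a conformal sum of EGMs, so its support is a union
    of EGM supports; the search therefore runs over the (deduplicated) union
    lattice of EGM supports in order of increasing size, pruning supersets of
    accepted MAC sets, and decides AC-support feasibility by exact LP.
    """
    egms = enumerate_egms(model) if egms is None else egms
    supports = sorted(
        {frozenset(model.reactions[j] for j in rec.support) for rec in egms}
    )
    # close under unions (bounded: distinct unions of <= 2^k supports)
    closure: set[frozenset[str]] = set(supports)
    frontier = set(supports)
    while frontier:
        new = set()
        for u in frontier:
            for s in supports:
                w = u | s
                if w not in closure:
                    new.add(w)
        closure |= new
        frontier = new
    macs: list[frozenset[str]] = []
    for cand in sorted(closure, key=lambda s: (len(s), sorted(s))):
        if any(mac <= cand for mac in macs):
            continue
        if ac_support_feasible(model, cand):
            macs.append(cand)
    return macs


def project_supports(
    sets: Sequence[frozenset[str]], reactions: Sequence[str]
) -> list[frozenset[str]]:
    """Project reaction subsets onto a sublist of reactions (deduplicated)."""
    keep = set(reactions)
    return sorted({s & keep for s in sets}, key=sorted)
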