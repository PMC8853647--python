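"""Growth cones and elementary growth modes (EGMs).

The growth cone C_g = {v : Nv >= 0, v_I >= 0} collects all fluxes compatible
with balanced growth: every species is produced (or balanced), irreversible
reactions run forward. Its elementary vectors — the conformally
non-decomposable growth modes — are the EGMs. Unlike classical EFMs they need
not be support-minimal, but every growth mode is a sum of EGMs without
cancellations, and EGMs with positive growth rate can be rescaled to a common
growth rate so that the decomposition becomes convex and the associated
biomass compositions mix linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from ._rational import Vec, dot, frac, mat_vec, vec
from .model import GrowthModel, growth_rate
from .polyhedra import (
    ConformalDecomposition,
    ElementaryVector,
    MembershipError,
    PolyCone,
    conformal_decompose,
    enumerate_cone_evs,
)


@dataclass(frozen=True)
class GrowthModeRecord:
    """An (elementary) growth mode with its associated quantities."""

    flux: Vec
    growth_rate_assoc: Fraction
    concentrations_assoc: Vec | None  # None for flux modes (mu = 0)
    produced_species: frozenset[str]  # supp(Nv)

    @property
    def is_flux_mode(self) -> bool:
        return self.growth_rate_assoc == 0

    @property
    def support(self) -> frozenset[int]:
        return frozenset(i for i, x in enumerate(self.flux) if x != 0)


def growth_cone(model: GrowthModel) -> PolyCone:
    """Inequality description of C_g: mass-balance rows and irreversibility."""
    rows = [vec(r) for r in model.stoich]
    labels = [f"mb {s}" for s in model.species]
    n = model.n_reactions
    for j, r in enumerate(model.reactions):
        if r in model.irreversible:
            rows.append(tuple(Fraction(int(k == j)) for k in range(n)))
            labels.append(f"irr {r}")
    return PolyCone(tuple(rows), n, row_labels=tuple(labels))


def _record(model: GrowthModel, v: Vec) -> GrowthModeRecord:
    nv = mat_vec(model.stoich, v)
    mu = dot(model.molar_masses, nv)
    x = tuple(c / mu for c in nv) if mu > 0 else None
    produced = frozenset(s for s, c in zip(model.species, nv) if c != 0)
    return GrowthModeRecord(v, mu, x, produced)


def enumerate_egms(
    model: GrowthModel, normalize_mu: Fraction | float | None = None
) -> list[GrowthModeRecord]:
    """All EGMs of the model, one canonical representative per ray.

    With normalize_mu given, EGMs with positive associated growth rate are
    rescaled so that mu(e) = normalize_mu; EGMs with mu = 0 (EFMs of the
    comprehensive network) are left at canonical integer scaling. Output is
    sorted by produced species (model order), then lexicographically.
    """
    evs = enumerate_cone_evs(growth_cone(model))
    records = []
    for ev in evs:
        v = ev.vector
        rec = _record(model, v)
        if normalize_mu is not None and rec.growth_rate_assoc > 0:
            scale = frac(normalize_mu) / rec.growth_rate_assoc
            rec = _record(model, tuple(scale * x for x in v))
        records.append(rec)
    order = {s: i for i, s in enumerate(model.species)}
    records.sort(
        key=lambda r: (
            sorted(order[s] for s in r.produced_species),
            r.flux,
        )
    )
    return records


def project_scaled(
    model: GrowthModel,
    records: Sequence[GrowthModeRecord],
    reactions: Sequence[str],
) -> list[Vec]:
    """Distinct growth modes after scaling to mu = 1 and projecting onto the
    given reactions (v_hat = v / mu(v)). Alternative routes that differ only
    outside the projection collapse; flux modes (mu = 0) are skipped."""
    idx = [model.reaction_index(r) for r in reactions]
    seen: set[Vec] = set()
    for rec in records:
        if rec.growth_rate_assoc == 0:
            continue
        mu = rec.growth_rate_assoc
        seen.add(tuple(rec.flux[j] / mu for j in idx))
    return sorted(seen)


def decompose_growth_mode(
    model: GrowthModel, v: Sequence, egms: list[GrowthModeRecord] | None = None
) -> ConformalDecomposition:
    """Conformal decomposition of a growth mode over the EGMs.

    Zero-growth EGMs enter as ray terms with the coefficient absorbed into the
    vector; positive-growth EGMs are rescaled to mu(v) and carry convex
    coefficients lambda_e (summing to 1), so that the associated
    concentrations mix as x(v) = sum lambda_e x(e).
    """
    v = vec(v)
    cone = growth_cone(model)
    if not cone.contains(v):
        raise MembershipError(["growth cone membership"])
    egms = enumerate_egms(model) if egms is None else egms
    raw = conformal_decompose(v, cone, [ElementaryVector(r.flux) for r in egms])
    mu_v = growth_rate(model, v)
    ray_terms: list[tuple[Vec, Fraction]] = []
    point_terms: list[tuple[Vec, Fraction]] = []
    for e, c in raw.ray_terms:
        w = tuple(c * x for x in e)
        mu_w = growth_rate(model, w)
        if mu_w == 0:
            ray_terms.append((w, Fraction(1)))
        else:
            lam = mu_w / mu_v
            point_terms.append((tuple(x / lam for x in w), lam))
    return ConformalDecomposition(
        ray_terms=ray_terms, point_terms=point_terms, convex=bool(point_terms)
    )
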