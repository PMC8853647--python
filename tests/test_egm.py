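"""Growth-cone construction and elementary growth modes."""

import random
from fractions import Fraction as F

import pytest

from egrowth import (
    associated_concentrations,
    decompose_growth_mode,
    enumerate_egms,
    growth_cone,
    growth_rate,
    is_conformally_nondecomposable,
    project_scaled,
)
from egrowth._rational import mat_vec
from egrowth.polyhedra import MembershipError


class TestGrowthCone:
    def test_row_structure(self, model):
        cone = growth_cone(model)
        assert len(cone.ineq_matrix) == 22  # 11 mass balance + 11 irreversibility
        assert cone.row_labels[0] == "mb G"
        assert cone.row_labels[-1] == "irr s_R"

    def test_fixture_cone_is_pointed(self, model):
        from egrowth.polyhedra import _lineality_dim

        assert _lineality_dim(growth_cone(model)) == 0


class TestEgmEnumeration:
    def test_eleven_egms_one_per_species(self, model, egms):
        assert len(egms) == 11
        produced = [rec.produced_species for rec in egms]
        assert all(len(p) == 1 for p in produced)
        # bijection onto the species set (square-matrix special case)
        assert {next(iter(p)) for p in produced} == set(model.species)

    def test_egm_produces_unit_vector(self, model, egm_by_species):
        # N e^i = (mu / omega_i) u^i with the mu = 1 normalisation
        for sp, rec in egm_by_species.items():
            nv = mat_vec(model.stoich, rec.flux)
            i = model.species_index(sp)
            assert nv[i] == F(1) / model.mass(sp)
            assert all(x == 0 for j, x in enumerate(nv) if j != i)

    def test_no_flux_modes(self, egms):
        assert all(not rec.is_flux_mode for rec in egms)

    def test_support_minimality_pattern(self, model, egm_by_species):
        # only the pure-uptake modes are support-minimal
        supports = {sp: rec.support for sp, rec in egm_by_species.items()}
        minimal = {
            sp
            for sp, sup in supports.items()
            if not any(o < sup for o in supports.values())
        }
        assert minimal == {"G", "N"}

    def test_egms_are_cnd(self, model, egms):
        cone = growth_cone(model)
        for rec in egms:
            assert is_conformally_nondecomposable(rec.flux, cone)

    def test_minimal_model_projection(self, minimal_model):
        # two uptake routes duplicate each producer in full flux space; after
        # scaling and projection to the synthesis fluxes the four canonical
        # modes remain, each producing exactly one species
        egms = enumerate_egms(minimal_model)
        assert len(egms) == 8
        assert all(len(r.produced_species) == 1 for r in egms)
        proj = project_scaled(minimal_model, egms, ("w1", "w2", "w_R"))
        assert len(proj) == 4


def _blend(egm_by_species, weights):
    return tuple(
        sum((w * egm_by_species[sp].flux[i] for sp, w in weights.items()), F(0))
        for i in range(11)
    )


class TestDecomposition:
    def test_mode_without_lipid_synthesis(self, model, egms, egm_by_species):
        # uptake + amino-acid synthesis + importer expression only: the
        # conformal decomposition can use exactly the five EGMs whose
        # supports avoid the lipid and enzyme branches
        v = _blend(egm_by_species, {"IG": F(1, 2), "IN": F(1, 2)})
        dec = decompose_growth_mode(model, v, egms)
        used = set()
        for e, _ in dec.point_terms:
            (sp,) = [
                s for s, r in egm_by_species.items() if _same_ray(e, r.flux)
            ]
            used.add(sp)
        assert used <= {"G", "N", "AA", "IG", "IN"}
        assert {"IG", "IN"} <= used
        assert sum(c for _, c in dec.point_terms) == 1

    def test_single_egm_is_its_own_decomposition(self, model, egms):
        rec = egms[0]
        dec = decompose_growth_mode(model, rec.flux, egms)
        assert len(dec.point_terms) == 1 and not dec.ray_terms

    def test_concentrations_mix_linearly(self, model, egms):
        rng = random.Random(3)
        for _ in range(10):
            weights = [F(rng.randint(0, 4)) for _ in egms]
            if sum(weights) == 0:
                continue
            weights = [w / sum(weights) for w in weights]
            v = tuple(
                sum((w * r.flux[i] for w, r in zip(weights, egms)), F(0))
                for i in range(11)
            )
            dec = decompose_growth_mode(model, v, egms)
            mu = growth_rate(model, v)
            x = associated_concentrations(model, v)
            mixed = [F(0)] * 11
            for e, lam in dec.point_terms:
                xe = associated_concentrations(model, e)
                for i in range(11):
                    mixed[i] += lam * xe[i]
            assert tuple(mixed) == x
            assert dec.reconstruct(11) == v

    def test_nonmember_rejected(self, model, egms):
        with pytest.raises(MembershipError):
            decompose_growth_mode(model, [-1] + [0] * 10, egms)


def _same_ray(a, b):
    # proportional with positive factor
    for x, y in zip(a, b):
        if (x == 0) != (y == 0):
            return False
    pairs = [(x, y) for x, y in zip(a, b) if x != 0]
    return all(x * pairs[0][1] == y * pairs[0][0] for x, y in pairs)


def test_growth_rate_dichotomy_on_random_members(model, egms):
    # mu(v) = 0 iff Nv = 0 for growth-cone members; the fixture has no flux
    # modes, so every nonzero combination has positive growth rate
    rng = random.Random(4)
    for _ in range(100):
        w = [F(rng.randint(0, 3)) for _ in egms]
        v = tuple(
            sum((wi * r.flux[i] for wi, r in zip(w, egms)), F(0))
            for i in range(11)
        )
        nv = mat_vec(model.stoich, v)
        assert (growth_rate(model, v) == 0) == all(x == 0 for x in nv)
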