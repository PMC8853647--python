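"""Capacity/membrane constraints, growth polyhedra, and EGV enumeration at
fixed growth rate."""

import random
from fractions import Fraction as F

import pytest

from egrowth import (
    capacity_constraints,
    decompose_growth_mode,
    decompose_growth_vector,
    enumerate_egvs,
    polyhedron_feasible,
    signature_constraints,
)
METABOLITES = {"G", "LD", "N", "AA"}


class TestConstraintConstruction:
    def test_row_structure(self, model, params):
        cs = capacity_constraints(model, params, F(1, 2))
        ineq = [r for r in cs.rows if r.relation == ">="]
        eq = [r for r in cs.rows if r.relation == "=="]
        assert len(ineq) == 7 and len(eq) == 1
        assert eq[0].label == "memb area"

    def test_unit_conversions(self, params):
        # turnover and elongation rates arrive per second; canonical units
        # are per hour
        assert params.kcat == 79 * 3600
        assert params.kel == 8 * 3600

    def test_membrane_rhs_positive(self, model, params):
        cs = capacity_constraints(model, params, F(1, 2))
        memb = next(r for r in cs.rows if r.label == "memb area")
        assert memb.rhs > 0  # the zero state violates the equality

    def test_surface_to_volume_range(self, model, params):
        with pytest.raises(ValueError):
            capacity_constraints(model, params, F(4))

    def test_ribosome_row_counts_amino_acids(self, model, params):
        cs = capacity_constraints(model, params, F(1))
        row = next(r for r in cs.rows if r.label == "cap R")
        assert row.flux["s_R"] == -22608
        assert row.flux["s_IG"] == -646
        assert row.conc["R"] == params.kel


class TestGrowthPolyhedron:
    def test_feasibility_by_regime(self, model, params):
        for mu, expected in ((F(1, 2), True), (F(3, 2), False)):
            cs = capacity_constraints(model, params, mu)
            assert polyhedron_feasible(model, cs, mu) is expected

    def test_members_satisfy_dry_mass_equality(self, model, params, egvs_low):
        # omega^T N v = mu holds exactly on every enumerated point
        for rec in egvs_low.records:
            assert sum(rec.mass_fractions) == 1
            assert rec.growth_rate == F(1, 2)

    def test_infeasible_is_a_result_not_an_exception(self, model, params):
        mu = F(3, 2)
        res = enumerate_egvs(model, capacity_constraints(model, params, mu), mu)
        assert not res.feasible and res.records == [] and res.mu == mu


class TestEgvEnumeration:
    def test_regime_L_count(self, egvs_low):
        assert len(egvs_low.records) == 24

    def test_regime_H_count(self, egvs_high):
        assert len(egvs_high.records) == 10

    def test_full_support(self, egvs_low, egvs_high):
        for res in (egvs_low, egvs_high):
            assert all(all(x > 0 for x in r.flux) for r in res.records)

    def test_exactly_two_inactive_signature_constraints(
        self, model, params, egvs_low, egvs_high
    ):
        sig_rows = signature_constraints(
            model, capacity_constraints(model, params, F(1, 2))
        )
        assert len(sig_rows) == 11
        for res in (egvs_low, egvs_high):
            for rec in res.records:
                assert len(rec.inactive_signature) == 2

    def test_signatures_injective_and_stable_within_regime(self, model, params, egvs_low):
        sigs = {r.inactive_signature for r in egvs_low.records}
        assert len(sigs) == 24
        mu2 = F(3, 5)
        res2 = enumerate_egvs(model, capacity_constraints(model, params, mu2), mu2)
        assert {r.inactive_signature for r in res2.records} == sigs

    def test_at_most_one_stored_metabolite(self, model, egvs_low, egvs_high):
        # hence no EGV is kinetically consistent
        for res in (egvs_low, egvs_high):
            for rec in res.records:
                stored = [
                    s
                    for s in METABOLITES
                    if rec.concentrations_assoc[model.species_index(s)] != 0
                ]
                assert len(stored) <= 1

    def test_macromolecule_concentrations_positive(self, model, egvs_low):
        for rec in egvs_low.records:
            for s in ("L", "IG", "IN", "EAA", "ELD", "EL", "R"):
                assert rec.concentrations_assoc[model.species_index(s)] > 0

    def test_uptake_fractions_sum_to_one(self, model, egvs_low, egvs_high):
        for res in (egvs_low, egvs_high):
            for rec in res.records:
                assert rec.gamma(model, "r_IG") + rec.gamma(model, "r_IN") == 1

    def test_recession_cone_is_trivial(self, egvs_low):
        # the comprehensive network has no flux modes, so P_g(mu) is a polytope
        assert egvs_low.ray_fluxes == []


class TestGrowthVectorDecomposition:
    def test_egv_decomposes_as_itself(self, model, params, egvs_low):
        rec = egvs_low.records[0]
        dec = decompose_growth_vector(
            model, capacity_constraints(model, params, rec.growth_rate),
            rec.growth_rate, rec.flux, egvs=egvs_low,
        )
        assert len(dec.point_terms) == 1 and dec.point_terms[0][1] == 1

    def test_convex_combination_recovers_coefficients(self, model, params, egvs_low):
        rng = random.Random(5)
        recs = egvs_low.records
        for _ in range(5):
            a, b = rng.sample(range(len(recs)), 2)
            lam = F(rng.randint(1, 9), 10)
            v = tuple(
                lam * x + (1 - lam) * y
                for x, y in zip(recs[a].flux, recs[b].flux)
            )
            dec = decompose_growth_vector(
                model, capacity_constraints(model, params, F(1, 2)),
                F(1, 2), v, egvs=egvs_low,
            )
            assert dec.reconstruct(11) == v
            assert sum(c for _, c in dec.point_terms) == 1
            # concentrations mix linearly over the decomposition
            mixed = [F(0)] * 11
            for e, c in dec.point_terms:
                for i in range(11):
                    mixed[i] += c * e[i]
            assert tuple(mixed) == v

    def test_growth_vectors_are_growth_modes(self, model, egvs_low, egms):
        # every GV also decomposes conformally over the EGMs
        rec = egvs_low.records[0]
        dec = decompose_growth_mode(model, rec.flux, egms)
        assert dec.reconstruct(11) == rec.flux
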