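"""File formats, CSV/TSV writers, and the random model generator.

Rationals are serialised as exact "p/q" strings in JSON and TSV; CSV result
tables (for plotting or inspection) carry floats. The model JSON schema is

    {"species":   [{"id": str, "molar_mass": "p/q" | null}, ...],
     "reactions": [{"id": str, "stoich": {species: "p/q"},
                    "irreversible": bool, "catalyst": str | null,
                    "exchange": bool}, ...]}

Species with null molar mass are completed from mass balance of the internal
reactions on load.
"""

from __future__ import annotations

import json
import random
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._rational import Mat, frac
from .constraints import CapacityParams, ConstraintRow, EGVResult, MuSweepResult
from .model import GrowthModel, derive_masses, validate_model
from .polyhedra import ConformalDecomposition


def _rat(x: Fraction) -> str:
    return str(x)


# ---------------------------------------------------------------------------
# model JSON


def model_to_dict(model: GrowthModel) -> dict:
    return {
        "species": [
            {"id": s, "molar_mass": _rat(model.mass(s))} for s in model.species
        ],
        "reactions": [
            {
                "id": r,
                "stoich": {
                    s: _rat(model.stoich[i][j])
                    for i, s in enumerate(model.species)
                    if model.stoich[i][j] != 0
                },
                "irreversible": r in model.irreversible,
                "catalyst": model.catalysts.get(r),
                "exchange": r in model.exchange,
            }
            for j, r in enumerate(model.reactions)
        ],
    }


def model_from_dict(data: dict) -> GrowthModel:
    species = tuple(s["id"] for s in data["species"])
    reactions = tuple(r["id"] for r in data["reactions"])
    stoich = tuple(
        tuple(frac(r["stoich"].get(s, 0)) for r in data["reactions"])
        for s in species
    )
    exchange = tuple(r["id"] for r in data["reactions"] if r.get("exchange"))
    known = {
        s["id"]: frac(s["molar_mass"])
        for s in data["species"]
        if s.get("molar_mass") is not None
    }
    masses = derive_masses(species, reactions, stoich, known, exchange)
    return GrowthModel(
        species=species,
        molar_masses=masses,
        reactions=reactions,
        stoich=stoich,
        irreversible=frozenset(
            r["id"] for r in data["reactions"] if r.get("irreversible", True)
        ),
        catalysts={
            r["id"]: r["catalyst"]
            for r in data["reactions"]
            if r.get("catalyst")
        },
        # honour the declared exchange partition (so that a mass-imbalanced
        # internal reaction is caught by validation, not silently
        # reclassified as exchange)
        exchange=frozenset(exchange),
    )


def write_model(model: GrowthModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path) -> GrowthModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# constraint config JSON (capacity parameters keyed by their usual symbols)


def params_to_dict(p: CapacityParams) -> dict:
    return {
        "k_cat": _rat(p.kcat),
        "k_el": _rat(p.kel),
        "A_L": _rat(p.area_L),
        "A_I": _rat(p.area_I),
        "r": [_rat(p.s2v_intercept), _rat(p.s2v_slope)],
        "rho": _rat(p.density),
        "alpha": _rat(p.alpha),
        "N_A": _rat(p.avogadro),
    }


def params_from_dict(data: dict) -> CapacityParams:
    kwargs = dict(
        kcat=frac(data["k_cat"]),
        kel=frac(data["k_el"]),
        area_L=frac(data["A_L"]),
        area_I=frac(data["A_I"]),
        s2v_intercept=frac(data["r"][0]),
        s2v_slope=frac(data["r"][1]),
        density=frac(data["rho"]),
        alpha=frac(data["alpha"]),
    )
    if "N_A" in data:
        kwargs["avogadro"] = frac(data["N_A"])
    return CapacityParams(**kwargs)


def custom_rows_from_list(rows: Sequence[dict]) -> list[ConstraintRow]:
    return [
        ConstraintRow(
            label=r["label"],
            relation=r.get("relation", ">="),
            conc={s: frac(c) for s, c in r.get("conc", {}).items()},
            flux={x: frac(c) for x, c in r.get("flux", {}).items()},
            rhs=frac(r.get("rhs", 0)),
        )
        for r in rows
    ]


def read_constraint_config(path) -> tuple[CapacityParams | None, list[ConstraintRow]]:
    data = json.loads(Path(path).read_text())
    params = params_from_dict(data["capacity"]) if "capacity" in data else None
    custom = custom_rows_from_list(data.get("custom", []))
    return params, custom


# ---------------------------------------------------------------------------
# matrices and elementary-vector sets as TSV


def write_matrix_tsv(rows: Mat, path, col_names, row_names) -> None:
    lines = ["\t".join(["#"] + list(col_names))]
    for name, row in zip(row_names, rows):
        lines.append("\t".join([name] + [_rat(frac(x)) for x in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path) -> tuple[Mat, tuple[str, ...], tuple[str, ...]]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    cols = tuple(lines[0].split("\t")[1:])
    row_names, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        row_names.append(parts[0])
        rows.append(tuple(frac(x) for x in parts[1:]))
    return tuple(rows), cols, tuple(row_names)


def write_ev_tsv(vectors: Sequence[Sequence], path, coord_names) -> None:
    write_matrix_tsv(
        tuple(tuple(frac(x) for x in v) for v in vectors),
        path,
        coord_names,
        [f"ev{i + 1}" for i in range(len(vectors))],
    )


# ---------------------------------------------------------------------------
# result tables (CSV, floats)


def egms_to_frame(model: GrowthModel, records) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {f"v {r}": float(x) for r, x in zip(model.reactions, rec.flux)}
        row["mu"] = float(rec.growth_rate_assoc)
        for s, x in zip(
            model.species, rec.concentrations_assoc or [0] * model.n_species
        ):
            row[f"x {s}"] = float(x)
            row[f"mf {s}"] = float(model.mass(s) * frac(x))
        row["produced"] = ";".join(sorted(rec.produced_species))
        row["support_size"] = len(rec.support)
        rows.append(row)
    return pd.DataFrame(rows)


def egvs_to_frame(model: GrowthModel, result: EGVResult) -> pd.DataFrame:
    rows = []
    for rec in result.records:
        row = {"mu": float(rec.growth_rate)}
        row.update(
            {f"v {r}": float(x) for r, x in zip(model.reactions, rec.flux)}
        )
        row.update(
            {
                f"x {s}": float(x)
                for s, x in zip(model.species, rec.concentrations_assoc)
            }
        )
        row.update(
            {
                f"mf {s}": float(x)
                for s, x in zip(model.species, rec.mass_fractions)
            }
        )
        if "r_IG" in model.reactions and "r_IN" in model.reactions:
            row["gamma_IG"] = float(rec.gamma(model, "r_IG"))
            row["gamma_IN"] = float(rec.gamma(model, "r_IN"))
        if {"G", "LD", "L"} <= set(model.species):
            row["s_C"] = float(rec.carbon_storage(model))
        if "R" in model.species:
            row["ribosome_mass_fraction"] = float(rec.mass_fraction(model, "R"))
        row["inactive_signature"] = ";".join(sorted(rec.inactive_signature))
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_to_frame(model: GrowthModel, sweep: MuSweepResult) -> pd.DataFrame:
    frames = []
    for mu in sweep.grid:
        df = egvs_to_frame(model, sweep.results[mu])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    classes = {
        ";".join(sorted(f.signature)): (f.uptake_class, f.ribosome_class)
        for f in sweep.families.values()
    }
    if not out.empty:
        out["uptake_class"] = out["inactive_signature"].map(
            lambda s: classes.get(s, (None, None))[0]
        )
        out["ribosome_class"] = out["inactive_signature"].map(
            lambda s: classes.get(s, (None, None))[1]
        )
    return out


def decomposition_to_dict(dec: ConformalDecomposition) -> dict:
    return {
        "convex": dec.convex,
        "ray_terms": [
            {"coefficient": _rat(c), "vector": [_rat(x) for x in v]}
            for v, c in dec.ray_terms
        ],
        "point_terms": [
            {"coefficient": _rat(c), "vector": [_rat(x) for x in v]}
            for v, c in dec.point_terms
        ],
    }


# ---------------------------------------------------------------------------
# random mass-consistent models (property-test inputs)


def generate_random_model(
    n_metabolites: int,
    n_macromolecules: int,
    n_reactions: int,
    seed: int,
    max_retries: int = 20,
) -> GrowthModel:
    """A random growth model that passes validation by construction.

    Every metabolite is imported (exchange), internal conversions are mass
    balanced by solving the last coefficient, and each macromolecule is
    polymerised from a metabolite with its mass derived from the balance.
    Deterministic for a given seed.
    """
    if n_metabolites < 1 or n_macromolecules < 1:
        raise ValueError("need at least one metabolite and one macromolecule")
    if n_reactions > 0 and n_metabolites < 2:
        raise ValueError("internal conversions need at least two metabolites")
    rng = random.Random(seed)
    for _ in range(max_retries):
        mets = [f"M{i + 1}" for i in range(n_metabolites)]
        macros = [f"P{i + 1}" for i in range(n_macromolecules)]
        species = tuple(mets + macros)
        masses = {m: Fraction(rng.randint(10, 500)) for m in mets}
        reactions: dict[str, dict[str, Fraction]] = {}
        exchange = []
        for m in mets:
            reactions[f"imp_{m}"] = {m: Fraction(1)}
            exchange.append(f"imp_{m}")
        for k in range(n_reactions):
            a, b = rng.sample(mets, 2)
            out = rng.choice(mets)
            ca, cb = Fraction(rng.randint(1, 3)), Fraction(rng.randint(1, 3))
            cout = (ca * masses[a] + cb * masses[b]) / masses[out]
            d = {a: -ca, b: -cb}
            d[out] = d.get(out, Fraction(0)) + cout
            reactions[f"cnv_{k + 1}"] = d
        for p in macros:
            prec = rng.choice(mets)
            n_units = Fraction(rng.randint(2, 50))
            masses[p] = n_units * masses[prec]
            reactions[f"syn_{p}"] = {prec: -n_units, p: Fraction(1)}
        catalysts = {
            r: rng.choice(macros) for r in reactions
        }
        rxn_ids = tuple(reactions)
        stoich = tuple(
            tuple(reactions[r].get(s, Fraction(0)) for r in rxn_ids)
            for s in species
        )
        model = GrowthModel(
            species=species,
            molar_masses=tuple(masses[s] for s in species),
            reactions=rxn_ids,
            stoich=stoich,
            irreversible=frozenset(rxn_ids),
            catalysts=catalysts,
        )
        if validate_model(model).passed:
            return model
    raise RuntimeError("could not generate a valid random model")
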