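"""Reading and writing species models, diets, metabolite lists and results.

Species models are read from SBML Level 3 + FBC (via cobrapy) or from a flat
JSON stoichiometric dialect; both serialize the same :class:`SpeciesModel`
contents.  Diets and metabolite lists are two-column / one-column TSV.
Campaign case tables are TSV with one row per case; community solutions dump
to JSON.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .model import (
    CrossfeedPolicy,
    DietSpec,
    ModelValidationError,
    Reaction,
    SpeciesModel,
)

__all__ = [
    "load_species_model",
    "write_species_json",
    "write_species_sbml",
    "load_diet",
    "write_diet",
    "load_metabolite_list",
    "write_metabolite_list",
    "write_case_table",
    "read_case_table",
    "solution_to_dict",
    "write_solution_json",
]

_BIOMASS_RE = re.compile(r"biomass|growth", re.IGNORECASE)
_ATPM_RE = re.compile(r"atpm|maintenance", re.IGNORECASE)


# ---------------------------------------------------------------------------
# species models


def _detect_reaction(ids: Sequence[str], pattern: re.Pattern, kind: str, sid: str) -> str:
    hits = [r for r in ids if pattern.search(r)]
    if not hits:
        raise ModelValidationError(
            f"{sid}: no {kind} reaction found; detection rule: id matching /{pattern.pattern}/i"
        )
    return sorted(hits)[0]


def _from_cobra(cm) -> SpeciesModel:
    import cobra

    mets = [(m.id, m.compartment or "c") for m in cm.metabolites]
    rxns = [
        Reaction(
            r.id,
            {m.id: float(c) for m, c in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
        )
        for r in cm.reactions
    ]
    rids = [r.id for r in rxns]
    # biomass: prefer the objective, fall back to the id pattern
    objective = [r.id for r in cm.reactions if r.objective_coefficient]
    biomass = objective[0] if objective else _detect_reaction(rids, _BIOMASS_RE, "biomass", cm.id)
    atpm = _detect_reaction(rids, _ATPM_RE, "ATPM", cm.id)
    return SpeciesModel(cm.id, mets, rxns, biomass, atpm).validate()


def _to_cobra(model: SpeciesModel):
    import cobra

    cm = cobra.Model(model.species_id)
    comp = model.compartments
    cobra_mets = {}
    for mid, c in model.metabolites:
        m = cobra.Metabolite(mid, compartment=c)
        cobra_mets[mid] = m
    cm.add_metabolites(list(cobra_mets.values()))
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({cobra_mets[m]: c for m, c in r.stoichiometry.items()})
    cm.objective = model.biomass_reaction_id
    return cm


def _from_json_dict(d: dict) -> SpeciesModel:
    try:
        model = SpeciesModel(
            species_id=d["species_id"],
            metabolites=[(m["id"], m["compartment"]) for m in d["metabolites"]],
            reactions=[
                Reaction(
                    r["id"],
                    {k: float(v) for k, v in r["stoichiometry"].items()},
                    float(r["lower_bound"]),
                    float(r["upper_bound"]),
                )
                for r in d["reactions"]
            ],
            biomass_reaction_id=d["biomass_reaction_id"],
            atpm_reaction_id=d["atpm_reaction_id"],
        )
    except KeyError as e:  # pragma: no cover - message detail only
        raise ModelValidationError(f"species JSON missing field {e}") from e
    return model.validate()


def _to_json_dict(model: SpeciesModel) -> dict:
    return {
        "species_id": model.species_id,
        "metabolites": [{"id": m, "compartment": c} for m, c in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
            }
            for r in model.reactions
        ],
        "biomass_reaction_id": model.biomass_reaction_id,
        "atpm_reaction_id": model.atpm_reaction_id,
    }


def load_species_model(path, format: Optional[str] = None) -> SpeciesModel:
    """Load and validate a :class:`SpeciesModel` from SBML or JSON.

    ``format`` is ``"sbml"`` or ``"json"``; if omitted it is inferred from
    the suffix (``.xml``/``.sbml`` vs ``.json``).  Biomass and ATPM reactions
    are auto-detected: biomass from the FBC objective (SBML) or by id pattern,
    ATPM by id pattern.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "json"
    if format == "sbml":
        import cobra.io

        return _from_cobra(cobra.io.read_sbml_model(str(path)))
    if format == "json":
        with open(path) as fh:
            return _from_json_dict(json.load(fh))
    raise ValueError(f"unknown model format {format!r}")


def write_species_json(model: SpeciesModel, path) -> None:
    model.validate()
    with open(path, "w") as fh:
        json.dump(_to_json_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_species_sbml(model: SpeciesModel, path) -> None:
    import cobra.io

    model.validate()
    cobra.io.write_sbml_model(_to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# diets and metabolite lists


def load_diet(path, name: Optional[str] = None) -> DietSpec:
    """Read a diet TSV with columns ``metabolite_id`` and ``max_uptake``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"metabolite_id": str})
    for col in ("metabolite_id", "max_uptake"):
        if col not in df.columns:
            raise ModelValidationError(f"diet file {path.name}: missing column {col!r}")
    if df["metabolite_id"].duplicated().any():
        dup = sorted(df.loc[df["metabolite_id"].duplicated(), "metabolite_id"])
        raise ModelValidationError(f"diet file {path.name}: duplicate metabolite rows {dup}")
    rates = pd.to_numeric(df["max_uptake"], errors="coerce")
    if rates.isna().any():
        bad = df.loc[rates.isna(), "metabolite_id"].tolist()
        raise ModelValidationError(f"diet file {path.name}: malformed max_uptake for {bad}")
    diet = DietSpec(name or path.stem, dict(zip(df["metabolite_id"], rates.astype(float))))
    return diet.validate()


def write_diet(diet: DietSpec, path) -> None:
    diet.validate()
    rows = sorted(diet.max_uptake.items())
    pd.DataFrame(rows, columns=["metabolite_id", "max_uptake"]).to_csv(path, sep="\t", index=False)


def load_metabolite_list(path) -> List[str]:
    """One-column TSV (header ``metabolite_id``) listing metabolite ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "metabolite_id" not in df.columns:
        raise ModelValidationError(f"metabolite list {Path(path).name}: missing column 'metabolite_id'")
    return df["metabolite_id"].tolist()


def write_metabolite_list(ids: Iterable[str], path) -> None:
    pd.DataFrame({"metabolite_id": list(ids)}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# case tables and solutions


def cases_to_frame(cases: Sequence) -> pd.DataFrame:
    """Flatten :class:`~gutcom.tradeoff.TradeoffCaseResult` objects into a table."""
    if not len(cases):
        raise ValueError("empty case list")
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "f": c.f,
            "seed": c.seed,
            "accepted": int(c.accepted),
            "mu": c.solution.mu if c.solution is not None else float("nan"),
            "growth_fraction": c.growth_fraction,
            "equitability": c.metrics.d_com if c.metrics is not None else float("nan"),
            "richness": c.metrics.richness if c.metrics is not None else -1,
        }
        for i, val in enumerate(c.scfa_fractions or (), start=1):
            row[f"scfa_frac{i}"] = val
        if c.solution is not None:
            for sp, p in c.solution.abundances.items():
                row[f"p:{sp}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def write_case_table(cases: Sequence, path) -> pd.DataFrame:
    """Write one TSV row per tradeoff case; floats at full precision (>=12 sig. digits)."""
    df = cases_to_frame(cases)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_case_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def solution_to_dict(solution) -> dict:
    return {
        "mu": solution.mu,
        "status": solution.status,
        "abundances": {k: float(v) for k, v in solution.abundances.items()},
        "fluxes": {k: float(v) for k, v in solution.fluxes.items()},
        "exchange_fluxes": {k: float(v) for k, v in solution.exchange_fluxes.items()},
    }


def write_solution_json(solution, path) -> None:
    with open(path, "w") as fh:
        json.dump(solution_to_dict(solution), fh, indent=1, sort_keys=True)
        fh.write("\n")
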