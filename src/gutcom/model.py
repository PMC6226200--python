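"""Core data types for constraint-based community modeling.

A :class:`SpeciesModel` is a single organism's stoichiometric model: a set of
metabolites assigned to compartments, reactions with flux bounds in
mmol/gDW/h, a biomass reaction whose flux equals the specific growth rate
(1/h), and a non-growth ATP maintenance (ATPM) reaction whose lower bound
enforces a mandatory upkeep flux.

Exchange reactions follow the dominant constraint-based convention: each
moves exactly one extracellular metabolite with stoichiometric coefficient
-1, so positive flux is secretion into the environment and negative flux is
uptake.  Extracellular metabolite identifiers are shared verbatim across
species so that a community build can pool them in one lumen compartment.

:class:`DietSpec` holds maximum uptake rates per extracellular metabolite
(the diet), and :class:`CrossfeedPolicy` the crossfeeding rules: which
byproducts any species may consume (and at what per-gram bound), which
short-chain fatty acids (SCFAs) are never consumed, and which metabolite ids
are tracked as the acetate/butyrate/propionate triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

__all__ = [
    "EXTRACELLULAR",
    "Reaction",
    "SpeciesModel",
    "DietSpec",
    "CrossfeedPolicy",
    "ModelValidationError",
    "InfeasibleError",
    "SamplingError",
]

#: compartment id used for extracellular metabolites in single-species models
EXTRACELLULAR = "e"

#: default cap used where a reaction is effectively unbounded (mmol/gDW/h)
LARGE_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model, diet or policy violates one of its declared invariants."""


class InfeasibleError(RuntimeError):
    """An LP that should characterize a model was infeasible or unbounded."""


class SamplingError(RuntimeError):
    """The randomized bound sampler exhausted its redraw budget."""


@dataclass
class Reaction:
    """One reaction: a stoichiometry map and flux bounds (mmol/gDW/h)."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = LARGE_BOUND

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound, self.upper_bound)


@dataclass
class SpeciesModel:
    """A validated single-species stoichiometric model.

    Parameters
    ----------
    species_id:
        Short label; used to prefix intracellular namespaces at community
        build time, so it must not contain the ``__`` separator.
    metabolites:
        ``(metabolite_id, compartment)`` pairs.  Compartment ``"e"`` marks
        extracellular metabolites.
    reactions:
        :class:`Reaction` objects referencing only declared metabolites.
    biomass_reaction_id, atpm_reaction_id:
        Must name existing, distinct reactions.
    """

    species_id: str
    metabolites: List[Tuple[str, str]]
    reactions: List[Reaction]
    biomass_reaction_id: str
    atpm_reaction_id: str

    # -- lookups ---------------------------------------------------------

    @property
    def compartments(self) -> Dict[str, str]:
        """Map metabolite id -> compartment."""
        return dict(self.metabolites)

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"{self.species_id}: no reaction {rid!r}")

    @property
    def exchange_reaction_ids(self) -> List[str]:
        """Reactions moving exactly one extracellular metabolite with coefficient -1."""
        comp = self.compartments
        out = []
        for r in self.reactions:
            if len(r.stoichiometry) == 1:
                (met, coef), = r.stoichiometry.items()
                if comp.get(met) == EXTRACELLULAR and coef == -1.0:
                    out.append(r.id)
        return out

    def exchange_metabolite(self, rid: str) -> str:
        """The extracellular metabolite moved by exchange reaction ``rid``."""
        r = self.reaction(rid)
        (met,) = r.stoichiometry
        return met

    def exchanges_by_metabolite(self) -> Dict[str, str]:
        """Map extracellular metabolite id -> exchange reaction id."""
        return {self.exchange_metabolite(rid): rid for rid in self.exchange_reaction_ids}

    # -- validation ------------------------------------------------------

    def validate(self) -> "SpeciesModel":
        """Check all declared invariants; raise :class:`ModelValidationError` naming the offender."""
        sid = self.species_id
        if "__" in sid:
            raise ModelValidationError(f"species id {sid!r} must not contain '__'")
        met_ids = [m for m, _ in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"{sid}: duplicate metabolite ids {dup}")
        declared = set(met_ids)
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"{sid}: duplicate reaction ids {dup}")
        for r in self.reactions:
            missing = set(r.stoichiometry) - declared
            if missing:
                raise ModelValidationError(
                    f"{sid}: reaction {r.id!r} references undeclared metabolites {sorted(missing)}"
                )
            if not r.stoichiometry:
                raise ModelValidationError(f"{sid}: reaction {r.id!r} has empty stoichiometry")
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"{sid}: reaction {r.id!r} has inverted bounds "
                    f"[{r.lower_bound}, {r.upper_bound}]"
                )
        if self.biomass_reaction_id not in set(rids):
            raise ModelValidationError(
                f"{sid}: biomass reaction {self.biomass_reaction_id!r} not found "
                "(expected a reaction whose id matches 'biomass'/'growth' or an explicit annotation)"
            )
        if self.atpm_reaction_id not in set(rids):
            raise ModelValidationError(f"{sid}: ATPM reaction {self.atpm_reaction_id!r} not found")
        if self.biomass_reaction_id == self.atpm_reaction_id:
            raise ModelValidationError(f"{sid}: biomass and ATPM reactions must be distinct")
        return self

    def copy(self) -> "SpeciesModel":
        return SpeciesModel(
            self.species_id,
            list(self.metabolites),
            [r.copy() for r in self.reactions],
            self.biomass_reaction_id,
            self.atpm_reaction_id,
        )


@dataclass
class DietSpec:
    """Maximum uptake rates per extracellular metabolite.

    For single-species use the rates are mmol/gDW/h; applied to a community
    extracellular space they are mmol/h per unit total community biomass
    (total abundance is normalized to 1, so the scales coincide).
    """

    name: str
    max_uptake: Dict[str, float]

    def validate(self) -> "DietSpec":
        for met, rate in self.max_uptake.items():
            if not (rate >= 0.0):
                raise ModelValidationError(f"diet {self.name!r}: max_uptake[{met!r}] = {rate} is negative")
        return self

    def copy(self) -> "DietSpec":
        return DietSpec(self.name, dict(self.max_uptake))


#: the 20 proteinogenic amino acids, lowercase three-letter codes
PROTEINOGENIC_AA: Tuple[str, ...] = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)

#: eight common fermentative byproducts promoted for crossfeeding
CROSSFED_BYPRODUCTS: Tuple[str, ...] = (
    "ac", "co2", "etoh", "for", "h2", "lac_D", "lac_L", "succ",
)


@dataclass
class CrossfeedPolicy:
    """Which metabolites may be crossfed, at what bound, and which are blocked.

    ``crossfed_ids`` default to 21 amino acids (20 proteinogenic plus one
    configurable extra, ornithine by default) and eight common metabolic
    byproducts; any species may take these up at ``crossfeed_uptake_bound``
    mmol/gDW/h.  ``blocked_uptake_ids`` (butyrate and propionate by default)
    can never be consumed by any species.  ``scfa_ids`` orders the SCFA
    analogs tracked by the metrics layer (acetate-, butyrate-,
    propionate-like).
    """

    crossfed_ids: Tuple[str, ...] = PROTEINOGENIC_AA + ("orn",) + CROSSFED_BYPRODUCTS
    crossfeed_uptake_bound: float = 10.0
    blocked_uptake_ids: Tuple[str, ...] = ("but", "ppa")
    scfa_ids: Tuple[str, ...] = ("ac", "but", "ppa")

    def validate(self) -> "CrossfeedPolicy":
        overlap = set(self.blocked_uptake_ids) & set(self.crossfed_ids)
        if overlap:
            raise ModelValidationError(
                f"policy: blocked_uptake_ids and crossfed_ids overlap on {sorted(overlap)}"
            )
        if not (self.crossfeed_uptake_bound >= 0.0):
            raise ModelValidationError(
                f"policy: crossfeed_uptake_bound = {self.crossfeed_uptake_bound} is negative"
            )
        return self

    def copy(self) -> "CrossfeedPolicy":
        return replace(self)
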