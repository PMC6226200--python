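"""Merging species models into a community with a shared extracellular space.

The community model follows the steady-state community FBA layout: each
species keeps its own intracellular (and periplasmic) namespace, prefixed
``<species_id>__``, while extracellular metabolite ids are pooled verbatim
into one shared lumen.  Each species exchange reaction is rewritten to
bridge the species' own extracellular copy and the lumen::

    EX_m (species k):  k__m  ->  m        flux > 0: secretion into the lumen
                                          flux < 0: uptake from the lumen

and every lumen metabolite gets exactly one community exchange reaction
``m -> (outside)`` whose lower bound is minus the diet's maximum uptake rate
(0 if the diet does not supply ``m``) and whose upper bound is a large
secretion cap.

Per-species reaction bounds are *templates* in mmol/gDW/h: at solve time
they are scaled by the species' abundance (see :mod:`gutcom.steadycom`).
Community exchange bounds are in mmol/h per unit total community biomass and
are not scaled.

Species-level uptake caps combine the model's own transporter limit with the
diet and the crossfeeding policy:

* metabolite in the diet: ``min(model cap, diet rate)``;
* crossfed metabolite: raised to at least ``policy.crossfeed_uptake_bound``;
* blocked SCFA (butyrate/propionate analogs): 0, community-wide;
* anything else: 0 (no uptake of metabolites neither fed nor crossfed).

Secretion bounds are left as in the species model, so net SCFA synthesis is
still reportable for blocked metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .model import (
    EXTRACELLULAR,
    LARGE_BOUND,
    CrossfeedPolicy,
    DietSpec,
    ModelValidationError,
    Reaction,
    SpeciesModel,
)

__all__ = ["CommunityModel", "build_community", "restrict_species", "SECRETION_CAP"]

#: default community secretion cap, mmol/h per unit community biomass
SECRETION_CAP = 1000.0


def qualify(species_id: str, name: str) -> str:
    return f"{species_id}__{name}"


@dataclass
class CommunityModel:
    """A merged multi-species model with a shared lumen compartment."""

    species: List[str]
    source_models: Dict[str, SpeciesModel]
    #: per species: qualified reactions whose bounds are per-gDW templates
    reactions: Dict[str, List[Reaction]]
    biomass_reaction: Dict[str, str]
    atpm_reaction: Dict[str, str]
    #: per species: lumen metabolite -> qualified exchange reaction id
    species_exchanges: Dict[str, Dict[str, str]]
    lumen_metabolites: List[str]
    #: lumen metabolite -> (lower, upper) bound of its community exchange
    community_exchange_bounds: Dict[str, Tuple[float, float]]
    abundance_bounds: Dict[str, Tuple[float, float]]
    diet: DietSpec
    policy: CrossfeedPolicy
    secretion_cap: float = SECRETION_CAP

    @property
    def n_species(self) -> int:
        return len(self.species)

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            species=list(self.species),
            source_models={s: m.copy() for s, m in self.source_models.items()},
            reactions={s: [r.copy() for r in rs] for s, rs in self.reactions.items()},
            biomass_reaction=dict(self.biomass_reaction),
            atpm_reaction=dict(self.atpm_reaction),
            species_exchanges={s: dict(d) for s, d in self.species_exchanges.items()},
            lumen_metabolites=list(self.lumen_metabolites),
            community_exchange_bounds=dict(self.community_exchange_bounds),
            abundance_bounds=dict(self.abundance_bounds),
            diet=self.diet.copy(),
            policy=self.policy.copy(),
            secretion_cap=self.secretion_cap,
        )

    def with_abundance_bounds(self, bounds: Dict[str, Tuple[float, float]]) -> "CommunityModel":
        """A copy with the given per-species abundance bounds applied on top."""
        out = self.copy()
        for sid, (lo, hi) in bounds.items():
            if sid not in out.abundance_bounds:
                raise KeyError(f"unknown species {sid!r}")
            if not (0.0 <= lo <= hi <= 1.0):
                raise ModelValidationError(
                    f"abundance bounds for {sid!r} must satisfy 0 <= lower <= upper <= 1, got [{lo}, {hi}]"
                )
            out.abundance_bounds[sid] = (float(lo), float(hi))
        return out

    # structural helpers used by tests -----------------------------------

    def intracellular_metabolites(self, sid: str) -> Set[str]:
        return {
            m
            for r in self.reactions[sid]
            for m in r.stoichiometry
            if m not in self.community_exchange_bounds
        }


def _species_uptake_cap(
    met: str, model_cap: float, diet: DietSpec, policy: CrossfeedPolicy
) -> float:
    if met in policy.blocked_uptake_ids:
        return 0.0
    cap = min(model_cap, diet.max_uptake[met]) if met in diet.max_uptake else 0.0
    if met in policy.crossfed_ids:
        cap = max(cap, policy.crossfeed_uptake_bound)
    return cap


def build_community(
    models: Iterable[SpeciesModel],
    diet: DietSpec,
    policy: Optional[CrossfeedPolicy] = None,
    secretion_cap: float = SECRETION_CAP,
    ignore_unused_diet: bool = False,
) -> CommunityModel:
    """Merge validated species models under a diet and crossfeeding policy.

    The community uptake bound for each lumen metabolite is the diet rate if
    the diet supplies it and 0 otherwise (the diet is the union of uptake
    constraints); the community secretion bound is ``secretion_cap``.  Diet
    metabolites no species can exchange raise an error unless
    ``ignore_unused_diet`` is set (useful when applying a shared diet to a
    community subset).
    """
    models = [m.validate() for m in models]
    policy = (policy or CrossfeedPolicy()).validate()
    diet.validate()
    if not models:
        raise ModelValidationError("need at least one species model")
    sids = [m.species_id for m in models]
    if len(set(sids)) != len(sids):
        dup = sorted({s for s in sids if sids.count(s) > 1})
        raise ModelValidationError(f"duplicate species ids {dup}")

    exchanged: Set[str] = set()
    for m in models:
        exchanged |= set(m.exchanges_by_metabolite())
    unknown = set(diet.max_uptake) - exchanged
    if unknown:
        if not ignore_unused_diet:
            raise ModelValidationError(
                f"diet {diet.name!r} names metabolites absent from every species: {sorted(unknown)}"
            )
        diet = DietSpec(
            diet.name,
            {k: v for k, v in diet.max_uptake.items() if k in exchanged},
        )

    reactions: Dict[str, List[Reaction]] = {}
    biomass: Dict[str, str] = {}
    atpm: Dict[str, str] = {}
    species_exchanges: Dict[str, Dict[str, str]] = {}
    for m in models:
        sid = m.species_id
        comp = m.compartments
        ex_ids = set(m.exchange_reaction_ids)
        qrs: List[Reaction] = []
        ex_map: Dict[str, str] = {}
        for r in m.reactions:
            qid = qualify(sid, r.id)
            if r.id in ex_ids:
                (met,) = r.stoichiometry
                cap = _species_uptake_cap(met, -r.lower_bound, diet, policy)
                qrs.append(
                    Reaction(qid, {qualify(sid, met): -1.0, met: 1.0}, -cap, r.upper_bound)
                )
                ex_map[met] = qid
            else:
                stoich = {qualify(sid, met): c for met, c in r.stoichiometry.items()}
                qrs.append(Reaction(qid, stoich, r.lower_bound, r.upper_bound))
        reactions[sid] = qrs
        biomass[sid] = qualify(sid, m.biomass_reaction_id)
        atpm[sid] = qualify(sid, m.atpm_reaction_id)
        species_exchanges[sid] = ex_map

    lumen = sorted(exchanged)
    community_exchange_bounds = {
        met: (-float(diet.max_uptake.get(met, 0.0)), float(secretion_cap)) for met in lumen
    }

    return CommunityModel(
        species=sids,
        source_models={m.species_id: m for m in models},
        reactions=reactions,
        biomass_reaction=biomass,
        atpm_reaction=atpm,
        species_exchanges=species_exchanges,
        lumen_metabolites=lumen,
        community_exchange_bounds=community_exchange_bounds,
        abundance_bounds={s: (0.0, 1.0) for s in sids},
        diet=diet.copy(),
        policy=policy,
        secretion_cap=secretion_cap,
    )


def restrict_species(
    community: CommunityModel, keep: Iterable[str], mode: str = "soft"
) -> CommunityModel:
    """Restrict the community to a subset of species.

    ``mode="soft"`` zeroes the abundance upper bound of excluded species;
    ``mode="hard"`` rebuilds the community from the kept species' source
    models.  Both produce identical optima.
    """
    keep = set(keep)
    unknown = keep - set(community.species)
    if unknown:
        raise KeyError(f"unknown species ids {sorted(unknown)}")
    if mode == "soft":
        bounds = {s: (0.0, 0.0) for s in community.species if s not in keep}
        return community.with_abundance_bounds(bounds)
    if mode == "hard":
        kept_models = [community.source_models[s] for s in community.species if s in keep]
        return build_community(
            kept_models,
            community.diet,
            community.policy,
            community.secretion_cap,
            ignore_unused_diet=True,
        )
    raise ValueError(f"mode must be 'soft' or 'hard', got {mode!r}")
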