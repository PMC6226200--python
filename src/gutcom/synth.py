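"""Synthetic toy communities with analytically known optima.

Every toy species follows one template: it imports a single substrate
(a diet carbohydrate or a crossfed byproduct), converts it to biomass with
a fixed yield (gDW/mmol), optionally secretes byproducts in fixed
proportion to growth, and pays a non-growth ATP maintenance (ATPM) modeled
as a mandatory substrate drain.  The closed-form standalone growth rate is
therefore

    mu = yield * (min(uptake_cap, diet_supply) - ATPM)        (>= 0)

with LP infeasibility when the maintenance drain exceeds the available
supply, and exactly zero growth when they coincide — which is how
zero-growth-at-maintenance species are generated.  Obligate crossfeeders
import a byproduct that no diet supplies, so they grow only in community.

Two documented fixtures ship with the package:

* :func:`toy3_fixture` — a 3-species chain (fast glucose specialist A,
  obligate crossfeeder B living on A's byproduct, slower specialist C that
  secretes a blocked SCFA analog) whose community optima are known in
  closed form and double-checked by the simplex-grid oracle.
* :func:`demo8_spec` — an 8-species community with heterogeneous growth
  rates, two obligate crossfeeders, one zero-growth maintainer and three
  tagged SCFA analogs, used for campaign-scale analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    CrossfeedPolicy,
    DietSpec,
    ModelValidationError,
    Reaction,
    SpeciesModel,
)

__all__ = [
    "ToySpeciesSpec",
    "ToyCommunitySpec",
    "build_toy_species",
    "make_toy_community",
    "toy3_fixture",
    "demo8_spec",
    "random_toy_spec",
    "write_fixture_set",
    "closed_form_single_growth",
    "TOY3_MU_MAX",
    "TOY3_OPTIMAL_ABUNDANCES",
    "TOY3_MU_MAX_A_CAPPED",
]

# closed-form facts about the toy3 fixture (derived in docs/methods.md and
# re-verified against the simplex-grid oracle in the tests)
TOY3_MU_MAX = 0.4
TOY3_OPTIMAL_ABUNDANCES = (1.0, 0.0, 0.0)
#: maximal growth when species A's abundance is capped at 0.5; the
#: abundance split between B and C is then non-unique
TOY3_MU_MAX_A_CAPPED = 0.3


@dataclass
class ToySpeciesSpec:
    """One template species: substrate, cap, yield, maintenance, byproducts."""

    species_id: str
    substrate: str
    uptake_cap: float  # mmol/gDW/h
    biomass_yield: float  # gDW per mmol substrate
    atpm: float = 0.0  # mmol/gDW/h substrate drain
    #: byproduct id -> mmol secreted per unit biomass flux
    byproducts: Dict[str, float] = field(default_factory=dict)


@dataclass
class ToyCommunitySpec:
    species: List[ToySpeciesSpec]
    diet: Dict[str, float]
    crossfed_ids: Tuple[str, ...]
    blocked_ids: Tuple[str, ...] = ()
    scfa_ids: Tuple[str, ...] = ()
    crossfeed_uptake_bound: float = 10.0
    allow_cycles: bool = False
    seed: int = 0

    def validate(self) -> "ToyCommunitySpec":
        for sp in self.species:
            if sp.biomass_yield <= 0:
                raise ModelValidationError(f"{sp.species_id}: yield must be > 0")
            if sp.uptake_cap < 0 or sp.atpm < 0:
                raise ModelValidationError(f"{sp.species_id}: negative cap or ATPM")
            if sp.substrate in sp.byproducts:
                raise ModelValidationError(
                    f"{sp.species_id}: substrate {sp.substrate!r} cannot also be a byproduct"
                )
        if not any(sp.substrate in self.diet for sp in self.species):
            raise ModelValidationError("no species imports a diet-supplied substrate")
        if not self.allow_cycles and self._has_cycle():
            raise ModelValidationError(
                "crossfeeding topology is cyclic; set allow_cycles=True to permit it"
            )
        return self

    def _has_cycle(self) -> bool:
        producers: Dict[str, List[str]] = {}
        for sp in self.species:
            for b in sp.byproducts:
                producers.setdefault(b, []).append(sp.species_id)
        edges: Dict[str, List[str]] = {
            sp.species_id: producers.get(sp.substrate, []) for sp in self.species
        }
        state: Dict[str, int] = {}

        def dfs(node: str) -> bool:
            state[node] = 1
            for nxt in edges.get(node, []):
                s = state.get(nxt, 0)
                if s == 1 or (s == 0 and dfs(nxt)):
                    return True
            state[node] = 2
            return False

        return any(state.get(sp.species_id, 0) == 0 and dfs(sp.species_id) for sp in self.species)


def build_toy_species(sp: ToySpeciesSpec) -> SpeciesModel:
    """Instantiate the template as a validated :class:`SpeciesModel`."""
    sub = sp.substrate
    mets: List[Tuple[str, str]] = [(sub, "e"), (f"{sub}_c", "c")]
    reactions = [
        Reaction(f"EX_{sub}", {sub: -1.0}, -sp.uptake_cap, 1000.0),
        Reaction(f"TR_{sub}", {sub: -1.0, f"{sub}_c": 1.0}, -1000.0, 1000.0),
        Reaction(
            "GROWTH",
            {f"{sub}_c": -1.0 / sp.biomass_yield}
            | {f"{b}_c": rate for b, rate in sp.byproducts.items()},
            0.0,
            1000.0,
        ),
        Reaction("ATPM", {f"{sub}_c": -1.0}, sp.atpm, 1000.0),
    ]
    for b in sp.byproducts:
        mets += [(b, "e"), (f"{b}_c", "c")]
        reactions.append(Reaction(f"TR_{b}", {f"{b}_c": -1.0, b: 1.0}, -1000.0, 1000.0))
        reactions.append(Reaction(f"EX_{b}", {b: -1.0}, 0.0, 1000.0))
    return SpeciesModel(sp.species_id, mets, reactions, "GROWTH", "ATPM").validate()


def closed_form_single_growth(sp: ToySpeciesSpec, diet: Dict[str, float]) -> Optional[float]:
    """Standalone growth of a template species; ``None`` where the LP is infeasible."""
    supply = min(sp.uptake_cap, diet.get(sp.substrate, 0.0))
    if supply < sp.atpm:
        return None
    return sp.biomass_yield * (supply - sp.atpm)


def make_toy_community(
    spec: ToyCommunitySpec,
) -> Tuple[List[SpeciesModel], DietSpec, CrossfeedPolicy]:
    """Materialize a toy community spec; deterministic given the spec (and its seed)."""
    spec.validate()
    models = [build_toy_species(sp) for sp in spec.species]
    diet = DietSpec("toy", dict(spec.diet)).validate()
    policy = CrossfeedPolicy(
        crossfed_ids=tuple(spec.crossfed_ids),
        crossfeed_uptake_bound=spec.crossfeed_uptake_bound,
        blocked_uptake_ids=tuple(spec.blocked_ids),
        scfa_ids=tuple(spec.scfa_ids) or ("ac", "but", "ppa"),
    ).validate()
    return models, diet, policy


# ---------------------------------------------------------------------------
# shipped fixtures


def toy3_spec() -> ToyCommunitySpec:
    """The analytically solvable 3-species fixture.

    A converts glucose (cap 10) to biomass at yield 0.04 and secretes one
    intermediate ``xm`` per glucose; B is an obligate crossfeeder on ``xm``
    (cap 10, yield 0.03); C converts glucose (cap 5) at yield 0.06 and
    secretes the blocked SCFA analog ``scfa_p``.  Community glucose supply
    is 10.  Closed form: unconstrained mu_max = 0.04 * 10 = 0.4 with
    abundances (1, 0, 0); capping A at 0.5 gives mu_max = 0.3 (both B's
    ``xm`` uptake cap and C's glucose cap bind at 0.3) with a non-unique
    B/C split; B alone grows at 0.
    """
    return ToyCommunitySpec(
        species=[
            ToySpeciesSpec("A", "glc", 10.0, 0.04, 0.0, {"xm": 1.0 / 0.04}),
            ToySpeciesSpec("B", "xm", 10.0, 0.03, 0.0, {}),
            ToySpeciesSpec("C", "glc", 5.0, 0.06, 0.0, {"scfa_p": 1.0 / 0.06}),
        ],
        diet={"glc": 10.0},
        crossfed_ids=("xm",),
        blocked_ids=("scfa_p",),
        scfa_ids=("scfa_p",),
    )


def toy3_fixture() -> Tuple[List[SpeciesModel], DietSpec, CrossfeedPolicy]:
    return make_toy_community(toy3_spec())


def demo8_spec(seed: int = 0) -> ToyCommunitySpec:
    """An 8-species community for campaign-scale analyses.

    Standalone growth rates span 0 to 0.5 1/h: a fast glucose specialist,
    butyrate- and propionate-analog producers, a fibrolytic that feeds an
    obligate crossfeeder chain, an acetate-consuming crossfeeder, a
    zero-growth maintainer (uptake cap exactly equal to its ATPM drain) and
    an ethanol producer.  The maximal-growth community is the specialist
    monoculture (mu = 0.5), so suboptimal campaigns raise diversity.
    """
    return ToyCommunitySpec(
        species=[
            ToySpeciesSpec("specialist", "glc", 10.0, 0.050, 0.0, {"ac": 10.0}),
            ToySpeciesSpec("butyrogen", "glc", 9.0, 0.050, 0.0, {"but": 8.0}),
            ToySpeciesSpec("propiogen", "glc", 7.0, 0.060, 0.0, {"ppa": 7.0}),
            ToySpeciesSpec("fibrolytic", "fib", 5.0, 0.080, 0.0, {"ac": 4.0, "xint": 5.0}),
            ToySpeciesSpec("xfeeder", "xint", 10.0, 0.045, 0.0, {"but": 6.0}),
            ToySpeciesSpec("acetovore", "ac", 10.0, 0.040, 0.0, {"ppa": 5.0}),
            ToySpeciesSpec("maintainer", "glc", 10.0, 0.040, 10.0, {}),
            ToySpeciesSpec("ethanologen", "fib", 4.0, 0.095, 0.0, {"etoh": 6.0}),
        ],
        diet={"glc": 10.0, "fib": 8.0},
        crossfed_ids=("ac", "xint", "etoh"),
        blocked_ids=("but", "ppa"),
        scfa_ids=("ac", "but", "ppa"),
        seed=seed,
    )


def random_toy_spec(
    n_species: int = 4,
    n_crossfeeders: int = 1,
    seed: int = 0,
) -> ToyCommunitySpec:
    """A randomized acyclic toy community (for property tests).

    Primary consumers import the diet substrate with random caps and
    yields; each crossfeeder imports the byproduct of one randomly chosen
    primary consumer.  Deterministic for a fixed seed.
    """
    if n_crossfeeders >= n_species:
        raise ValueError("need at least one primary consumer")
    rng = np.random.default_rng(seed)
    species: List[ToySpeciesSpec] = []
    n_primary = n_species - n_crossfeeders
    for i in range(n_primary):
        species.append(
            ToySpeciesSpec(
                f"prim{i}",
                "glc",
                float(rng.uniform(2.0, 10.0)),
                float(rng.uniform(0.03, 0.10)),
                0.0,
                {f"byp{i}": float(rng.uniform(1.0, 10.0))},
            )
        )
    for i in range(n_crossfeeders):
        host = int(rng.integers(0, n_primary))
        species.append(
            ToySpeciesSpec(
                f"xf{i}",
                f"byp{host}",
                float(rng.uniform(2.0, 10.0)),
                float(rng.uniform(0.03, 0.10)),
                0.0,
                {},
            )
        )
    return ToyCommunitySpec(
        species=species,
        diet={"glc": float(rng.uniform(5.0, 15.0))},
        crossfed_ids=tuple(f"byp{i}" for i in range(n_primary)),
        blocked_ids=(),
        scfa_ids=(f"byp{0}",),
        seed=seed,
    )


def write_fixture_set(directory, n_cases_per_level: int = 10) -> List[str]:
    """Write the shipped fixtures (SBML + JSON models, diet and policy TSVs,
    reduced campaign schedule) into ``directory``; returns the file names."""
    from . import io as gio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: List[str] = []
    for name, spec in (("toy3", toy3_spec()), ("demo8", demo8_spec())):
        models, diet, policy = make_toy_community(spec)
        for m in models:
            for fmt, writer in (("xml", gio.write_species_sbml), ("json", gio.write_species_json)):
                fn = directory / f"{name}_{m.species_id}.{fmt}"
                writer(m, fn)
                written.append(fn.name)
        gio.write_diet(diet, directory / f"{name}_diet.tsv")
        gio.write_metabolite_list(policy.crossfed_ids, directory / f"{name}_crossfed.tsv")
        written += [f"{name}_diet.tsv", f"{name}_crossfed.tsv"]
    sched = pd.DataFrame(
        {"f": [0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.99]}
    )
    sched["n_cases"] = n_cases_per_level
    sched.to_csv(directory / "schedule_reduced.tsv", sep="\t", index=False)
    written.append("schedule_reduced.tsv")
    return written
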