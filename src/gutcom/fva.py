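"""Abundance variability analysis: which species can, or must, be present.

At a fixed fraction ``f`` of the maximal community growth rate, each species
abundance is minimized and maximized subject to the community FBA constraint
set with total abundance fixed to 1 (2N LPs for N species).  Growth is fixed
as an *equality* at ``f * mu_max``, so possibility need not be monotone in
``f``; coexistence cutoffs are therefore reported on an explicit grid.

A species is *possible* at ``f`` if its abundance can be maximized to exceed
a threshold (1% by default) and *essential* if it cannot be minimized below
it; essential implies possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .community import CommunityModel
from .model import InfeasibleError
from .steadycom import CommunityLP, CommunitySolution

__all__ = [
    "FVAResult",
    "abundance_fva",
    "classify_possible_essential",
    "coexistence_cutoff",
    "reduce_community",
    "DEFAULT_F_GRID",
    "POSSIBLE_THRESHOLD",
]

#: abundance threshold defining possible/essential species and richness
POSSIBLE_THRESHOLD = 0.01

#: growth-fraction grid for coexistence cutoffs (10% to 99.99% of maximum)
DEFAULT_F_GRID: Tuple[float, ...] = (
    0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95, 0.99, 0.9999,
)


@dataclass
class FVAResult:
    """Per-species abundance ranges at a fixed fraction of maximal growth."""

    f: float
    mu: float
    species: List[str]
    p_min: pd.Series
    p_max: pd.Series
    #: (species_id, "min"/"max") -> optimizing CommunitySolution
    solutions: Dict[Tuple[str, str], CommunitySolution] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p_min": self.p_min, "p_max": self.p_max})


def abundance_fva(
    community: CommunityModel,
    f: float,
    mu_max: float,
    abundance_bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    keep_solutions: bool = True,
) -> FVAResult:
    """Minimize and maximize every species abundance at growth ``f * mu_max``.

    If the LP is infeasible at exactly ``f * mu_max`` (possible at ``f = 1``
    given the bisection tolerance) the target is retried once at
    ``f * mu_max * (1 - 1e-6)``.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError(f"f must be in (0, 1], got {f}")
    lp = CommunityLP(community)
    mu = f * mu_max

    def solve_all(mu_try: float) -> Optional[FVAResult]:
        p_min, p_max, sols = {}, {}, {}
        for sid in community.species:
            for sense, store in ((-1, p_min), (+1, p_max)):
                sol = lp.solve(
                    mu_try,
                    objective=("abundance", sid, sense),
                    fix_total=True,
                    abundance_bounds=abundance_bounds,
                )
                if sol.status != "optimal":
                    return None
                store[sid] = float(sol.abundances[sid])
                if keep_solutions:
                    sols[(sid, "min" if sense < 0 else "max")] = sol
        return FVAResult(
            f=f,
            mu=mu_try,
            species=list(community.species),
            p_min=pd.Series(p_min),
            p_max=pd.Series(p_max),
            solutions=sols,
        )

    result = solve_all(mu)
    if result is None:
        result = solve_all(mu * (1.0 - 1e-6))
    if result is None:
        raise InfeasibleError(f"abundance FVA infeasible at f={f} (mu={mu})")
    return result


def classify_possible_essential(
    result: FVAResult, threshold: float = POSSIBLE_THRESHOLD
) -> Tuple[int, int, pd.DataFrame]:
    """Counts and per-species flags of possible and essential species.

    Possible: the abundance can be maximized to *exceed* ``threshold``
    (strict inequality).  Essential: it cannot be minimized to ``threshold``
    or below.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    possible = result.p_max > threshold
    essential = result.p_min > threshold
    flags = pd.DataFrame({"possible": possible, "essential": essential})
    return int(possible.sum()), int(essential.sum()), flags


def coexistence_cutoff(
    community: CommunityModel,
    mu_max: float,
    f_grid: Sequence[float] = DEFAULT_F_GRID,
    threshold: float = POSSIBLE_THRESHOLD,
) -> pd.DataFrame:
    """Largest grid fraction at which each species is still possible.

    Returns a frame with columns ``cutoff`` (0 for species never possible)
    and ``monotone`` (False where possibility is non-monotone across the
    grid, which can occur because growth is fixed as an equality).
    """
    f_grid = sorted(f_grid)
    if not all(0.0 < f <= 1.0 for f in f_grid):
        raise ValueError("f_grid values must lie in (0, 1]")
    possible = {}
    for f in f_grid:
        res = abundance_fva(community, f, mu_max, keep_solutions=False)
        possible[f] = res.p_max > threshold
    table = pd.DataFrame(possible)  # species x f
    cutoff = {}
    monotone = {}
    for sid, row in table.iterrows():
        fs = [f for f in f_grid if row[f]]
        cutoff[sid] = max(fs) if fs else 0.0
        # monotone means: once impossible, never possible again at higher f
        flags = [bool(row[f]) for f in f_grid]
        monotone[sid] = all(
            not (not a and b) for a, b in zip(flags, flags[1:])
        ) or all(flags)
    out = pd.DataFrame({"cutoff": pd.Series(cutoff), "monotone": pd.Series(monotone)})
    return out.loc[community.species]


def reduce_community(
    cutoffs_by_diet: Dict[str, pd.Series], f_cut: float = 0.70
) -> List[str]:
    """Species retained after eliminating weak coexistors.

    A species is retained if its coexistence cutoff exceeds ``f_cut`` on at
    least one diet.  Raises if nothing survives.
    """
    if not cutoffs_by_diet:
        raise ValueError("need cutoffs for at least one diet")
    frames = pd.DataFrame(cutoffs_by_diet)
    retained = frames.index[(frames > f_cut).any(axis=1)].tolist()
    if not retained:
        raise InfeasibleError(f"no species coexists above f_cut={f_cut} on any diet")
    return retained
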