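"""Randomized abundance-bound sampling of the growth-diversity tradeoff.

The sampler converts abundance-FVA maxima at a growth fraction ``f`` into
randomized per-species upper bounds

    p_U_j = min(1, 2 r_j p_max_j / sum_i p_max_i),   r_j ~ U[0, 1] i.i.d.

The division normalizes the FVA maxima to sum to 1 and the factor 2
compensates the expectation of ``r`` (E[2r] = 1), so species with larger
FVA abundances receive larger bounds on average.  Whole vectors are redrawn
until ``sum_j p_U_j >= 1``, which avoids structurally infeasible LPs while
preserving the stated distribution conditional on feasibility.  The bounds
are heuristic: they bias solutions toward higher diversity than the
unconstrained optimum but do not guarantee Pareto optimality in the
growth-diversity plane.

A campaign runs a schedule of cases per FVA level (default 900 cases,
weighted toward low growth fractions), maximizes community growth under
each sampled bound vector, discards solutions whose abundance sum strays
from 1 by more than 1e-4, and attaches diversity and SCFA metrics.  Every
case draws from its own counter-seeded RNG stream, so results are
bit-reproducible for a fixed master seed and independent of execution
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .community import CommunityModel
from .fva import FVAResult
from .metrics import DiversityMetrics, diversity_metrics
from .model import InfeasibleError, SamplingError
from .steadycom import (
    ABUNDANCE_SUM_TOL,
    CommunitySolution,
    maximize_community_growth,
)
from . import metrics as _metrics

__all__ = [
    "TradeoffCaseResult",
    "CampaignSchedule",
    "scaled_upper_bounds",
    "sample_bounds",
    "run_campaign",
    "DEFAULT_SCHEDULE",
]

#: cases per FVA growth fraction; totals 900
DEFAULT_SCHEDULE: Dict[float, int] = {
    0.60: 150,
    0.65: 150,
    0.70: 125,
    0.75: 125,
    0.80: 100,
    0.85: 100,
    0.90: 100,
    0.95: 25,
    0.99: 25,
}


@dataclass
class CampaignSchedule:
    """Number of sampled cases per FVA growth fraction, plus the master seed."""

    cases: Dict[float, int] = field(default_factory=lambda: dict(DEFAULT_SCHEDULE))
    master_seed: int = 0

    def validate(self) -> "CampaignSchedule":
        for f, n in self.cases.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"schedule level {f} outside (0, 1]")
            if n < 0:
                raise ValueError(f"schedule count for level {f} is negative")
        return self

    @property
    def total_cases(self) -> int:
        return sum(self.cases.values())

    @classmethod
    def reduced(cls, n_per_level: int = 10, master_seed: int = 0) -> "CampaignSchedule":
        """Small-footprint schedule (same levels, ``n_per_level`` cases each)."""
        return cls({f: n_per_level for f in DEFAULT_SCHEDULE}, master_seed)


@dataclass
class TradeoffCaseResult:
    """One sampled case: the draw, the solution and its derived metrics."""

    case_id: int
    f: float
    seed: int
    r: np.ndarray
    p_upper: np.ndarray
    solution: Optional[CommunitySolution]
    accepted: bool
    growth_fraction: float = float("nan")
    metrics: Optional[DiversityMetrics] = None
    scfa_fractions: Optional[Tuple[float, ...]] = None
    note: str = ""


def scaled_upper_bounds(
    p_max: np.ndarray, r: np.ndarray, clamp: bool = True
) -> np.ndarray:
    """Evaluate ``p_U = 2 r p_max / sum(p_max)``, optionally clamped to <= 1."""
    p_max = np.asarray(p_max, dtype=float)
    total = p_max.sum()
    if total <= 0:
        raise ValueError("sum of FVA maxima must be positive")
    p_u = 2.0 * np.asarray(r, dtype=float) * p_max / total
    if clamp:
        p_u = np.minimum(p_u, 1.0)
    return p_u


def sample_bounds(
    p_max: Sequence[float],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``(r, p_U)`` with the whole vector redrawn until ``sum(p_U) >= 1``.

    Species with a zero FVA maximum are forced to a zero upper bound (they
    are excluded from the case outright).  Raises
    :class:`~gutcom.model.SamplingError` when the redraw budget is
    exhausted, which signals that ``sum(p_max)`` is barely above the
    feasibility threshold.
    """
    p_max = np.asarray(p_max, dtype=float)
    for _ in range(max_attempts):
        r = rng.uniform(0.0, 1.0, size=p_max.size)
        p_u = scaled_upper_bounds(p_max, r, clamp=True)
        p_u[p_max == 0.0] = 0.0
        if p_u.sum() >= 1.0:
            return r, p_u
    raise SamplingError(
        f"no feasible bound vector in {max_attempts} draws (sum p_max = {p_max.sum():.4g})"
    )


def _case_seed(master_seed: int, case_index: int) -> int:
    # stable, order-independent stream per case; keep derived seeds < 2^31
    ss = np.random.SeedSequence([int(master_seed), int(case_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_campaign(
    community: CommunityModel,
    mu_max: float,
    fva_by_level: Dict[float, FVAResult],
    schedule: CampaignSchedule,
    sum_tol: float = ABUNDANCE_SUM_TOL,
) -> List[TradeoffCaseResult]:
    """Run the full sampled-bounds campaign.

    ``fva_by_level`` must hold an :class:`~gutcom.fva.FVAResult` for every
    growth fraction in the schedule.  Accepted and discarded cases are both
    returned; per-case failures (sampling budget, LP infeasibility) are
    recorded in the case's ``note`` and never abort the campaign.
    """
    schedule.validate()
    missing = set(schedule.cases) - set(fva_by_level)
    if missing:
        raise KeyError(f"no FVA result for schedule levels {sorted(missing)}")
    species = list(community.species)
    cases: List[TradeoffCaseResult] = []
    case_index = 0
    for f in sorted(schedule.cases):
        p_max = fva_by_level[f].p_max.reindex(species).to_numpy()
        for _ in range(schedule.cases[f]):
            seed = _case_seed(schedule.master_seed, case_index)
            rng = np.random.default_rng(seed)
            case = TradeoffCaseResult(
                case_id=case_index,
                f=f,
                seed=seed,
                r=np.array([]),
                p_upper=np.array([]),
                solution=None,
                accepted=False,
            )
            try:
                r, p_u = sample_bounds(p_max, rng)
                case.r, case.p_upper = r, p_u
                bounds = {s: (0.0, float(u)) for s, u in zip(species, p_u)}
                sol = maximize_community_growth(community, abundance_bounds=bounds)
                case.solution = sol
                case.growth_fraction = sol.mu / mu_max if mu_max > 0 else float("nan")
                if abs(sol.total_abundance - 1.0) > sum_tol:
                    case.note = "discarded: abundance sum outside tolerance"
                else:
                    case.accepted = True
                    case.metrics = diversity_metrics(sol.abundances.to_numpy())
                    fr, defined = _metrics.scfa_fractions(sol, community.policy.scfa_ids)
                    case.scfa_fractions = fr if defined else None
            except SamplingError as e:
                case.note = f"sampling failed: {e}"
            except InfeasibleError as e:
                case.note = f"LP failed: {e}"
            cases.append(case)
            case_index += 1
    return cases


def acceptance_rate(cases: Sequence[TradeoffCaseResult]) -> float:
    if not cases:
        return float("nan")
    return sum(c.accepted for c in cases) / len(cases)
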