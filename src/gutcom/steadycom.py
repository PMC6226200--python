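"""Steady-state community FBA with species-abundance variables.

The community model couples every species to a common specific growth rate
``mu`` (1/h) through abundance variables.  For species ``k`` with abundance
``p_k`` (fraction of total community biomass) and aggregate fluxes ``V^k``
(mmol/h per unit total community biomass) the feasibility problem at fixed
``mu`` is the linear program

.. code-block:: text

    max  sum_k p_k
    s.t. S^k V^k = 0                      per-species steady state
         l^k_j p_k <= V^k_j <= u^k_j p_k  bounds scale with abundance
         V^k_biomass = mu p_k             shared growth rate
         sum_k V^k_ex(m) - e_m = 0        lumen balance per metabolite m
         -U_m <= e_m <= cap               diet uptake / secretion cap
         lb_k <= p_k <= ub_k              abundance bounds

``mu`` is feasible for a unit community iff the optimum total abundance is
>= 1, and the maximal community growth rate is located by bisection on
``mu`` (the feasible set shrinks monotonically with ``mu``).  At the fixed
point the LP is re-solved with ``sum_k p_k = 1`` to extract a solution.
Because per-species bounds scale linearly with ``p_k``, a one-species
community reproduces the species' standalone FBA growth rate exactly.

All LPs are solved with HiGHS through :func:`scipy.optimize.linprog`
(deterministic, single-threaded); feasibility tolerances are tightened to
1e-9.  Degenerate optima (non-unique abundance splits) are returned as-is —
uniqueness is assessed by abundance variability analysis in
:mod:`gutcom.fva`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .community import CommunityModel, restrict_species
from .model import DietSpec, InfeasibleError, SpeciesModel

__all__ = [
    "CommunitySolution",
    "CommunityLP",
    "fba_single",
    "feasible_at_mu",
    "maximize_community_growth",
    "single_species_profile",
    "tune_atpm",
    "validate_solution",
    "assert_solution",
    "MU_TOL",
    "ABUNDANCE_SUM_TOL",
    "BALANCE_TOL",
]

#: bisection tolerance on the community growth rate (1/h)
MU_TOL = 1e-6
#: acceptance tolerance on |sum(p) - 1|
ABUNDANCE_SUM_TOL = 1e-4
#: tolerance on metabolite balance residuals
BALANCE_TOL = 1e-6

_HIGHS_OPTS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}


@dataclass
class CommunitySolution:
    """One community FBA solution.

    ``fluxes`` are aggregate per-species fluxes (mmol/h per unit total
    community biomass) indexed by qualified reaction id;
    ``exchange_fluxes`` are community exchange fluxes per lumen metabolite
    (positive = net community secretion).
    """

    mu: float
    abundances: pd.Series
    fluxes: pd.Series
    exchange_fluxes: pd.Series
    status: str = "optimal"
    objective: float = float("nan")

    @property
    def total_abundance(self) -> float:
        return float(self.abundances.sum())


class CommunityLP:
    """Sparse LP assembly for a :class:`~gutcom.community.CommunityModel`.

    Columns are ordered ``[V (species reactions) | e (community exchanges) |
    p (abundances)]``; the stoichiometric and coupling blocks are built once
    and reused across solves at different growth rates.
    """

    def __init__(self, community: CommunityModel):
        self.community = community
        self.species = list(community.species)

        self.reaction_cols: List[str] = []
        self.reaction_species: List[str] = []
        self._rxn_bounds: List[Tuple[float, float]] = []
        for sid in self.species:
            for r in community.reactions[sid]:
                self.reaction_cols.append(r.id)
                self.reaction_species.append(sid)
                self._rxn_bounds.append((r.lower_bound, r.upper_bound))
        self.n_v = len(self.reaction_cols)
        self.lumen = list(community.lumen_metabolites)
        self.n_e = len(self.lumen)
        self.n_p = len(self.species)
        self.n_cols = self.n_v + self.n_e + self.n_p

        col_of_rxn = {rid: j for j, rid in enumerate(self.reaction_cols)}
        col_of_met_ex = {m: self.n_v + i for i, m in enumerate(self.lumen)}
        self.col_of_p = {s: self.n_v + self.n_e + i for i, s in enumerate(self.species)}

        # metabolite rows: species-prefixed rows first, lumen rows last
        row_of_met: Dict[str, int] = {}
        rows, cols, vals = [], [], []
        for sid in self.species:
            for r in community.reactions[sid]:
                j = col_of_rxn[r.id]
                for met, coef in r.stoichiometry.items():
                    if met not in row_of_met:
                        row_of_met[met] = len(row_of_met)
                    rows.append(row_of_met[met])
                    cols.append(j)
                    vals.append(coef)
        for m in self.lumen:
            if m not in row_of_met:  # exchanged only via community (degenerate)
                row_of_met[m] = len(row_of_met)
            rows.append(row_of_met[m])
            cols.append(col_of_met_ex[m])
            vals.append(-1.0)
        self.row_of_met = row_of_met
        self.n_mets = len(row_of_met)
        self.S = sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_mets, self.n_cols)
        )
        self.lumen_rows = np.array([row_of_met[m] for m in self.lumen])

        # biomass coupling rows: V_bio_k - mu * p_k = 0
        bv_rows, bv_cols = [], []
        for i, sid in enumerate(self.species):
            bv_rows.append(i)
            bv_cols.append(col_of_rxn[community.biomass_reaction[sid]])
        self.B_v = sp.csr_matrix(
            (np.ones(self.n_p), (bv_rows, bv_cols)), shape=(self.n_p, self.n_cols)
        )
        self.P_sel = sp.csr_matrix(
            (
                np.ones(self.n_p),
                (np.arange(self.n_p), [self.col_of_p[s] for s in self.species]),
            ),
            shape=(self.n_p, self.n_cols),
        )
        self.total_row = self.P_sel.sum(axis=0)

        # coupling inequalities: V_j - ub_j p_k <= 0 ; -V_j + lb_j p_k <= 0
        c_rows, c_cols, c_vals = [], [], []
        for j, (sid, (lb, ub)) in enumerate(zip(self.reaction_species, self._rxn_bounds)):
            pc = self.col_of_p[sid]
            c_rows += [2 * j, 2 * j, 2 * j + 1, 2 * j + 1]
            c_cols += [j, pc, j, pc]
            c_vals += [1.0, -ub, -1.0, lb]
        self.A_ub = sp.csr_matrix(
            (c_vals, (c_rows, c_cols)), shape=(2 * self.n_v, self.n_cols)
        )
        self.b_ub = np.zeros(2 * self.n_v)

        self._e_bounds = [community.community_exchange_bounds[m] for m in self.lumen]

    # -- assembly --------------------------------------------------------

    def _bounds(self, abundance_bounds: Optional[Dict[str, Tuple[float, float]]]):
        merged = dict(self.community.abundance_bounds)
        if abundance_bounds:
            for sid, b in abundance_bounds.items():
                lo0, hi0 = merged[sid]
                merged[sid] = (max(lo0, b[0]), min(hi0, b[1]))
        out: List[Tuple[Optional[float], Optional[float]]] = [(None, None)] * self.n_v
        out += [(lo, hi) for lo, hi in self._e_bounds]
        out += [merged[s] for s in self.species]
        return out

    def solve(
        self,
        mu: float,
        *,
        objective: object = "total_abundance",
        fix_total: bool = False,
        abundance_bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    ):
        """Solve the community LP at growth rate ``mu``.

        ``objective`` is ``"total_abundance"`` (maximize sum of p),
        ``("abundance", species_id, sense)`` with sense +1 (maximize) or -1
        (minimize), or ``"none"`` (feasibility).  Returns a
        :class:`CommunitySolution` with ``status`` in
        {"optimal", "infeasible", "unbounded"}.
        """
        blocks = [self.S, self.B_v - mu * self.P_sel]
        b_eq = np.zeros(self.n_mets + self.n_p)
        if fix_total:
            blocks.append(sp.csr_matrix(self.total_row))
            b_eq = np.append(b_eq, 1.0)
        A_eq = sp.vstack(blocks, format="csr")

        c = np.zeros(self.n_cols)
        if objective == "total_abundance":
            c[self.n_v + self.n_e :] = -1.0
        elif objective == "none":
            pass
        else:
            kind, sid, sense = objective
            assert kind == "abundance"
            c[self.col_of_p[sid]] = -float(sense)

        res = linprog(
            c,
            A_ub=self.A_ub,
            b_ub=self.b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=self._bounds(abundance_bounds),
            method="highs",
            options=dict(_HIGHS_OPTS),
        )
        if res.status == 2:
            return CommunitySolution(
                mu, pd.Series(dtype=float), pd.Series(dtype=float), pd.Series(dtype=float),
                status="infeasible",
            )
        if res.status == 3:
            return CommunitySolution(
                mu, pd.Series(dtype=float), pd.Series(dtype=float), pd.Series(dtype=float),
                status="unbounded",
            )
        if res.status != 0:  # pragma: no cover - solver failure
            raise InfeasibleError(f"LP solver failure at mu={mu}: {res.message}")
        x = res.x
        return CommunitySolution(
            mu=mu,
            abundances=pd.Series(
                x[self.n_v + self.n_e :], index=self.species, dtype=float
            ),
            fluxes=pd.Series(x[: self.n_v], index=self.reaction_cols, dtype=float),
            exchange_fluxes=pd.Series(
                x[self.n_v : self.n_v + self.n_e], index=self.lumen, dtype=float
            ),
            status="optimal",
            objective=-float(res.fun),
        )


# ---------------------------------------------------------------------------
# single-species FBA


def _single_lp(
    reactions,
    bounds: Sequence[Tuple[float, float]],
    objective_rid: str,
) -> Tuple[float, pd.Series]:
    rids = [r.id for r in reactions]
    col = {rid: j for j, rid in enumerate(rids)}
    row_of_met: Dict[str, int] = {}
    rows, cols, vals = [], [], []
    for r in reactions:
        for met, coef in r.stoichiometry.items():
            row_of_met.setdefault(met, len(row_of_met))
            rows.append(row_of_met[met])
            cols.append(col[r.id])
            vals.append(coef)
    A_eq = sp.csr_matrix((vals, (rows, cols)), shape=(len(row_of_met), len(rids)))
    c = np.zeros(len(rids))
    c[col[objective_rid]] = -1.0
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(len(row_of_met)),
        bounds=list(bounds),
        method="highs",
        options=dict(_HIGHS_OPTS),
    )
    if res.status == 2:
        raise InfeasibleError("single-species LP infeasible (inconsistent model/diet/ATPM)")
    if res.status == 3:
        raise InfeasibleError("single-species LP unbounded (missing cap)")
    if res.status != 0:  # pragma: no cover
        raise InfeasibleError(f"LP solver failure: {res.message}")
    return -float(res.fun), pd.Series(res.x, index=rids, dtype=float)


def fba_single(
    model: SpeciesModel,
    diet: DietSpec,
    atpm_override: Optional[float] = None,
) -> Tuple[float, pd.Series]:
    """Standalone FBA: maximize biomass flux under the diet's uptake limits.

    Exchange uptake caps become ``min(model cap, diet rate)`` for dieted
    metabolites and 0 otherwise (no crossfeeding partner exists in a
    single-species context).  ``atpm_override`` replaces the ATPM lower
    bound, e.g. during maintenance tuning.  Raises
    :class:`~gutcom.model.InfeasibleError` when the LP is infeasible, which
    is distinct from an optimal growth rate of 0.
    """
    model.validate()
    diet.validate()
    ex_ids = set(model.exchange_reaction_ids)
    bounds = []
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if r.id in ex_ids:
            (met,) = r.stoichiometry
            cap = min(-lb, diet.max_uptake[met]) if met in diet.max_uptake else 0.0
            lb = -max(cap, 0.0)
        if atpm_override is not None and r.id == model.atpm_reaction_id:
            lb = float(atpm_override)
            ub = max(ub, lb)
        bounds.append((lb, ub))
    return _single_lp(model.reactions, bounds, model.biomass_reaction_id)


def _relaxed_single_growth(lp: CommunityLP, sid: str) -> float:
    """Max standalone growth of one species under its community bound templates.

    Lumen balance is dropped (supply limited only by the species' own caps),
    giving a cheap upper bracket for the community growth bisection.
    """
    community = lp.community
    reactions = community.reactions[sid]
    prefix = f"{sid}__"
    trimmed = []
    for r in reactions:
        stoich = {m: c for m, c in r.stoichiometry.items() if m.startswith(prefix)}
        trimmed.append(type(r)(r.id, stoich or {f"{prefix}_void": 0.0}, r.lower_bound, r.upper_bound))
    # reactions with empty trimmed stoichiometry (pure lumen movers) keep a
    # zero row so the column still exists
    try:
        mu, _ = _single_lp(
            trimmed,
            [(r.lower_bound, r.upper_bound) for r in reactions],
            community.biomass_reaction[sid],
        )
    except InfeasibleError:
        return 0.0
    return mu


# ---------------------------------------------------------------------------
# community growth


def feasible_at_mu(
    community: CommunityModel,
    mu: float,
    abundance_bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    lp: Optional[CommunityLP] = None,
) -> Tuple[float, CommunitySolution]:
    """Maximum total abundance achievable at growth rate ``mu``.

    ``mu`` is feasible for a unit community iff the returned total is >= 1.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    lp = lp or CommunityLP(community)
    sol = lp.solve(mu, objective="total_abundance", abundance_bounds=abundance_bounds)
    if sol.status == "unbounded":
        raise InfeasibleError(
            f"community LP unbounded at mu={mu}: missing secretion cap or abundance bound"
        )
    total = sol.objective if sol.status == "optimal" else -np.inf
    return total, sol


def maximize_community_growth(
    community: CommunityModel,
    abundance_bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    mu_tol: float = MU_TOL,
    max_iter: int = 60,
) -> CommunitySolution:
    """Largest community growth rate with total abundance 1, by bisection.

    The upper bracket starts from the best single-species growth under the
    crossfeed-relaxed bound templates and is doubled until infeasible; the
    bisection then closes to ``mu_tol`` and the LP is re-solved at the fixed
    point with ``sum(p) = 1`` to extract the solution.
    """
    lp = CommunityLP(community)
    feas = lambda m: feasible_at_mu(community, m, abundance_bounds, lp)[0] >= 1.0 - 1e-9

    if not feas(0.0):
        raise InfeasibleError(
            "community infeasible at mu=0: diet cannot support maintenance "
            "requirements of any unit community"
        )
    hi = max(max((_relaxed_single_growth(lp, s) for s in community.species), default=0.0), mu_tol)
    lo = 0.0
    for _ in range(60):
        if not feas(hi):
            break
        lo, hi = hi, hi * 2.0
        if hi > 1e6:  # pragma: no cover - defensive
            raise InfeasibleError("community growth appears unbounded")
    for _ in range(max_iter):
        if hi - lo <= mu_tol:
            break
        mid = 0.5 * (lo + hi)
        if feas(mid):
            lo = mid
        else:
            hi = mid

    for mu_final in (lo, lo * (1.0 - 1e-9), max(lo - mu_tol, 0.0)):
        sol = lp.solve(mu_final, objective="total_abundance", fix_total=True,
                       abundance_bounds=abundance_bounds)
        if sol.status == "optimal":
            return sol
    raise InfeasibleError(f"could not extract a solution at mu={lo}")  # pragma: no cover


def single_species_profile(
    community: CommunityModel,
    byproduct_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Growth rate and byproduct secretion of every species grown alone.

    Each species is restricted to a one-species community (all other
    abundances zero) and its maximal growth and net community exchange of
    the requested byproducts (mmol/h per unit biomass, secretion positive)
    are recorded.  LP failures are recorded per species without aborting.
    """
    if byproduct_ids is None:
        byproduct_ids = list(community.policy.scfa_ids)
    rows = []
    for sid in community.species:
        alone = restrict_species(community, {sid}, mode="hard")
        row: Dict[str, float] = {}
        try:
            sol = maximize_community_growth(alone)
            row["growth_rate"] = sol.mu
            for m in byproduct_ids:
                row[m] = float(sol.exchange_fluxes.get(m, 0.0))
            row["status"] = sol.status
        except InfeasibleError as e:
            row["growth_rate"] = float("nan")
            for m in byproduct_ids:
                row[m] = float("nan")
            row["status"] = f"error: {e}"
        rows.append(pd.Series(row, name=sid))
    return pd.DataFrame(rows)


def tune_atpm(
    model: SpeciesModel,
    diet: DietSpec,
    target_mu: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Tuple[float, bool]:
    """ATPM lower bound at which standalone growth equals ``target_mu``.

    Returns ``(atpm, attained)``.  If even ATPM = 0 cannot reach the target
    the pair ``(0.0, False)`` is returned (maintenance can only lower
    growth).  For ``target_mu = 0`` the result is the largest maintenance
    flux the diet can support with zero growth.  Growth is monotone
    non-increasing in ATPM, so a bisection suffices.
    """

    def growth(a: float) -> float:
        try:
            mu, _ = fba_single(model, diet, atpm_override=a)
        except InfeasibleError:
            return -np.inf
        return mu

    g0 = growth(0.0)
    if g0 < target_mu - tol:
        return 0.0, False
    lo, hi = 0.0, 1.0
    for _ in range(60):
        if growth(hi) < target_mu:
            break
        lo, hi = hi, hi * 2.0
    else:  # pragma: no cover - unbounded maintenance capacity
        return hi, False
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        g = growth(mid)
        if abs(g - target_mu) <= tol and g > -np.inf:
            return mid, True
        if g >= target_mu:
            lo = mid
        else:
            hi = mid
    a = lo
    return a, abs(growth(a) - target_mu) <= 10 * tol


# ---------------------------------------------------------------------------
# solution validation


def validate_solution(
    community: CommunityModel,
    sol: CommunitySolution,
    mu: Optional[float] = None,
    lp: Optional[CommunityLP] = None,
) -> Dict[str, float]:
    """Residuals of all conservation and coupling invariants of a solution.

    Keys: ``intracellular`` (||S V||_inf over species-internal rows),
    ``lumen`` (lumen balance vs community exchange), ``biomass``
    (|V_bio - mu p|_inf), ``abundance_sum`` (|sum p - 1|), ``p_negative``
    (most negative abundance, as a positive number), ``coupling`` (worst
    violation of the abundance-scaled flux bounds).
    """
    lp = lp or CommunityLP(community)
    mu = sol.mu if mu is None else mu
    x = np.zeros(lp.n_cols)
    x[: lp.n_v] = sol.fluxes.reindex(lp.reaction_cols).to_numpy()
    x[lp.n_v : lp.n_v + lp.n_e] = sol.exchange_fluxes.reindex(lp.lumen).to_numpy()
    p = sol.abundances.reindex(lp.species).to_numpy()
    x[lp.n_v + lp.n_e :] = p

    met_res = np.abs(lp.S @ x)
    lumen_mask = np.zeros(lp.n_mets, dtype=bool)
    lumen_mask[lp.lumen_rows] = True
    bio_res = np.abs((lp.B_v - mu * lp.P_sel) @ x)
    coupling = np.max(lp.A_ub @ x) if lp.n_v else 0.0
    return {
        "intracellular": float(met_res[~lumen_mask].max(initial=0.0)),
        "lumen": float(met_res[lumen_mask].max(initial=0.0)),
        "biomass": float(bio_res.max(initial=0.0)),
        "abundance_sum": float(abs(p.sum() - 1.0)),
        "p_negative": float(max(0.0, -p.min(initial=0.0))),
        "coupling": float(max(0.0, coupling)),
    }


def assert_solution(
    community: CommunityModel,
    sol: CommunitySolution,
    mu: Optional[float] = None,
    balance_tol: float = BALANCE_TOL,
    sum_tol: float = ABUNDANCE_SUM_TOL,
) -> Dict[str, float]:
    """Raise ``AssertionError`` if any solution invariant is violated."""
    res = validate_solution(community, sol, mu=mu)
    limits = {
        "intracellular": balance_tol,
        "lumen": balance_tol,
        "biomass": balance_tol,
        "abundance_sum": sum_tol,
        "p_negative": 1e-9,
        "coupling": balance_tol,
    }
    bad = {k: v for k, v in res.items() if v > limits[k]}
    if bad:
        raise AssertionError(f"solution invariants violated: {bad}")
    return res
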