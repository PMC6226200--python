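"""Brute-force oracles for community growth and abundance variability.

These scan the abundance simplex on a fixed grid and solve, at every grid
point, a *fixed-abundance* LP in which the abundance variables have been
eliminated into the flux bounds (``l_j p_k <= V_j <= u_j p_k`` becomes a box
on ``V_j``).  The assembly is deliberately separate from the
coupling-constraint formulation in :mod:`gutcom.steadycom`, and the LPs are
solved with GLPK (via swiglpk, warm-started across grid points) rather than
HiGHS, so the two routes share neither formulation nor solver; the oracles
are used as independent cross-checks in the tests and the acceptance
analysis, never as the implementation.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import swiglpk as glp

from .community import CommunityModel

__all__ = ["simplex_grid", "FixedAbundanceLP", "grid_max_growth", "grid_fva"]

glp.glp_term_out(glp.GLP_OFF)

_INF = 1e30


def simplex_grid(n: int, step: float = 0.01) -> Iterator[np.ndarray]:
    """All abundance vectors of length ``n`` on a ``step`` grid summing to 1."""
    k = int(round(1.0 / step))

    def rec(prefix: List[int], remaining: int, slots: int):
        if slots == 1:
            yield prefix + [remaining]
            return
        for v in range(remaining + 1):
            yield from rec(prefix + [v], remaining - v, slots - 1)

    for ints in rec([], k, n):
        yield np.array(ints, dtype=float) / k


def _set_col(lp, j: int, lo: float, hi: float) -> None:
    # 1-based GLPK column index
    if lo == hi:
        glp.glp_set_col_bnds(lp, j, glp.GLP_FX, lo, hi)
    elif lo <= -_INF and hi >= _INF:
        glp.glp_set_col_bnds(lp, j, glp.GLP_FR, 0.0, 0.0)
    elif hi >= _INF:
        glp.glp_set_col_bnds(lp, j, glp.GLP_LO, lo, 0.0)
    elif lo <= -_INF:
        glp.glp_set_col_bnds(lp, j, glp.GLP_UP, 0.0, hi)
    else:
        glp.glp_set_col_bnds(lp, j, glp.GLP_DB, lo, hi)


class FixedAbundanceLP:
    """GLPK LPs over fluxes and community exchanges at fixed abundances.

    One persistent problem per mode ("feasible": growth pinned through the
    biomass column bounds; "max_mu": growth as an extra variable entering
    the biomass balance rows with coefficient ``-p_k``), re-solved with a
    warm basis as the grid point changes.
    """

    def __init__(self, community: CommunityModel):
        self.community = community
        self.species = list(community.species)

        cols: List[str] = []
        col_species: List[int] = []
        lbs, ubs = [], []
        for i, sid in enumerate(self.species):
            for r in community.reactions[sid]:
                cols.append(r.id)
                col_species.append(i)
                lbs.append(r.lower_bound)
                ubs.append(r.upper_bound)
        self.n_v = len(cols)
        self.template_lb = np.array(lbs)
        self.template_ub = np.array(ubs)
        self.col_species = np.array(col_species)
        self.lumen = list(community.lumen_metabolites)
        self.n_e = len(self.lumen)
        self.e_bounds = [community.community_exchange_bounds[m] for m in self.lumen]

        col_of = {rid: j for j, rid in enumerate(cols)}
        self.bio_cols = np.array([col_of[community.biomass_reaction[s]] for s in self.species])

        row_of: Dict[str, int] = {}
        entries: List[Tuple[int, int, float]] = []  # (met row, col, coef)
        for sid in self.species:
            for r in community.reactions[sid]:
                j = col_of[r.id]
                for met, coef in r.stoichiometry.items():
                    row_of.setdefault(met, len(row_of))
                    entries.append((row_of[met], j, coef))
        for i, m in enumerate(self.lumen):
            row_of.setdefault(m, len(row_of))
            entries.append((row_of[m], self.n_v + i, -1.0))
        self.n_mets = len(row_of)
        self._entries = entries
        self._problems: Dict[str, object] = {}

    # -- problem construction -------------------------------------------

    def _build(self, mode: str):
        n_rows = self.n_mets + (len(self.species) if mode == "max_mu" else 0)
        n_cols = self.n_v + self.n_e + (1 if mode == "max_mu" else 0)
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, n_rows)
        glp.glp_add_cols(lp, n_cols)
        for i in range(1, n_rows + 1):
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)
        entries = list(self._entries)
        if mode == "max_mu":
            # biomass rows: V_bio_k - p_k * mu = 0; the mu column is
            # rewritten per grid point
            for k, bc in enumerate(self.bio_cols):
                entries.append((self.n_mets + k, int(bc), 1.0))
            glp.glp_set_obj_coef(lp, n_cols, 1.0)
            glp.glp_set_obj_dir(lp, glp.GLP_MAX)
            _set_col(lp, n_cols, 0.0, 1e4)
        nnz = len(entries)
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for idx, (i, j, v) in enumerate(entries, start=1):
            ia[idx] = i + 1
            ja[idx] = j + 1
            ar[idx] = v
        glp.glp_load_matrix(lp, nnz, ia, ja, ar)
        for i, (lo, hi) in enumerate(self.e_bounds):
            _set_col(lp, self.n_v + i + 1, lo, hi)
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        return lp, parm

    def _problem(self, mode: str):
        if mode not in self._problems:
            self._problems[mode] = self._build(mode)
        return self._problems[mode]

    def _apply_flux_bounds(self, lp, p: np.ndarray, skip=()) -> None:
        scale = p[self.col_species]
        lb = self.template_lb * scale
        ub = self.template_ub * scale
        for j in range(self.n_v):
            if j in skip:
                continue
            _set_col(lp, j + 1, lb[j], ub[j])

    # -- queries ---------------------------------------------------------

    def feasible(self, p: np.ndarray, mu: float, tol: float = 1e-9) -> bool:
        """Is growth rate ``mu`` supportable at the exact abundances ``p``?"""
        scale = p[self.col_species]
        tgt = mu * p
        blo = (self.template_lb * scale)[self.bio_cols]
        bhi = (self.template_ub * scale)[self.bio_cols]
        if np.any(tgt > bhi + tol) or np.any(tgt < blo - tol):
            return False
        lp, parm = self._problem("feasible")
        self._apply_flux_bounds(lp, p, skip=set(int(b) for b in self.bio_cols))
        for k, bc in enumerate(self.bio_cols):
            _set_col(lp, int(bc) + 1, tgt[k], tgt[k])
        if glp.glp_simplex(lp, parm) != 0:
            glp.glp_std_basis(lp)
            glp.glp_simplex(lp, parm)
        return glp.glp_get_status(lp) in (glp.GLP_OPT, glp.GLP_FEAS)

    def max_growth(self, p: np.ndarray) -> Optional[float]:
        """Largest ``mu`` supportable at fixed ``p`` (``None`` if infeasible)."""
        lp, parm = self._problem("max_mu")
        self._apply_flux_bounds(lp, p)
        mu_col = self.n_v + self.n_e + 1
        nz = [(self.n_mets + k + 1, -p[k]) for k in range(len(p))]
        ind = glp.intArray(len(nz) + 1)
        val = glp.doubleArray(len(nz) + 1)
        for idx, (i, v) in enumerate(nz, start=1):
            ind[idx] = i
            val[idx] = v
        glp.glp_set_mat_col(lp, mu_col, len(nz), ind, val)
        if glp.glp_simplex(lp, parm) != 0 or glp.glp_get_status(lp) not in (
            glp.GLP_OPT,
            glp.GLP_FEAS,
        ):
            # warm basis can go stale after bound/column edits; rebuild it
            glp.glp_std_basis(lp)
            glp.glp_simplex(lp, parm)
        if glp.glp_get_status(lp) != glp.GLP_OPT:
            return None
        return float(glp.glp_get_obj_val(lp))


def grid_max_growth(
    community: CommunityModel, step: float = 0.01
) -> Tuple[float, np.ndarray]:
    """Scan the abundance simplex; return the best growth rate and its grid point."""
    lp = FixedAbundanceLP(community)
    best, best_p = -np.inf, None
    for p in simplex_grid(len(community.species), step):
        mu = lp.max_growth(p)
        if mu is not None and mu > best:
            best, best_p = mu, p
    return best, best_p


def grid_fva(
    community: CommunityModel, mu: float, step: float = 0.01
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Per-species abundance min/max over feasible grid points at growth ``mu``.

    Returns ``(p_min, p_max, n_feasible)``; with no feasible grid point the
    ranges collapse to zero.
    """
    lp = FixedAbundanceLP(community)
    n = len(community.species)
    p_min = np.full(n, np.inf)
    p_max = np.full(n, -np.inf)
    count = 0
    for p in simplex_grid(n, step):
        if lp.feasible(p, mu):
            count += 1
            p_min = np.minimum(p_min, p)
            p_max = np.maximum(p_max, p)
    if count == 0:
        return np.zeros(n), np.zeros(n), 0
    return p_min, p_max, count
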