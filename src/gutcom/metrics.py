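"""Diversity, SCFA and crossfeeding metrics over community solutions.

Diversity uses the inverse Simpson equitability index

    D_com = (1/N) / sum_i p_i^2

which runs from 1/N (a single participating species) to 1 (all N species
equally abundant).  Richness counts species above an abundance threshold
(1% by default).  SCFA fractions divide each short-chain fatty acid's net
community synthesis rate by the summed synthesis of the tracked triple
(acetate, butyrate, propionate analogs).  Crossfeeding is summarized as a
species x metabolite matrix of aggregate exchange rates (mmol/h per unit
community biomass; uptake negative, secretion positive) whose column sums
equal the community exchange fluxes by lumen conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityModel
from .steadycom import CommunitySolution

__all__ = [
    "DiversityMetrics",
    "CrossfeedReport",
    "BinnedSummary",
    "equitability",
    "diversity_metrics",
    "scfa_fractions",
    "exchange_matrix",
    "crossfeed_report",
    "rank_crossfed",
    "bin_cases",
    "fit_tradeoff_line",
    "presence_fraction",
    "abundance_growth_correlation",
    "DEFAULT_BIN_CENTERS",
]

RICHNESS_THRESHOLD = 0.01

#: 15 growth-fraction bin centers, 0.71 .. 0.99, width 0.02
DEFAULT_BIN_CENTERS: Tuple[float, ...] = tuple(
    round(0.71 + 0.02 * k, 2) for k in range(15)
)


@dataclass
class DiversityMetrics:
    n_species: int
    d_com: float
    richness: int
    threshold: float = RICHNESS_THRESHOLD


@dataclass
class CrossfeedReport:
    """Species x crossfed-metabolite aggregate exchange rates and summaries."""

    matrix: pd.DataFrame  # species x metabolites, uptake negative
    mean_abs: pd.Series  # per metabolite, across all species (zeros included)
    std_abs: pd.Series
    net_secretion: pd.Series  # per metabolite = column sum

    @property
    def overall_std_abs(self) -> float:
        """Population std of |rate| over every (species, metabolite) entry."""
        return float(np.abs(self.matrix.to_numpy()).std())


@dataclass
class BinnedSummary:
    centers: Tuple[float, ...]
    width: float
    table: pd.DataFrame  # indexed by center: counts + mean/std columns
    n_out_of_range: int


def equitability(p: Sequence[float], sum_tol: float = 1e-4) -> float:
    """Inverse Simpson equitability of an abundance vector summing to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.all(p == 0):
        raise ValueError("equitability undefined for an all-zero abundance vector")
    if np.any(p < -1e-9):
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > sum_tol:
        raise ValueError(f"abundances must sum to 1 within {sum_tol}, got {total}")
    return float(1.0 / (len(p) * np.sum(p**2)))


def diversity_metrics(
    p: Union[pd.Series, Sequence[float]], threshold: float = RICHNESS_THRESHOLD
) -> DiversityMetrics:
    arr = np.asarray(p, dtype=float)
    return DiversityMetrics(
        n_species=arr.size,
        d_com=equitability(arr),
        richness=int((arr > threshold).sum()),
        threshold=threshold,
    )


def scfa_fractions(
    solution: CommunitySolution,
    scfa_ids: Sequence[str],
    tol: float = 1e-9,
) -> Tuple[Tuple[float, ...], bool]:
    """Fractional synthesis of each tracked SCFA.

    Each fraction is the net community secretion rate of that SCFA divided
    by the summed secretion of all tracked SCFAs.  Returns
    ``(fractions, defined)``; when no SCFA is produced the fractions are
    NaN and ``defined`` is False.  Net consumption of an SCFA (possible
    only if the uptake-blocking policy was violated) raises.
    """
    rates = np.array(
        [float(solution.exchange_fluxes.get(m, 0.0)) for m in scfa_ids]
    )
    if np.any(rates < -tol):
        bad = [m for m, r in zip(scfa_ids, rates) if r < -tol]
        raise ValueError(f"net community consumption of blocked SCFA(s) {bad}")
    rates = np.maximum(rates, 0.0)
    total = rates.sum()
    if total <= tol:
        return tuple(float("nan") for _ in scfa_ids), False
    return tuple(rates / total), True


def exchange_matrix(
    community: CommunityModel,
    solution: CommunitySolution,
    metabolite_ids: Sequence[str],
) -> pd.DataFrame:
    """Aggregate exchange rate of each species for each metabolite.

    Entry (k, m) is species k's lumen-exchange flux for m (secretion
    positive); species without an exchange reaction for m contribute 0.
    """
    data = np.zeros((len(community.species), len(metabolite_ids)))
    for i, sid in enumerate(community.species):
        ex = community.species_exchanges[sid]
        for j, m in enumerate(metabolite_ids):
            rid = ex.get(m)
            if rid is not None:
                data[i, j] = float(solution.fluxes.get(rid, 0.0))
    return pd.DataFrame(data, index=community.species, columns=list(metabolite_ids))


def crossfeed_report(
    community: CommunityModel,
    solutions: Union[CommunitySolution, Sequence[CommunitySolution]],
    crossfed_ids: Optional[Sequence[str]] = None,
) -> CrossfeedReport:
    """Exchange-rate summary for the crossfed metabolites.

    Multiple solutions (e.g. all cases in a growth-fraction bin) are
    averaged entrywise before the |rate| statistics, which include the zero
    entries of non-exchanging species.
    """
    if isinstance(solutions, CommunitySolution):
        solutions = [solutions]
    if not solutions:
        raise ValueError("need at least one solution")
    if crossfed_ids is None:
        crossfed_ids = list(community.policy.crossfed_ids)
    mats = [exchange_matrix(community, s, crossfed_ids) for s in solutions]
    avg = sum(mats[1:], start=mats[0]) / len(mats)
    absmat = avg.abs()
    return CrossfeedReport(
        matrix=avg,
        mean_abs=absmat.mean(axis=0),
        std_abs=absmat.std(axis=0, ddof=0),
        net_secretion=avg.sum(axis=0),
    )


def rank_crossfed(report: CrossfeedReport, k: Optional[int] = None) -> List[str]:
    """Top-k metabolites by total |exchange| across species; ties break lexically."""
    totals = report.matrix.abs().sum(axis=0)
    ranked = sorted(totals.index, key=lambda m: (-totals[m], m))
    return ranked[: (len(ranked) if k is None else k)]


def bin_cases(
    cases: pd.DataFrame,
    centers: Sequence[float] = DEFAULT_BIN_CENTERS,
    width: float = 0.02,
    value_columns: Optional[Sequence[str]] = None,
) -> BinnedSummary:
    """Collect accepted cases into half-open growth-fraction bins.

    ``cases`` must carry a ``growth_fraction`` column; bin ``c`` covers
    ``[c - width/2, c + width/2)``.  Cases outside every bin are counted in
    ``n_out_of_range``.  Per-bin mean and std (population) are reported for
    ``value_columns`` (default: every numeric column except the binning
    variable).
    """
    centers = tuple(centers)
    half = width / 2.0
    if value_columns is None:
        value_columns = [
            c
            for c in cases.columns
            if c != "growth_fraction" and pd.api.types.is_numeric_dtype(cases[c])
        ]
    frac = cases["growth_fraction"].to_numpy()
    edges = np.array([c - half for c in centers] + [centers[-1] + half])
    idx = np.digitize(frac, edges) - 1
    in_range = (idx >= 0) & (idx < len(centers))
    rows = []
    for b, center in enumerate(centers):
        sub = cases.loc[in_range & (idx == b)]
        row: Dict[str, float] = {"center": center, "count": len(sub)}
        for col in value_columns:
            vals = sub[col].to_numpy(dtype=float)
            row[f"mean_{col}"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"std_{col}"] = float(vals.std()) if len(vals) else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("center")
    return BinnedSummary(
        centers=centers,
        width=width,
        table=table,
        n_out_of_range=int((~in_range).sum()),
    )


def fit_tradeoff_line(
    cases: pd.DataFrame, max_fraction: float = 0.97
) -> Tuple[float, float, float]:
    """OLS fit of equitability on growth fraction below ``max_fraction``.

    Returns ``(slope, intercept, r_squared)``.  The growth-diversity
    tradeoff is near-linear away from the optimum, so the fit is restricted
    to growth fractions below the cutoff.
    """
    sub = cases[cases["growth_fraction"] < max_fraction]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 cases below growth fraction {max_fraction}")
    x = sub["growth_fraction"].to_numpy(dtype=float)
    y = sub["equitability"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all cases share one growth fraction")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def presence_fraction(
    cases: pd.DataFrame, threshold: float = RICHNESS_THRESHOLD
) -> pd.Series:
    """Fraction of accepted cases in which each species exceeds ``threshold``.

    Expects per-species abundance columns named ``p:<species_id>`` as
    written by the case table.
    """
    cols = [c for c in cases.columns if c.startswith("p:")]
    if not len(cases):
        raise ValueError("need at least one accepted case")
    out = {}
    for c in cols:
        out[c[2:]] = float((cases[c].to_numpy(dtype=float) > threshold).mean())
    return pd.Series(out)


def abundance_growth_correlation(
    abundances: Sequence[float],
    growth_rates: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Spearman rank correlation with a seeded permutation p-value.

    Rank correlation is robust to the many exactly-zero abundances of
    optimal communities.  The two-sided p-value counts permutations with
    |rho| at least as large as observed, with the +1 small-sample guard.
    """
    a = np.asarray(abundances, dtype=float)
    g = np.asarray(growth_rates, dtype=float)
    if a.size != g.size or a.size < 4:
        raise ValueError("need equal-length vectors with at least 4 entries")
    if np.ptp(a) == 0 or np.ptp(g) == 0:
        raise ValueError("correlation undefined for a constant vector")
    # Spearman rho is the Pearson correlation of the (tie-averaged) ranks;
    # the permutation null permutes one rank vector, vectorized below.
    ra = stats.rankdata(a) - (a.size + 1) / 2.0
    rg = stats.rankdata(g) - (g.size + 1) / 2.0
    denom = np.sqrt((ra**2).sum() * (rg**2).sum())
    rho = float(ra @ rg / denom)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(ra) for _ in range(n_permutations)])
    null = perms @ rg / denom
    count = int((np.abs(null) >= abs(rho) - 1e-12).sum())
    p = (count + 1) / (n_permutations + 1)
    return rho, float(p)
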