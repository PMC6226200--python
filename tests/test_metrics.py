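"""Diversity, SCFA, crossfeeding, binning and correlation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gutcom as g
from gutcom.metrics import (
    DEFAULT_BIN_CENTERS,
    abundance_growth_correlation,
    bin_cases,
    equitability,
    fit_tradeoff_line,
    presence_fraction,
    rank_crossfed,
    scfa_fractions,
)


def test_equitability_known_values():
    assert equitability([1.0] + [0.0] * 27) == pytest.approx(1 / 28)
    assert equitability(np.full(28, 1 / 28)) == pytest.approx(1.0)
    assert equitability([0.5, 0.3, 0.2]) == pytest.approx(0.8772, abs=5e-5)


def test_equitability_rejects_bad_input():
    with pytest.raises(ValueError):
        equitability([0.0, 0.0])
    with pytest.raises(ValueError):
        equitability([0.7, 0.7])  # sum far from 1


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_equitability_bounds(raw):
    p = np.asarray(raw)
    if p.sum() <= 0:
        return
    p = p / p.sum()
    d = equitability(p)
    assert 1.0 / len(p) - 1e-9 <= d <= 1.0 + 1e-9


def test_scfa_fractions_cases(toy3_opt):
    class Dummy:
        exchange_fluxes = pd.Series({"ac": 9.1, "but": 0.0, "ppa": 0.9})

    fr, defined = scfa_fractions(Dummy(), ("ac", "but", "ppa"))
    assert defined
    np.testing.assert_allclose(fr, (0.91, 0.0, 0.09))

    class Zero:
        exchange_fluxes = pd.Series({"ac": 0.0, "but": 0.0, "ppa": 0.0})

    fr, defined = scfa_fractions(Zero(), ("ac", "but", "ppa"))
    assert not defined and all(np.isnan(fr))

    class Equal:
        exchange_fluxes = pd.Series({"ac": 2.0, "but": 2.0, "ppa": 2.0})

    fr, defined = scfa_fractions(Equal(), ("ac", "but", "ppa"))
    np.testing.assert_allclose(fr, np.full(3, 1 / 3))

    class Bad:
        exchange_fluxes = pd.Series({"ac": 1.0, "but": -0.5, "ppa": 0.0})

    with pytest.raises(ValueError, match="blocked"):
        scfa_fractions(Bad(), ("ac", "but", "ppa"))


def test_crossfeed_report_single_species(demo8_community):
    com = g.restrict_species(demo8_community, {"specialist"}, mode="hard")
    sol = g.maximize_community_growth(com)
    rep = g.crossfeed_report(com, sol, crossfed_ids=["ac"])
    assert rep.matrix.shape == (1, 1)
    assert rep.matrix.iloc[0, 0] == pytest.approx(5.0, rel=1e-6)  # 10 * mu
    assert rep.std_abs["ac"] == pytest.approx(0.0, abs=1e-12)


def test_crossfeed_column_net_equals_community_exchange(demo8_community, demo8_campaign):
    _, cases = demo8_campaign
    accepted = [c for c in cases if c.accepted][:10]
    for c in accepted:
        rep = g.crossfeed_report(demo8_community, c.solution)
        for met in rep.net_secretion.index:
            assert rep.net_secretion[met] == pytest.approx(
                float(c.solution.exchange_fluxes[met]), abs=1e-6
            )


def test_rank_crossfed_ordering_and_ties():
    mat = pd.DataFrame(
        {"b": [3.0, -2.0], "a": [1.0, -1.0], "c": [4.0, 1.0]}, index=["s1", "s2"]
    )
    rep = g.CrossfeedReport(
        matrix=mat,
        mean_abs=mat.abs().mean(),
        std_abs=mat.abs().std(ddof=0),
        net_secretion=mat.sum(),
    )
    # totals: b = 5, c = 5, a = 2 -> tie between b and c broken lexically
    assert rank_crossfed(rep) == ["b", "c", "a"]
    assert rank_crossfed(rep, k=0) == []
    assert rank_crossfed(rep, k=1) == ["b"]


def test_toy3_top_crossfed_is_the_intermediate(toy3_community):
    sol = g.maximize_community_growth(
        toy3_community, abundance_bounds={"A": (0.0, 0.5)}
    )
    rep = g.crossfeed_report(toy3_community, sol)
    assert rank_crossfed(rep, k=1) == ["xm"]


def test_bin_edges_and_out_of_range():
    df = pd.DataFrame(
        {
            "growth_fraction": [0.79, 0.70, 0.699, 0.799999, 0.80, 1.0],
            "equitability": 1.0,
        }
    )
    b = bin_cases(df)
    assert b.table.loc[0.79, "count"] == 2  # 0.79 and 0.799999
    assert b.table.loc[0.81, "count"] == 1  # 0.80 joins the next half-open bin
    assert b.table.loc[0.71, "count"] == 1  # 0.70 is the first bin's left edge
    assert b.n_out_of_range == 2  # 0.699 below the first bin, 1.0 above the last
    assert b.table["count"].sum() + b.n_out_of_range == len(df)


def test_binned_means_permutation_invariant(demo8_campaign):
    _, cases = demo8_campaign
    df = g.io.cases_to_frame([c for c in cases if c.accepted])
    b1 = bin_cases(df, value_columns=["equitability", "richness"])
    b2 = bin_cases(
        df.sample(frac=1.0, random_state=0), value_columns=["equitability", "richness"]
    )
    pd.testing.assert_frame_equal(b1.table, b2.table)


def test_fit_tradeoff_line_degenerate_cases():
    x = np.linspace(0.6, 0.9, 10)
    df = pd.DataFrame({"growth_fraction": x, "equitability": 1.0 - x})
    slope, intercept, r2 = fit_tradeoff_line(df)
    assert slope == pytest.approx(-1.0) and r2 == pytest.approx(1.0)
    flat = pd.DataFrame({"growth_fraction": x, "equitability": 0.4})
    slope, _, _ = fit_tradeoff_line(flat)
    assert slope == pytest.approx(0.0, abs=1e-12)
    same_x = pd.DataFrame({"growth_fraction": [0.7] * 5, "equitability": np.arange(5.0)})
    with pytest.raises(ValueError, match="degenerate"):
        fit_tradeoff_line(same_x)


def test_presence_fraction(demo8_campaign):
    _, cases = demo8_campaign
    df = g.io.cases_to_frame([c for c in cases if c.accepted])
    frac = presence_fraction(df)
    assert ((frac >= 0.0) & (frac <= 1.0)).all()
    # the zero-growth maintainer cannot participate at campaign growth rates
    assert frac["maintainer"] == 0.0


def test_correlation_monotone_pairs():
    x = np.arange(10, dtype=float)
    rho, p = abundance_growth_correlation(x, x**2 + 1)
    assert rho == pytest.approx(1.0)
    assert p < 0.01
    rho, _ = abundance_growth_correlation(x, -x)
    assert rho == pytest.approx(-1.0)


def test_correlation_null_calibration():
    """Independent vectors (N = 28) stay non-significant in >= 95% of replicates."""
    rng = np.random.default_rng(7)
    n_sig = 0
    reps = 40
    for i in range(reps):
        a = rng.uniform(size=28)
        b = rng.uniform(size=28)
        _, p = abundance_growth_correlation(a, b, n_permutations=2000, seed=i)
        n_sig += p <= 0.05
    assert n_sig <= 0.05 * reps + 2
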