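"""Abundance variability analysis against closed forms and the grid oracle."""

import numpy as np
import pandas as pd
import pytest

import gutcom as g
from gutcom.fva import DEFAULT_F_GRID, classify_possible_essential, reduce_community


def test_toy3_fva_unique_at_optimum(toy3_community, toy3_opt):
    res = g.abundance_fva(toy3_community, 1.0, toy3_opt.mu)
    for sid, expect in zip(("A", "B", "C"), (1.0, 0.0, 0.0)):
        assert res.p_min[sid] == pytest.approx(expect, abs=1e-6)
        assert res.p_max[sid] == pytest.approx(expect, abs=1e-6)


def test_toy3_fva_suboptimal_closed_form(toy3_community, toy3_opt):
    # at mu = 0.3: B <= 0.75 * A from intermediate supply => p_max(B) = 3/7;
    # C alone sustains exactly 0.3 => p_max(C) = 1; every p_min is 0
    res = g.abundance_fva(toy3_community, 0.75, toy3_opt.mu)
    assert res.p_max["A"] == pytest.approx(1.0, abs=1e-6)
    assert res.p_max["B"] == pytest.approx(3.0 / 7.0, abs=1e-6)
    assert res.p_max["C"] == pytest.approx(1.0, abs=1e-6)
    assert res.p_min.abs().max() < 1e-6


def test_toy3_fva_with_abundance_cap(toy3_community):
    # capping A at 0.5 gives mu_max = 0.3; at that growth the B/C split is
    # non-unique with p_max(B) = 0.75 * 0.5 and p_min(C) = 1 - 0.5 - 0.375
    bounds = {"A": (0.0, 0.5)}
    mu = g.maximize_community_growth(toy3_community, abundance_bounds=bounds).mu
    res = g.abundance_fva(toy3_community, 1.0, mu, abundance_bounds=bounds)
    assert res.p_max["A"] == pytest.approx(0.5, abs=1e-6)
    assert res.p_max["B"] == pytest.approx(0.375, abs=1e-6)
    assert res.p_max["C"] == pytest.approx(1.0, abs=1e-6)
    assert res.p_min["C"] == pytest.approx(0.125, abs=1e-6)


def test_fva_solutions_satisfy_invariants_and_bracket_optimum(
    toy3_community, toy3_opt
):
    res = g.abundance_fva(toy3_community, 1.0, toy3_opt.mu)
    for sol in res.solutions.values():
        g.assert_solution(toy3_community, sol)
        d = g.equitability(sol.abundances.to_numpy())
        assert 1.0 / 3.0 - 1e-9 <= d <= 1.0 + 1e-9
    for sid in toy3_community.species:
        p = toy3_opt.abundances[sid]
        assert res.p_min[sid] - 1e-6 <= p <= res.p_max[sid] + 1e-6


def test_classification_definitions():
    res = g.FVAResult(
        f=0.8,
        mu=0.3,
        species=["a", "b", "c"],
        p_min=pd.Series({"a": 0.5, "b": 0.0, "c": 0.0}),
        p_max=pd.Series({"a": 0.9, "b": 0.02, "c": 0.005}),
    )
    n_pos, n_ess, flags = classify_possible_essential(res)
    assert (n_pos, n_ess) == (2, 1)
    assert flags.loc["a", "essential"] and flags.loc["b", "possible"]
    assert not flags.loc["c", "possible"]
    # essential implies possible
    assert not (flags["essential"] & ~flags["possible"]).any()


def test_threshold_is_strict():
    res = g.FVAResult(
        f=1.0,
        mu=0.1,
        species=["a"],
        p_min=pd.Series({"a": 0.01}),
        p_max=pd.Series({"a": 0.01}),
    )
    n_pos, n_ess, _ = classify_possible_essential(res)
    assert (n_pos, n_ess) == (0, 0)  # "exceed 1%" means strictly above


def test_coexistence_cutoffs_toy3(toy3_community, toy3_opt):
    grid = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    table = g.coexistence_cutoff(toy3_community, toy3_opt.mu, f_grid=grid)
    # A is possible at every fraction; B needs mu <= 0.3, i.e. f <= 0.75
    assert table.loc["A", "cutoff"] == 1.0
    assert table.loc["B", "cutoff"] == 0.7
    assert table.loc["C", "cutoff"] == 0.7
    assert table["monotone"].all()


def test_reduce_community_rules():
    cutoffs = {
        "west": pd.Series({"a": 1.0, "b": 0.65, "c": 0.72}),
        "fiber": pd.Series({"a": 0.9, "b": 0.60, "c": 0.60}),
    }
    retained = reduce_community(cutoffs, f_cut=0.70)
    assert retained == ["a", "c"]  # c retained by the at-least-one-diet rule
    assert reduce_community({"west": pd.Series({"a": 1.0, "b": 0.65})}) == ["a"]
    with pytest.raises(g.InfeasibleError):
        reduce_community({"west": pd.Series({"a": 0.1})}, f_cut=0.70)


def test_symmetric_community_is_fully_degenerate():
    # equal yields, no crossfeeding: any abundance split attains mu_max,
    # so FVA ranges collapse to [0, 1]
    spec = g.ToyCommunitySpec(
        species=[
            g.ToySpeciesSpec(f"s{i}", "glc", 10.0, 0.05, 0.0, {}) for i in range(3)
        ],
        diet={"glc": 10.0},
        crossfed_ids=(),
        scfa_ids=(),
    )
    models, diet, policy = g.make_toy_community(spec)
    com = g.build_community(models, diet, policy)
    sol = g.maximize_community_growth(com)
    assert sol.mu == pytest.approx(0.5, abs=1e-6)
    res = g.abundance_fva(com, 1.0, sol.mu)
    assert res.p_min.abs().max() < 1e-6
    assert (res.p_max > 1.0 - 1e-6).all()
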