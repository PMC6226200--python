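"""Community growth maximization, single-species FBA and maintenance tuning."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

import gutcom as g
from gutcom.steadycom import feasible_at_mu


def test_toy3_unconstrained_optimum(toy3_community, toy3_opt):
    # closed form: fastest species dominates, mu = yield * uptake = 0.04 * 10
    assert toy3_opt.mu == pytest.approx(0.4, abs=1e-6)
    assert toy3_opt.abundances["A"] == pytest.approx(1.0, abs=1e-6)
    assert toy3_opt.abundances[["B", "C"]].abs().max() < 1e-6
    g.assert_solution(toy3_community, toy3_opt)


def test_toy3_capped_optimum(toy3_community):
    # with A capped at 0.5 both B's crossfed uptake cap and C's transporter
    # cap bind at mu = 0.3; the B/C split is non-unique
    sol = g.maximize_community_growth(toy3_community, abundance_bounds={"A": (0.0, 0.5)})
    assert sol.mu == pytest.approx(0.3, abs=1e-6)
    assert sol.abundances["A"] <= 0.5 + 1e-9
    g.assert_solution(toy3_community, sol)


def test_fba_single_closed_forms(toy3):
    models, diet, _ = toy3
    mu_a, flux_a = g.fba_single(models[0], diet)
    assert mu_a == pytest.approx(0.4, abs=1e-9)  # 0.04 * 10
    mu_b, _ = g.fba_single(models[1], diet)
    assert mu_b == pytest.approx(0.0, abs=1e-9)  # obligate crossfeeder
    mu_c, _ = g.fba_single(models[2], diet)
    assert mu_c == pytest.approx(0.3, abs=1e-9)  # 0.06 * 5


def test_feasible_at_mu_bracket(toy3_community):
    total_low, _ = feasible_at_mu(toy3_community, 0.2)
    assert total_low >= 1.0 - 1e-9
    total_high, _ = feasible_at_mu(toy3_community, 0.5)
    assert total_high < 1.0
    # mu = 0 with no maintenance anywhere: any simplex point works
    total_zero, _ = feasible_at_mu(toy3_community, 0.0)
    assert total_zero >= 1.0 - 1e-9


def test_single_species_profile_toy3(toy3_community):
    prof = g.single_species_profile(toy3_community, byproduct_ids=["xm", "scfa_p"])
    assert list(prof.index) == ["A", "B", "C"]
    assert prof.loc["B", "growth_rate"] == pytest.approx(0.0, abs=1e-6)
    assert prof.loc["A", "growth_rate"] == pytest.approx(0.4, abs=1e-6)
    # A alone secretes its byproduct at 1 mmol per glc = 25 * mu mmol/h
    assert prof.loc["A", "xm"] == pytest.approx(25 * 0.4, rel=1e-6)
    # SCFA-analog secretion can never be negative (uptake blocked)
    assert (prof["scfa_p"].dropna() >= -1e-9).all()


def test_profile_secretion_equals_community_exchange(demo8_community):
    # lumen balance: for a 1-species community the species' exchange flux is
    # exactly the community exchange flux
    com = g.restrict_species(demo8_community, {"specialist"}, mode="hard")
    sol = g.maximize_community_growth(com)
    rid = com.species_exchanges["specialist"]["ac"]
    assert sol.fluxes[rid] == pytest.approx(sol.exchange_fluxes["ac"], abs=1e-9)


def test_tightening_abundance_bounds_never_increases_growth(toy3_community):
    mus = [
        g.maximize_community_growth(toy3_community, abundance_bounds=b).mu
        for b in (None, {"A": (0.0, 0.8)}, {"A": (0.0, 0.5)}, {"A": (0.0, 0.2)})
    ]
    assert all(a >= b - 1e-9 for a, b in zip(mus, mus[1:]))


def test_tune_atpm_fixed_point(toy3):
    models, diet, _ = toy3
    atpm, attained = g.tune_atpm(models[0], diet, target_mu=0.2)
    assert attained
    mu, _ = g.fba_single(models[0], diet, atpm_override=atpm)
    assert mu == pytest.approx(0.2, abs=1e-6)
    # closed form for the template: atpm = cap - target/yield = 10 - 0.2/0.04
    assert atpm == pytest.approx(5.0, abs=1e-4)


def test_tune_atpm_unattainable_target(toy3):
    models, diet, _ = toy3
    # C grows at most 0.3 < 0.5: maintenance cannot raise growth
    atpm, attained = g.tune_atpm(models[2], diet, target_mu=0.5)
    assert atpm == 0.0 and not attained


def test_tune_atpm_target_zero_is_max_maintenance(toy3):
    models, diet, _ = toy3
    atpm, attained = g.tune_atpm(models[0], diet, target_mu=0.0)
    assert attained
    # all supply goes to maintenance: atpm = uptake cap
    assert atpm == pytest.approx(10.0, abs=1e-4)
    mu, _ = g.fba_single(models[0], diet, atpm_override=atpm)
    assert mu == pytest.approx(0.0, abs=1e-6)


@settings(max_examples=8, deadline=None, derandomize=True,
          suppress_health_check=[HealthCheck.too_slow])
@given(seed=st.integers(0, 10_000), frac=st.floats(0.1, 0.9))
def test_feasibility_monotone_in_mu(seed, frac):
    """If mu2 > mu1 is feasible then mu1 is feasible (bisection validity)."""
    models, diet, policy = g.make_toy_community(g.random_toy_spec(4, 1, seed=seed))
    com = g.build_community(models, diet, policy)
    sol = g.maximize_community_growth(com)
    if sol.mu <= 1e-6:
        return
    mu2 = sol.mu * 0.95
    mu1 = mu2 * frac
    t2, _ = feasible_at_mu(com, mu2)
    t1, _ = feasible_at_mu(com, mu1)
    assert t2 >= 1.0 - 1e-9
    assert t1 >= t2 - 1e-9
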