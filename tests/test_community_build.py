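"""Community construction: namespaces, diet/crossfeed bounds, subsetting."""

import numpy as np
import pytest

import gutcom as g
from gutcom.model import ModelValidationError


def test_toy3_structure(toy3_community):
    com = toy3_community
    assert com.species == ["A", "B", "C"]
    # one community exchange per extracellular metabolite exchanged by >=1 species
    assert sorted(com.lumen_metabolites) == ["glc", "scfa_p", "xm"]
    assert set(com.community_exchange_bounds) == set(com.lumen_metabolites)
    # diet-driven community uptake: glc at 10, everything else 0
    assert com.community_exchange_bounds["glc"][0] == -10.0
    assert com.community_exchange_bounds["xm"][0] == 0.0
    for met, (lo, hi) in com.community_exchange_bounds.items():
        assert hi == com.secretion_cap


def test_intracellular_rows_touch_one_species_block(demo8_community):
    com = demo8_community
    owner = {}
    for sid in com.species:
        for r in com.reactions[sid]:
            for met in r.stoichiometry:
                if met in com.community_exchange_bounds:
                    continue
                assert owner.setdefault(met, sid) == sid, (
                    f"intracellular metabolite {met} coupled across species"
                )


def test_blocked_scfa_uptake_zero_secretion_unchanged(demo8_community):
    com = demo8_community
    for sid in com.species:
        ex = com.species_exchanges[sid]
        for met in com.policy.blocked_uptake_ids:
            if met in ex:
                rxn = next(r for r in com.reactions[sid] if r.id == ex[met])
                assert rxn.lower_bound == 0.0  # no uptake anywhere
                assert rxn.upper_bound > 0.0  # secretion still allowed


def test_crossfed_uptake_raised_to_policy_bound(demo8_community):
    com = demo8_community
    policy = com.policy
    for sid in com.species:
        for met, rid in com.species_exchanges[sid].items():
            rxn = next(r for r in com.reactions[sid] if r.id == rid)
            if met in policy.crossfed_ids:
                assert -rxn.lower_bound >= policy.crossfeed_uptake_bound


def test_species_model_caps_survive_diet(toy3_community):
    # C's own glucose transporter cap (5) is tighter than the diet (10)
    rid = toy3_community.species_exchanges["C"]["glc"]
    rxn = next(r for r in toy3_community.reactions["C"] if r.id == rid)
    assert rxn.lower_bound == -5.0


def test_single_species_community_matches_standalone_fba(toy3, demo8):
    for models, diet, policy in (toy3, demo8):
        for m in models:
            com1 = g.build_community([m], diet, policy, ignore_unused_diet=True)
            sol = g.maximize_community_growth(com1)
            mu_fba, _ = g.fba_single(m, diet)
            assert sol.mu == pytest.approx(mu_fba, abs=1e-6)


def test_restrict_soft_and_hard_agree(toy3_community):
    for keep in ({"A"}, {"A", "B"}, {"C"}):
        soft = g.restrict_species(toy3_community, keep, mode="soft")
        hard = g.restrict_species(toy3_community, keep, mode="hard")
        mu_soft = g.maximize_community_growth(soft).mu
        mu_hard = g.maximize_community_growth(hard).mu
        assert mu_soft == pytest.approx(mu_hard, abs=1e-9)


def test_restrict_keep_all_is_identity(toy3_community):
    same = g.restrict_species(toy3_community, set(toy3_community.species), mode="soft")
    assert same.abundance_bounds == toy3_community.abundance_bounds
    assert g.maximize_community_growth(same).mu == pytest.approx(0.4, abs=1e-6)


def test_restrict_to_single_species_equals_standalone(toy3_community, toy3):
    models, diet, _ = toy3
    only_a = g.restrict_species(toy3_community, {"A"}, mode="soft")
    mu = g.maximize_community_growth(only_a).mu
    assert mu == pytest.approx(g.fba_single(models[0], diet)[0], abs=1e-6)


def test_build_errors(toy3):
    models, diet, policy = toy3
    with pytest.raises(ModelValidationError, match="duplicate species"):
        g.build_community([models[0], models[0]], diet, policy)
    bad_diet = g.DietSpec("bad", {"unobtainium": 1.0})
    with pytest.raises(ModelValidationError, match="unobtainium"):
        g.build_community(models, bad_diet, policy)
    with pytest.raises(KeyError):
        g.restrict_species(g.build_community(models, diet, policy), {"Z"})


def test_crossfeed_relaxation_never_decreases_growth(demo8):
    models, diet, policy = demo8
    mus = []
    for bound in (0.0, 2.0, 10.0):
        p = policy.copy()
        p.crossfeed_uptake_bound = bound
        com = g.build_community(models, diet, p)
        mus.append(g.maximize_community_growth(com).mu)
    assert mus[0] <= mus[1] + 1e-9 <= mus[2] + 2e-9
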