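"""Model, diet and result serialization: round trips and validation errors."""

import numpy as np
import pandas as pd
import pytest

import gutcom as g
from gutcom.model import ModelValidationError, Reaction, SpeciesModel


def _assert_same_reactions(a, b, rel=1e-12):
    """Field-by-field reaction comparison; floats at serialization precision."""
    ra = {r.id: r for r in a.reactions}
    rb = {r.id: r for r in b.reactions}
    assert set(ra) == set(rb)
    for rid, x in ra.items():
        y = rb[rid]
        assert set(x.stoichiometry) == set(y.stoichiometry)
        for met, coef in x.stoichiometry.items():
            assert y.stoichiometry[met] == pytest.approx(coef, rel=rel)
        assert y.lower_bound == pytest.approx(x.lower_bound, rel=rel, abs=1e-12)
        assert y.upper_bound == pytest.approx(x.upper_bound, rel=rel, abs=1e-12)


def test_sbml_and_json_serialize_identically(tmp_path, toy3):
    models, _, _ = toy3
    for m in models:
        g.io.write_species_sbml(m, tmp_path / f"{m.species_id}.xml")
        g.io.write_species_json(m, tmp_path / f"{m.species_id}.json")
        sb = g.io.load_species_model(tmp_path / f"{m.species_id}.xml")
        js = g.io.load_species_model(tmp_path / f"{m.species_id}.json")
        for loaded in (sb, js):
            assert loaded.species_id == m.species_id
            assert sorted(loaded.metabolites) == sorted(m.metabolites)
            _assert_same_reactions(loaded, m)
            assert loaded.biomass_reaction_id == m.biomass_reaction_id
            assert loaded.atpm_reaction_id == m.atpm_reaction_id


def test_missing_biomass_reaction_names_detection_rule(tmp_path):
    model = SpeciesModel(
        "X",
        [("s", "e"), ("s_c", "c")],
        [
            Reaction("EX_s", {"s": -1.0}, -10.0, 1000.0),
            Reaction("TR_s", {"s": -1.0, "s_c": 1.0}, -1000.0, 1000.0),
            Reaction("ATPM", {"s_c": -1.0}, 0.0, 1000.0),
        ],
        "GROWTH",
        "ATPM",
    )
    with pytest.raises(ModelValidationError, match="biomass"):
        model.validate()
    # the SBML path reports the same rule when nothing matches the pattern
    path = tmp_path / "x.json"
    import json

    payload = {
        "species_id": "X",
        "metabolites": [{"id": "s", "compartment": "e"}],
        "reactions": [
            {"id": "EX_s", "stoichiometry": {"s": -1.0}, "lower_bound": -10.0, "upper_bound": 1000.0}
        ],
        "biomass_reaction_id": "GROWTH",
        "atpm_reaction_id": "ATPM",
    }
    path.write_text(json.dumps(payload))
    with pytest.raises(ModelValidationError, match="GROWTH"):
        g.io.load_species_model(path)


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda m: setattr(m.reactions[0], "lower_bound", 5000.0), "inverted bounds"),
        (lambda m: m.reactions[2].stoichiometry.update({"ghost": 1.0}), "undeclared"),
        (lambda m: setattr(m, "atpm_reaction_id", "GROWTH"), "distinct"),
    ],
)
def test_validation_rejects_broken_models(toy3, mutate, message):
    m = toy3[0][0].copy()
    mutate(m)
    with pytest.raises(ModelValidationError, match=message):
        m.validate()


def test_diet_round_trip_and_errors(tmp_path):
    diet = g.DietSpec("test", {"glc": 10.0, "o2": 0.0})
    g.io.write_diet(diet, tmp_path / "d.tsv")
    back = g.io.load_diet(tmp_path / "d.tsv", name="test")
    assert back.max_uptake == diet.max_uptake
    assert len(back.max_uptake) == 2

    (tmp_path / "neg.tsv").write_text("metabolite_id\tmax_uptake\nglc\t-1\n")
    with pytest.raises(ModelValidationError, match="negative"):
        g.io.load_diet(tmp_path / "neg.tsv")
    (tmp_path / "dup.tsv").write_text("metabolite_id\tmax_uptake\nglc\t1\nglc\t2\n")
    with pytest.raises(ModelValidationError, match="duplicate"):
        g.io.load_diet(tmp_path / "dup.tsv")
    (tmp_path / "bad.tsv").write_text("metabolite_id\tmax_uptake\nglc\tten\n")
    with pytest.raises(ModelValidationError, match="malformed"):
        g.io.load_diet(tmp_path / "bad.tsv")


def test_empty_diet_blocks_growth_when_maintenance_positive(toy3):
    models, _, _ = toy3
    empty = g.DietSpec("empty", {})
    mu, _ = g.fba_single(models[0], empty)
    assert mu == pytest.approx(0.0, abs=1e-9)
    drained = models[0].copy()
    with pytest.raises(g.InfeasibleError):
        g.fba_single(drained, empty, atpm_override=10.0)


def test_case_table_round_trip(demo8_campaign, tmp_path):
    _, cases = demo8_campaign
    df = g.io.write_case_table(cases, tmp_path / "cases.tsv")
    assert len(df) == len(cases)
    back = g.io.read_case_table(tmp_path / "cases.tsv")
    assert len(back) == len(cases)
    # float round trip is exact (values written at full precision)
    pd.testing.assert_series_equal(back["equitability"], df["equitability"])
    pd.testing.assert_series_equal(back["mu"], df["mu"])


def test_single_species_case_row_has_richness_one(toy3_community, toy3_opt):
    # the unconstrained toy3 optimum is a monoculture of species A
    dm = g.diversity_metrics(toy3_opt.abundances.to_numpy())
    assert dm.richness == 1
    assert dm.d_com == pytest.approx(1.0 / 3.0)


def test_metabolite_list_round_trip(tmp_path):
    ids = ["ac", "but", "ppa"]
    g.io.write_metabolite_list(ids, tmp_path / "m.tsv")
    assert g.io.load_metabolite_list(tmp_path / "m.tsv") == ids
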