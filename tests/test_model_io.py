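"""Model, atom-map and measurement IO: validation contracts and round trips."""

import json

import numpy as np
import pytest

from mfa2s import io as mio
from mfa2s import synthetic
from mfa2s.model import (
    AtomMap,
    AtomTransition,
    AtomTransitionTable,
    FeedSpec,
    LabelingDataset,
    MDVMeasurement,
    Metabolite,
    ModelValidationError,
    Reaction,
    StoichiometricModel,
)

TOY_JSON = {
    "id": "toy",
    "metabolites": [
        {"id": "a_c", "compartment": "c", "formula": "C3H4O3"},
        {"id": "b_c", "compartment": "c", "formula": "C3H4O3"},
        {"id": "c_c", "compartment": "c", "formula": "C2"},
    ],
    "reactions": [
        {"id": "R1", "metabolites": {"a_c": -1, "b_c": 1}, "lower_bound": 0, "upper_bound": 10},
        {"id": "R2", "metabolites": {"b_c": -1, "c_c": 1}, "lower_bound": -5, "upper_bound": 5},
    ],
    "genes": [],
}


def test_load_toy_json_shapes_and_bounds(tmp_path):
    p = tmp_path / "toy.json"
    p.write_text(json.dumps(TOY_JSON))
    model = mio.load_model(p, "cobra-json")
    assert model.S.shape == (3, 2)
    assert model.reaction("R1").lb == 0 and model.reaction("R1").ub == 10
    assert model.reaction("R2").reversible
    assert model.metabolite("a_c").n_carbons == 3
    assert model.metabolite("c_c").n_carbons == 2


def test_undeclared_metabolite_names_both_ids(tmp_path):
    bad = json.loads(json.dumps(TOY_JSON))
    bad["reactions"][0]["metabolites"]["ghost_c"] = 1
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(bad))
    with pytest.raises(ModelValidationError, match="R1.*ghost_c"):
        mio.load_model(p, "cobra-json")


@pytest.mark.parametrize("dialect", ["cobra-json", "sbml"])
def test_model_round_trip_preserves_stoichiometry(tmp_path, dialect, exemplary):
    path = tmp_path / ("m.json" if dialect == "cobra-json" else "m.xml")
    mio.write_model(exemplary.model, path, dialect)
    back = mio.load_model(path, dialect)
    assert back.reaction_ids == exemplary.model.reaction_ids
    for rid in exemplary.model.reaction_ids:
        a, b = exemplary.model.reaction(rid), back.reaction(rid)
        assert a.stoichiometry == b.stoichiometry
        assert np.isclose(a.lb, b.lb) and np.isclose(a.ub, b.ub)
    for m in exemplary.model.metabolites:
        assert back.metabolite(m.id).n_carbons == m.n_carbons


def test_atom_transitions_round_trip(tmp_path, exemplary):
    path = tmp_path / "trans.tsv"
    mio.write_atom_transitions(exemplary.transitions, path)
    back = mio.parse_atom_transitions(path, exemplary.model)
    assert set(back.reaction_ids()) == set(exemplary.transitions.reaction_ids())
    for rid in back.reaction_ids():
        assert back[rid].maps == exemplary.transitions[rid].maps


def test_identity_map_accepted(exemplary):
    tr = exemplary.transitions["R_BD"]
    assert tr.maps[0].reactants == (("B", "abc"),)
    assert tr.maps[0].products == (("D", "abc"),)


def _tiny_model():
    mets = [Metabolite("a", 3), Metabolite("b", 3)]
    return StoichiometricModel(mets, [Reaction("R", {"a": -1, "b": 1}, 0, 10)])


def test_product_letter_without_source_rejected():
    model = _tiny_model()
    t = AtomTransitionTable({"R": AtomTransition("R", [AtomMap((("a", "abc"),), (("b", "abz"),))])})
    with pytest.raises(ModelValidationError, match="no reactant source"):
        t.validate(model)


def test_letter_count_mismatch_rejected():
    model = _tiny_model()
    t = AtomTransitionTable({"R": AtomTransition("R", [AtomMap((("a", "ab"),), (("b", "ab"),))])})
    with pytest.raises(ModelValidationError, match="R"):
        t.validate(model)


def test_measurements_renormalized_and_rejected(tmp_path, exemplary):
    rows = ["metabolite_id,carbon_range,m,f_exp,delta"]
    for m, f in enumerate([0.51, 0.31, 0.2, 0.0]):  # sums to 1.02
        rows.append(f"C,all,{m},{f},0.01")
    p = tmp_path / "mdv.csv"
    p.write_text("\n".join(rows))
    ds = mio.load_measurements(p, exemplary.model)
    meas = ds.measurement("C")
    assert np.isclose(meas.f_exp.sum(), 1.0)
    assert np.isclose(meas.f_exp[0], 0.51 / 1.02)

    rows = ["metabolite_id,carbon_range,m,f_exp,delta"]
    for m, f in enumerate([0.6, 0.3, 0.2, 0.1]):  # sums to 1.2: beyond 5%
        rows.append(f"C,all,{m},{f},0.01")
    p2 = tmp_path / "mdv2.csv"
    p2.write_text("\n".join(rows))
    with pytest.raises(ModelValidationError, match="tolerance"):
        mio.load_measurements(p2, exemplary.model)


def test_growth_interval_stored_as_biomass_bounds(tmp_path, exemplary):
    mdv = tmp_path / "mdv.csv"
    rows = ["metabolite_id,carbon_range,m,f_exp,delta"]
    for m, f in enumerate([0.5, 0.3, 0.2, 0.0]):
        rows.append(f"C,all,{m},{f},0.01")
    mdv.write_text("\n".join(rows))
    ex = tmp_path / "flux.csv"
    ex.write_text("reaction_id,lb,ub\ngrowth,0.83,0.9\nupt,9.9,10.1\n")
    ds = mio.load_measurements(mdv, exemplary.model, ex)
    assert ds.growth_rate == (0.83, 0.9)
    assert ("upt", 9.9, 10.1) in ds.extracellular_measurements


def test_negative_delta_rejected():
    with pytest.raises(ModelValidationError, match="Delta"):
        MDVMeasurement("x", np.array([0.5, 0.5]), np.array([0.01, -0.01]))


def test_feed_validation_and_isotopomers():
    feed = FeedSpec("S", [("1100", 0.5), ("0000", 0.5)])
    dist = feed.isotopomer_distribution()
    assert np.isclose(dist[0b0011], 0.5) and np.isclose(dist[0], 0.5)
    with pytest.raises(ModelValidationError):
        FeedSpec("S", [("11", 0.5), ("00", 0.4)])
    with pytest.raises(ModelValidationError):
        FeedSpec("S", [("1a", 1.0)])


def test_feed_and_core_round_trip(tmp_path, exemplary):
    mio.write_feed(exemplary.feed, tmp_path / "feed.csv")
    feed = mio.load_feed(tmp_path / "feed.csv")
    assert feed.substrate_id == exemplary.feed.substrate_id
    assert feed.components == exemplary.feed.components
    mio.write_core_set(exemplary.core_reactions, tmp_path / "core.txt")
    assert mio.load_core_set(tmp_path / "core.txt") == exemplary.core_reactions


def test_scenario_bundle_save(tmp_path, exemplary):
    synthetic.save_scenario(exemplary, tmp_path / "bundle")
    for name in ["model.json", "transitions.tsv", "core.txt", "feed.csv",
                 "mdv.csv", "extracellular.csv", "truth.csv", "manifest.json"]:
        assert (tmp_path / "bundle" / name).exists()
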