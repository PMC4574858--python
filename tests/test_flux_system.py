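"""Split fluxes, the net mapping, and the LP layer (FBA/FVA)."""

import numpy as np
import pytest

from mfa2s import lp
from mfa2s.fluxes import SplitFluxVector, map_split_to_net, split_reversible
from mfa2s.model import Metabolite, Reaction, StoichiometricModel


def chain_model():
    mets = [
        Metabolite("s", 0, boundary=True),
        Metabolite("a", 0),
        Metabolite("bio", 0, boundary=True),
    ]
    rxns = [
        Reaction("upt", {"s": -1, "a": 1}, 0, 10),
        Reaction("grow", {"a": -1, "bio": 1}, 0, 500),
    ]
    return StoichiometricModel(mets, rxns, biomass_reaction="grow", substrate_uptake_reaction="upt")


def test_split_reversible_signs(exemplary):
    sys = split_reversible(exemplary.model, exemplary.core_reactions)
    assert sys.pairs["R_GE"] == ("R_GE_f", "R_GE_b")
    assert sys.pairs["R_BD"] == ("R_BD", None)
    S = exemplary.model.S
    Sstar = sys.S_star
    jf = sys.split_ids.index("R_GE_f")
    jb = sys.split_ids.index("R_GE_b")
    col = S[:, exemplary.model.rxn_index("R_GE")]
    assert np.allclose(Sstar[:, jf], col)
    assert np.allclose(Sstar[:, jb], -col)
    # irreversible column equals the S column
    jc = sys.split_ids.index("R_BD")
    assert np.allclose(Sstar[:, jc], S[:, exemplary.model.rxn_index("R_BD")])


def test_net_mapping_and_round_trip(exemplary, rng):
    sys = split_reversible(exemplary.model, exemplary.core_reactions)
    # v = glucupt * (V_f - V_b) for random nonnegative normalized values
    values = {lid: float(rng.uniform(0, 2)) for lid in sys.split_ids}
    V = SplitFluxVector(values, sys.glucupt)
    net = map_split_to_net(V, sys)
    for rid, (f, b) in sys.pairs.items():
        expected = sys.glucupt * (values[f] - (values[b] if b else 0.0))
        assert np.isclose(net[rid], expected)
    # pure exchange cancels
    V2 = SplitFluxVector({lid: 0.3 for lid in sys.split_ids}, sys.glucupt)
    net2 = map_split_to_net(V2, sys)
    assert np.isclose(net2["R_GE"], 0.0)
    assert np.isclose(net2["R_BD"], 0.3 * sys.glucupt)
    # absolute/normalized round trip
    back = SplitFluxVector.from_absolute(V.absolute(), sys.glucupt)
    for lid in sys.split_ids:
        assert np.isclose(back.values[lid], V.values[lid])


def test_split_net_consistency_with_S(exemplary, rng):
    """S v = S* u for any split assignment and its mapped net fluxes."""
    sys = split_reversible(exemplary.model, exemplary.core_reactions)
    values = {lid: float(rng.uniform(0, 3)) for lid in sys.split_ids}
    V = SplitFluxVector(values, sys.glucupt)
    net = map_split_to_net(V, sys)
    S = exemplary.model.S
    v = np.zeros(len(exemplary.model.reactions))
    for rid, x in net.items():
        v[exemplary.model.rxn_index(rid)] = x
    u = np.array([values[lid] * sys.glucupt for lid in sys.split_ids])
    assert np.abs(S @ v - sys.S_star @ u).max() < 1e-9


def test_missing_split_flux_errors(exemplary):
    sys = split_reversible(exemplary.model, exemplary.core_reactions)
    V = SplitFluxVector({"R_GE_f": 1.0}, sys.glucupt)
    with pytest.raises(KeyError):
        map_split_to_net(V, sys)


def test_fba_linear_chain():
    res = lp.fba(chain_model(), "grow", "max")
    assert res.feasible
    assert np.isclose(res.objective_value, 10.0)


def test_fba_infeasible_flag():
    m = chain_model()
    assert not lp.fba(m, "grow", extra_bounds={"upt": (12.0, 13.0)}).feasible


def test_fva_collapse_and_optimum_inside():
    m = chain_model()
    ivs = lp.fva(m, ["upt", "grow"], extra_bounds={"grow": (10, 10)})
    for iv in ivs:
        assert np.isclose(iv.v_min, 10) and np.isclose(iv.v_max, 10)
        assert iv.v_min <= iv.v_max
    opt = lp.fba(m, "grow", "max")
    iv = lp.fva(m, ["grow"])[0]
    assert iv.v_min - 1e-9 <= opt.objective_value <= iv.v_max + 1e-9


def test_fva_parallel_paths_degenerate():
    mets = [Metabolite("s", 0, boundary=True), Metabolite("a", 0), Metabolite("b", 0, boundary=True)]
    rxns = [
        Reaction("in", {"s": -1, "a": 1}, 10, 10),
        Reaction("p1", {"a": -1, "b": 1}, 0, 500),
        Reaction("p2", {"a": -1, "b": 1}, 0, 500),
    ]
    m = StoichiometricModel(mets, rxns)
    ivs = {iv.reaction_id: iv for iv in lp.fva(m, ["p1", "p2"])}
    for rid in ("p1", "p2"):
        assert np.isclose(ivs[rid].v_min, 0.0) and np.isclose(ivs[rid].v_max, 10.0)


def test_fva_futile_triangle_spans_bounds(futile_fit):
    scn, ds, (measured, limited, part, program, res) = futile_fit
    ivs = {iv.reaction_id: iv for iv in lp.fva(measured, ["NDPK1", "ADK1", "ADK2"])}
    for rid, iv in ivs.items():
        assert iv.v_min <= -499.99 and iv.v_max >= 499.99


def test_fba_matches_cobra_oracle(exemplary):
    """Independent LP oracle: the same toy solved through cobrapy."""
    cobra = pytest.importorskip("cobra")
    from mfa2s.io import _to_cobra

    model = exemplary.model.copy()
    model.reaction("upt").ub = 10.0
    # cobra balances every species: boundary species become one-sided
    # (exchange-style) reactions there
    for r in model.reactions:
        for mid in [m for m in r.stoichiometry if model.metabolite(m).boundary]:
            del r.stoichiometry[mid]
    cm = _to_cobra(model)
    cm.objective = "BIOMASS"
    sol = cm.optimize()
    ours = lp.fba(model, "BIOMASS", "max")
    assert ours.feasible
    assert np.isclose(sol.objective_value, ours.objective_value, atol=1e-6)


def test_dump_lp_contains_constraints(exemplary):
    text = lp.dump_lp(exemplary.model, "BIOMASS")
    assert "Maximize" in text and "BIOMASS" in text and "Bounds" in text
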