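"""EMU decomposition/simulation and its agreement with the isotopomer oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfa2s import synthetic
from mfa2s.emu import (
    EMUSimulationError,
    convolve,
    decompose,
    make_emu,
    mdv_from_isotopomers,
)
from mfa2s.model import AtomMap
from mfa2s.oracle import brute_force_oracle


def full_emus(carbons, mets):
    return [make_emu(m, tuple(range(1, carbons[m] + 1))) for m in mets]


@pytest.mark.parametrize(
    "mdvs,expected",
    [
        ([(1, 0), (1, 0)], (1, 0, 0)),
        ([(0, 1), (0, 1)], (0, 0, 1)),
        ([(0.5, 0.5), (0.5, 0.5)], (0.25, 0.5, 0.25)),
        ([(0.5, 0.5), (0.5, 0.5), (1.0, 0.0)], (0.25, 0.5, 0.25, 0.0)),
    ],
)
def test_convolve_known_cases(mdvs, expected):
    out = convolve([np.array(m, dtype=float) for m in mdvs])
    assert np.allclose(out, expected)


@given(
    st.lists(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
        min_size=1,
        max_size=3,
    )
)
@settings(max_examples=50, deadline=None)
def test_convolve_preserves_normalization(raw):
    mdvs = [np.array(v) / np.sum(v) for v in raw]
    out = convolve(mdvs)
    assert np.isclose(out.sum(), 1.0, atol=1e-9)
    assert len(out) == sum(len(m) - 1 for m in mdvs) + 1
    assert np.all(out >= -1e-12)


def test_marginal_mdv_from_isotopomers():
    dist = np.zeros(4)
    dist[0b01] = 0.25  # carbon 1 labeled
    dist[0b11] = 0.75
    assert np.allclose(mdv_from_isotopomers(dist, (1,), 2), [0, 1])
    assert np.allclose(mdv_from_isotopomers(dist, (2,), 2), [0.25, 0.75])
    assert np.allclose(mdv_from_isotopomers(dist, (1, 2), 2), [0, 0.25, 0.75])


def test_single_reaction_label_conservation():
    """S -> A with 100% [1-13C] feed on 3 carbons gives MDV (0,1,0,0)."""
    trans = {"r": [AtomMap((("S", "abc"),), (("A", "abc"),))]}
    carbons = {"S": 3, "A": 3}
    net = decompose(trans, full_emus(carbons, ["A"]), {"S": 3}, carbons)
    feed = np.zeros(8)
    feed[0b001] = 1.0
    mdv = net.simulate({"r": 5.0}, {"S": feed})
    assert np.allclose(mdv[make_emu("A", (1, 2, 3))], [0, 1, 0, 0])


def test_flux_weighted_mixing():
    """Two inflows with fluxes 3:1 mix their MDVs 0.75/0.25."""
    trans = {
        "r1": [AtomMap((("P", "ab"),), (("A", "ab"),))],
        "r2": [AtomMap((("Q", "ab"),), (("A", "ab"),))],
    }
    carbons = {"P": 2, "Q": 2, "A": 2}
    net = decompose(trans, full_emus(carbons, ["A"]), {"P": 2, "Q": 2}, carbons)
    p = np.zeros(4); p[0b11] = 1.0  # fully labeled
    q = np.zeros(4); q[0] = 1.0  # unlabeled
    mdv = net.simulate({"r1": 3.0, "r2": 1.0}, {"P": p, "Q": q})
    assert np.allclose(mdv[make_emu("A", (1, 2))], [0.25, 0.0, 0.75])


def test_unreachable_measured_emu_errors():
    trans = {"r": [AtomMap((("S", "ab"),), (("A", "ab"),))]}
    carbons = {"S": 2, "A": 2, "Z": 2}
    with pytest.raises(EMUSimulationError, match="Z"):
        decompose(trans, full_emus(carbons, ["Z"]), {"S": 2}, carbons)


def test_zero_production_is_singular():
    trans = {
        "r": [AtomMap((("S", "ab"),), (("A", "ab"),))],
        "r2": [AtomMap((("A", "ab"),), (("B", "ab"),))],
    }
    carbons = {"S": 2, "A": 2, "B": 2}
    net = decompose(trans, full_emus(carbons, ["B"]), {"S": 2}, carbons)
    feed = np.zeros(4); feed[0] = 1.0
    with pytest.raises(EMUSimulationError, match="zero tracked production"):
        net.simulate({"r": 0.0, "r2": 1.0}, {"S": feed})


def _random_feed(rng, n):
    d = rng.dirichlet(np.ones(2**n))
    return d


@pytest.mark.parametrize("case", synthetic.oracle_validation_cases(), ids=lambda c: c["name"])
def test_emu_matches_isotopomer_oracle(case, rng):
    """On every fixture network, 100 random flux draws agree with the
    exhaustive isotopomer oracle to 1e-8."""
    carbons = case["carbons"]
    tracked = sorted(
        {mid for maps in case["transitions"].values() for am in maps for mid, _ in am.products}
    )
    emus = full_emus(carbons, tracked)
    net = decompose(case["transitions"], emus, {case["feed"]: carbons[case["feed"]]}, carbons)
    worst = 0.0
    for _ in range(100):
        fluxes = case["sample_fluxes"](rng)
        feed = _random_feed(rng, carbons[case["feed"]])
        mdv = net.simulate(fluxes, {case["feed"]: feed})
        oracle = brute_force_oracle(case["transitions"], fluxes, {case["feed"]: feed}, carbons)
        for e in emus:
            worst = max(worst, np.abs(mdv[e] - oracle[e.metabolite]).max())
    assert worst <= 1e-8


def test_symmetric_molecule_averages_orientations(rng):
    """A symmetric intermediate's MDV equals the average over both carbon
    orientations (checked against the oracle with an asymmetric feed)."""
    case = [c for c in synthetic.oracle_validation_cases() if c["name"] == "symmetric"][0]
    carbons = case["carbons"]
    net = decompose(
        case["transitions"], full_emus(carbons, ["Q"]), {"S": 2}, carbons
    )
    feed = np.zeros(4); feed[0b01] = 1.0  # [1-13C] only
    mdv = net.simulate({"upt": 1.0, "R_sym": 1.0, "R_out": 1.0}, {"S": feed})
    oracle = brute_force_oracle(
        case["transitions"], {"upt": 1.0, "R_sym": 1.0, "R_out": 1.0}, {"S": feed}, carbons
    )
    assert np.allclose(mdv[make_emu("Q", (1, 2))], oracle["Q"], atol=1e-10)
    # single-position marginals are symmetrized: each carries half the label
    assert np.allclose(
        net.simulate({"upt": 1, "R_sym": 1, "R_out": 1}, {"S": feed})[make_emu("Q", (1, 2))],
        [0, 1, 0],
    )


def test_unlabeled_feed_invariance(exemplary):
    """With an unlabeled feed every simulated MDV is (1, 0, ..., 0)."""
    from mfa2s.fluxes import split_reversible

    sys = split_reversible(exemplary.model, exemplary.core_reactions + ["R_FDM"])
    trans = sys.split_transitions(exemplary.transitions)
    carbons = {m.id: m.n_carbons for m in exemplary.model.metabolites}
    net = decompose(trans, full_emus(carbons, ["A", "C", "E"]), {"S_e": 4}, carbons)
    feed = np.zeros(16); feed[0] = 1.0
    mdv = net.simulate(exemplary.true_split_fluxes(), {"S_e": feed})
    for e, v in mdv.items():
        expected = np.zeros(e.size + 1); expected[0] = 1.0
        assert np.allclose(v, expected, atol=1e-10)


def test_flux_scaling_invariance(exemplary):
    """MDVs are unchanged when all split fluxes are scaled by c > 0."""
    from mfa2s.fluxes import split_reversible

    sys = split_reversible(exemplary.model, exemplary.core_reactions + ["R_FDM"])
    trans = sys.split_transitions(exemplary.transitions)
    carbons = {m.id: m.n_carbons for m in exemplary.model.metabolites}
    net = decompose(trans, full_emus(carbons, ["A", "C", "E"]), {"S_e": 4}, carbons)
    iso = exemplary.feed.isotopomer_distribution()
    base = exemplary.true_split_fluxes()
    m1 = net.simulate(base, {"S_e": iso})
    m2 = net.simulate({k: 7.3 * v for k, v in base.items()}, {"S_e": iso})
    for e in m1:
        assert np.allclose(m1[e], m2[e], atol=1e-10)


def test_simulated_mdvs_normalized(exemplary, rng):
    """Every simulated MDV sums to 1 within 1e-9 under random fluxes."""
    from mfa2s.fluxes import split_reversible

    sys = split_reversible(exemplary.model, exemplary.core_reactions + ["R_FDM"])
    trans = sys.split_transitions(exemplary.transitions)
    carbons = {m.id: m.n_carbons for m in exemplary.model.metabolites}
    net = decompose(trans, full_emus(carbons, ["A", "C", "E"]), {"S_e": 4}, carbons)
    iso = exemplary.feed.isotopomer_distribution()
    base = exemplary.true_split_fluxes()
    for _ in range(20):
        fluxes = {k: v * float(rng.uniform(0.2, 3.0)) for k, v in base.items()}
        mdv = net.simulate(fluxes, {"S_e": iso})
        for v in mdv.values():
            assert abs(v.sum() - 1.0) < 1e-9


def test_dot_export_mentions_emus(exemplary):
    from mfa2s.fluxes import split_reversible

    sys = split_reversible(exemplary.model, exemplary.core_reactions)
    trans = sys.split_transitions(exemplary.transitions)
    carbons = {m.id: m.n_carbons for m in exemplary.model.metabolites}
    net = decompose(trans, full_emus(carbons, ["C"]), {"S_e": 4}, carbons)
    dot = net.to_dot()
    assert dot.startswith("digraph") and "C_123" in dot


def test_oracle_refuses_oversized_state_space():
    trans = {"r": [AtomMap((("S", "abc"),), (("A", "abc"),))]}
    with pytest.raises(EMUSimulationError, match="cap"):
        brute_force_oracle(trans, {"r": 1.0}, {"S": np.ones(8) / 8}, {"S": 3, "A": 3}, state_cap=4)
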