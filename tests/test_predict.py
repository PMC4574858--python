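"""Knockout flux and labeling prediction (FBA / MOMA / ROOM and the
13C-referenced variants)."""

import numpy as np
import pytest

from mfa2s import lp, synthetic
from mfa2s import predict as P
from tests.conftest import fitted_bundle


@pytest.fixture(scope="module")
def ko_bundle():
    scn = synthetic.knockout_pair_scenario()
    wt_ds = synthetic.generate_dataset(scn, noise_sd=0.01, seed=7)
    measured, limited, part, program, wt_fit = fitted_bundle(scn, wt_ds, n_restarts=4)
    full_model = scn.model.copy()
    r = full_model.reaction("upt")
    r.lb, r.ub = 9.9, 10.1  # substrate bound carried from the reference run
    ko_model = P.knockout(full_model, ["R1"])
    true_ko = P.predict_fluxes(
        ko_model, "moma", P.ReferenceProfile(scn.true_fluxes, "fba")
    ).fluxes
    ko_ds = synthetic.generate_dataset(scn, noise_sd=0.01, seed=8, true_fluxes=true_ko)
    return scn, part, wt_fit, full_model, ko_model, true_ko, ko_ds


def test_knockout_zeroes_bounds(ko_bundle):
    scn, part, wt_fit, full_model, ko_model, *_ = ko_bundle
    r = ko_model.reaction("R1")
    assert r.lb == 0.0 and r.ub == 0.0
    # knocking out an already-zero reaction is a no-op
    again = P.knockout(ko_model, ["R1"])
    assert again.reaction("R1").lb == 0.0 and again.reaction("R1").ub == 0.0
    with pytest.raises(KeyError):
        P.knockout(full_model, ["no-such-gene"])


def test_knockout_propagates_through_solves(ko_bundle):
    scn, part, wt_fit, full_model, ko_model, *_ = ko_bundle
    for method, ref in [
        ("fba-growth", None),
        ("moma", P.ReferenceProfile(scn.true_fluxes, "fba")),
    ]:
        pred = P.predict_fluxes(ko_model, method, ref)
        assert pred.fluxes["R1"] == pytest.approx(0.0, abs=1e-9)


def test_moma_returns_reference_when_feasible(ko_bundle):
    """Knocking out a zero-flux reaction leaves MOMA at distance 0."""
    scn, *_ = ko_bundle
    m = scn.model.copy()
    m.reaction("upt").lb, m.reaction("upt").ub = 9.9, 10.1
    ref = dict(scn.true_fluxes)
    ref["R3"] = 0.0
    ref["R2"] = 3.0  # keep steady state: upt = R1 + 2(R2+R3)
    ref["upt"] = ref["R1"] + 2 * (ref["R2"] + ref["R3"])
    ref["R_W4X"] = ref["R2"]
    ref["R_Bbio"] = ref["R1"] + ref["R2"]
    ko = P.knockout(m, ["R3"])
    pred = P.predict_fluxes(ko, "moma", P.ReferenceProfile(ref, "fba"))
    for rid, v in ref.items():
        assert pred.fluxes[rid] == pytest.approx(v, abs=1e-4)
    assert pred.objective_value == pytest.approx(0.0, abs=1e-6)


def test_predictions_satisfy_stoichiometry_and_ko_bounds(ko_bundle):
    scn, part, wt_fit, full_model, ko_model, *_ = ko_bundle
    A, _ = ko_model.balance_matrix()
    ids = ko_model.reaction_ids
    refs = {
        "moma": P.ReferenceProfile(lp.fba(full_model, "R_Bbio", "max").fluxes, "fba"),
        "13c-moma": P.ReferenceProfile(wt_fit.fluxes, "2s13c-fit"),
        "room": P.ReferenceProfile(lp.fba(full_model, "R_Bbio", "max").fluxes, "fba"),
    }
    results = {}
    for method, ref in refs.items():
        pred = P.predict_fluxes(ko_model, method, ref)
        v = np.array([pred.fluxes[r] for r in ids])
        assert np.abs(A @ v).max() < 1e-6
        assert pred.fluxes["R1"] == pytest.approx(0.0, abs=1e-9)
        results[method] = pred
    # different references give different adjustment predictions
    assert abs(results["moma"].fluxes["R2"] - results["13c-moma"].fluxes["R2"]) > 0.1


def test_reference_provenance_enforced(ko_bundle):
    scn, part, wt_fit, full_model, ko_model, *_ = ko_bundle
    fba_ref = P.ReferenceProfile(lp.fba(full_model, "R_Bbio", "max").fluxes, "fba")
    with pytest.raises(ValueError, match="2s13c-fit"):
        P.predict_fluxes(ko_model, "13c-moma", fba_ref)
    with pytest.raises(ValueError, match="reference"):
        P.predict_fluxes(ko_model, "moma", None)


def test_partial_mode_respects_target_bounds(ko_bundle):
    scn, part, wt_fit, full_model, ko_model, true_ko, ko_ds = ko_bundle
    mu = true_ko["R_Bbio"]
    pred = P.predict_fluxes(
        ko_model, "fba-growth", mode="partial",
        partial_bounds={"R_Bbio": (0.99 * mu, 1.01 * mu)},
    )
    assert 0.99 * mu - 1e-9 <= pred.fluxes["R_Bbio"] <= 1.01 * mu + 1e-9
    assert pred.partial_bounds == {"R_Bbio": (0.99 * mu, 1.01 * mu)}
    with pytest.raises(ValueError):
        P.predict_fluxes(ko_model, "fba-growth", mode="full", partial_bounds={"R_Bbio": (1, 2)})


def test_fba_atp_needs_objective_and_maximizes(ko_bundle):
    scn, part, wt_fit, full_model, *_ = ko_bundle
    with pytest.raises(ValueError):
        P.predict_fluxes(full_model, "fba-atp")
    pred = P.predict_fluxes(full_model, "fba-atp", atp_reaction="R_W1X")
    best = lp.fba(full_model, "R_W1X", "max").objective_value
    assert pred.fluxes["R_W1X"] == pytest.approx(best, abs=1e-6)


def test_labeling_prediction_identity_and_unlabeled(ko_bundle):
    scn, part, wt_fit, full_model, ko_model, true_ko, ko_ds = ko_bundle
    # prediction equal to the dataset's own generating fluxes scores the
    # same OF as direct simulation of those fluxes
    pred = P.PredictionResult(method="identity", fluxes=dict(true_ko))
    pred = P.predict_labeling(pred, scn.model, part, scn.transitions, scn.feed, ko_ds)
    assert pred.of < 3.0  # consistent with the noise level
    for m in pred.mdvs:
        assert np.isclose(np.sum(m), 1.0, atol=1e-9)
    # unlabeled feed: every predicted MDV collapses to (1, 0, ..., 0)
    from mfa2s.model import FeedSpec

    unl = FeedSpec("S_e", [("000", 1.0)])
    pred2 = P.PredictionResult(method="identity", fluxes=dict(true_ko))
    pred2 = P.predict_labeling(pred2, scn.model, part, scn.transitions, unl, ko_ds)
    for m in pred2.mdvs:
        assert np.isclose(m[0], 1.0, atol=1e-9)
    assert pred2.of is not None


def test_13c_moma_beats_plain_moma_on_labeling(ko_bundle):
    """The non-FBA-optimal wild type: referencing the 13C fit predicts the
    knockout labeling better than referencing FBA."""
    scn, part, wt_fit, full_model, ko_model, true_ko, ko_ds = ko_bundle
    fba_ref = P.ReferenceProfile(lp.fba(full_model, "R_Bbio", "max").fluxes, "fba")
    moma = P.predict_fluxes(ko_model, "moma", fba_ref)
    c13 = P.predict_fluxes(ko_model, "13c-moma", P.ReferenceProfile(wt_fit.fluxes, "2s13c-fit"))
    moma = P.predict_labeling(moma, scn.model, part, scn.transitions, scn.feed, ko_ds)
    c13 = P.predict_labeling(c13, scn.model, part, scn.transitions, scn.feed, ko_ds)
    assert c13.of < moma.of


def test_room_counts_changes_and_respects_gap(ko_bundle):
    scn, part, wt_fit, full_model, ko_model, *_ = ko_bundle
    ref = P.ReferenceProfile(wt_fit.fluxes, "2s13c-fit")
    pred = P.predict_fluxes(ko_model, "13c-room", ref)
    assert pred.gap is not None and pred.gap <= 1e-4
    # minimum possible change count here is 5: the knockout and its waste
    # drain are forced to zero, growth and the four-carbon waste follow,
    # and one of the two remaining routes must absorb the flux
    changed = 0
    for rid, v in pred.fluxes.items():
        w = ref.fluxes.get(rid, 0.0)
        lo = w - P.ROOM_DELTA * abs(w) - P.ROOM_EPSILON
        hi = w + P.ROOM_DELTA * abs(w) + P.ROOM_EPSILON
        changed += not (lo - 1e-6 <= v <= hi + 1e-6)
    assert changed == 5
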