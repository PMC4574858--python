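"""Synthetic scenario generators: validity, determinism, perturbations."""

import numpy as np
import pytest

from mfa2s import synthetic
from mfa2s.model import ModelValidationError


@pytest.mark.parametrize(
    "factory",
    [
        synthetic.exemplary_network,
        lambda: synthetic.recovery_scenario(0),
        synthetic.futile_cycle_scenario,
        synthetic.knockout_pair_scenario,
    ],
    ids=["exemplary", "recovery", "futile", "kopair"],
)
def test_scenarios_pass_all_validators(factory):
    scn = factory()
    scn.transitions.validate(scn.model)  # atom maps consistent with model
    A, _ = scn.model.balance_matrix()
    v = np.array([scn.true_fluxes[r] for r in scn.model.reaction_ids])
    assert np.abs(A @ v).max() < 1e-9
    lb, ub = scn.model.bounds_array()
    assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)
    for lid, u in scn.true_split_fluxes().items():
        assert u >= 0


def test_exemplary_matches_its_storyline(exemplary):
    assert len(exemplary.model.reactions) == 20
    assert exemplary.measured_metabolites == ["A", "C", "E"]
    assert "R_FDM" not in exemplary.core_reactions  # initially non-core
    assert "R_FDM" in exemplary.transitions  # map available for expansion
    # M is essential for growth and only produced by R_FDM
    producers = [
        r.id for r in exemplary.model.reactions if r.stoichiometry.get("M", 0) > 0
    ]
    assert producers == ["R_FDM"]
    assert exemplary.model.reaction("BIOMASS").stoichiometry["M"] < 0


def test_generated_dataset_is_deterministic_and_noise_controlled():
    scn = synthetic.recovery_scenario(1)
    a = synthetic.generate_dataset(scn, noise_sd=0.01, seed=9)
    b = synthetic.generate_dataset(scn, noise_sd=0.01, seed=9)
    for x, y in zip(a.mdv_measurements, b.mdv_measurements):
        assert np.array_equal(x.f_exp, y.f_exp)
    # zero noise reproduces the oracle exactly
    clean = synthetic.generate_dataset(scn, noise_sd=0.0, seed=9)
    truth = scn.true_mdvs()
    for m in clean.mdv_measurements:
        assert np.allclose(m.f_exp, truth[m.metabolite_id], atol=1e-12)


def test_noisy_dataset_of_at_truth_is_order_one():
    """With noise of size Delta the OF evaluated at the true labeling is
    about 1 (mean normalized squared residual)."""
    from mfa2s.fit import compute_of

    ofs = []
    for seed in range(15):
        scn = synthetic.recovery_scenario(2)
        ds = synthetic.generate_dataset(scn, noise_sd=0.01, seed=seed)
        truth = scn.true_mdvs()
        sims = [truth[m.metabolite_id] for m in ds.mdv_measurements]
        ofs.append(compute_of(sims, ds)[0])
    assert 0.4 < np.mean(ofs) < 1.6


def test_resample_within_error():
    scn = synthetic.recovery_scenario(3)
    ds = synthetic.generate_dataset(scn, noise_sd=0.01, seed=0)
    sets = synthetic.resample_within_error(ds, 30, seed=5)
    assert len(sets) == 30
    for rds in sets:
        for m0, m1 in zip(ds.mdv_measurements, rds.mdv_measurements):
            # renormalization can stretch the +-Delta box slightly
            assert np.all(np.abs(m1.f_exp - m0.f_exp) <= 2.5 * m0.delta)
            assert np.isclose(m1.f_exp.sum(), 1.0)
    # zero error: all copies identical
    for m in ds.mdv_measurements:
        m.delta = np.full_like(m.delta, 1e-12)
    same = synthetic.resample_within_error(ds, 3, seed=5)
    for rds in same:
        for m0, m1 in zip(ds.mdv_measurements, rds.mdv_measurements):
            assert np.allclose(m1.f_exp, m0.f_exp, atol=1e-9)


def test_cofactor_swap_is_an_involution(exemplary):
    swapped = synthetic.perturb_cofactor(exemplary.model, "R_AF", "nadph->nadh")
    r = swapped.reaction("R_AF")
    assert r.stoichiometry["NADH"] == 1 and r.stoichiometry["NAD"] == -1
    assert "NADPH" not in r.stoichiometry and "NADP" not in r.stoichiometry
    back = synthetic.perturb_cofactor(swapped, "R_AF", "nadh->nadph")
    assert back.reaction("R_AF").stoichiometry == exemplary.model.reaction("R_AF").stoichiometry
    with pytest.raises(ValueError, match="does not use"):
        synthetic.perturb_cofactor(exemplary.model, "R_BD", "nadph->nadh")


def test_cofactor_swap_compensated_by_transhydrogenase(exemplary):
    """A simulated reconstruction error (NADPH -> NADH swap on the core
    dehydrogenase) leaves the labeling-fitted carbon fluxes nearly
    unchanged: the redox shift is absorbed by the reversible
    transhydrogenase-like reaction, not by rerouting carbon."""
    from tests.conftest import fitted_bundle

    watch = ["R_DC", "R_CE", "R_FG", "R_AB", "R_AF"]
    _, _, _, _, fit0 = fitted_bundle(exemplary, exemplary.dataset, n_restarts=2)
    swapped = synthetic.perturb_cofactor(exemplary.model, "R_AF", "nadph->nadh")
    scn2 = synthetic.SyntheticScenario(**{**exemplary.__dict__, "model": swapped})
    _, _, _, _, fit1 = fitted_bundle(scn2, exemplary.dataset, n_restarts=2)
    fit_shift = max(abs(fit0.fluxes[r] - fit1.fluxes[r]) for r in watch)
    assert fit_shift < 0.1  # under 1% of the substrate uptake
    assert fit1.of < 5.0  # data still well explained
    # the transhydrogenase-analogue reverses to supply NADPH
    assert fit0.fluxes["R_NOX"] > 0.5
    assert fit1.fluxes["R_NOX"] < -0.5


def test_oracle_validation_cases_shapes(rng):
    cases = synthetic.oracle_validation_cases()
    assert len(cases) >= 5
    for case in cases:
        tracked = {
            mid
            for maps in case["transitions"].values()
            for am in maps
            for mid, _ in am.products
        }
        assert sum(case["carbons"][m] for m in tracked) <= 8
        fluxes = case["sample_fluxes"](rng)
        assert all(v >= 0 for v in fluxes.values())
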