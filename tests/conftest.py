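import numpy as np
import pytest

from mfa2s import synthetic
from mfa2s.fit import TwoScaleProgram, fit
from mfa2s.partition import CorePartition, apply_measurements, limit_flux_to_core
from mfa2s.workflow import run_two_scale


@pytest.fixture(scope="session")
def exemplary():
    """Exemplary 20-reaction scenario with a generated noisy dataset."""
    scn = synthetic.exemplary_network()
    synthetic.generate_dataset(scn, noise_sd=0.01, seed=1)
    return scn


@pytest.fixture(scope="session")
def exemplary_run(exemplary):
    """Full recursive two-scale run on the exemplary network, starting
    without F -> D + M in the core."""
    return run_two_scale(
        exemplary.model,
        exemplary.transitions,
        exemplary.dataset,
        exemplary.feed,
        exemplary.core_reactions,
        n_restarts=3,
        seed=0,
    )


def fitted_bundle(scn, dataset, n_restarts=4, seed=0):
    """limit-core + fit on a scenario; returns (measured model, limited
    model, partition, program, fit result)."""
    part = CorePartition.from_transitions(scn.model, scn.core_reactions, scn.transitions)
    measured = apply_measurements(scn.model, dataset)
    limited, _ = limit_flux_to_core(measured, part)
    program = TwoScaleProgram(limited, part, scn.transitions, dataset, scn.feed)
    res = fit(program, n_restarts=n_restarts, seed=seed)
    return measured, limited, part, program, res


@pytest.fixture(scope="session")
def recovery_fit():
    """A fitted recovery scenario with mild noise (shared across tests)."""
    scn = synthetic.recovery_scenario(0)
    ds = synthetic.generate_dataset(scn, noise_sd=0.01, seed=100)
    return scn, ds, fitted_bundle(scn, ds)


@pytest.fixture(scope="session")
def futile_fit():
    scn = synthetic.futile_cycle_scenario()
    ds = synthetic.generate_dataset(scn, noise_sd=0.01, seed=2)
    return scn, ds, fitted_bundle(scn, ds, n_restarts=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
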