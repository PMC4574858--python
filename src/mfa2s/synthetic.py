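"""Synthetic scenarios: networks with known ground-truth fluxes, generated
labeling datasets, resampling and perturbation experiments.

Every fixture is built programmatically so the whole pipeline is testable
without external model or data downloads.  The centerpiece is
:func:`exemplary_network`, a 20-reaction toy whose topology reproduces the
two-scale storyline: a core (glycolysis-like) box feeding peripheral
drains, an NADPH-producing core reaction balanced partly outside the core,
and a growth-essential non-core reaction (F -> D + M) that leaks carbon
back into the core and must eventually be adopted into it.  Its carbon
skeletons (sizes 1-4) are invented for the fixture and chosen so that the
F -> D backflow measurably perturbs the labeling of the measured
metabolite C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    AtomMap,
    AtomTransition,
    AtomTransitionTable,
    FeedSpec,
    LabelingDataset,
    MDVMeasurement,
    Metabolite,
    Reaction,
    StoichiometricModel,
)
from .oracle import brute_force_oracle

__all__ = [
    "SyntheticScenario",
    "exemplary_network",
    "recovery_scenario",
    "futile_cycle_scenario",
    "knockout_pair_scenario",
    "generate_dataset",
    "resample_within_error",
    "perturb_cofactor",
    "save_scenario",
]


@dataclass
class SyntheticScenario:
    """A model + transitions + ground truth bundle.

    ``true_fluxes`` are net fluxes; ``true_exchange`` optionally carries the
    bidirectional (exchange) component of reversible mapped reactions, so
    that split fluxes are V_f = max(v,0)+x, V_b = max(-v,0)+x.
    """

    name: str
    model: StoichiometricModel
    transitions: AtomTransitionTable
    core_reactions: list[str]
    feed: FeedSpec
    true_fluxes: dict[str, float]
    measured_metabolites: list[str]
    measured_extracellular: list[str]
    true_exchange: dict[str, float] = field(default_factory=dict)
    dataset: LabelingDataset | None = None
    seed: int | None = None

    def true_split_fluxes(self) -> dict[str, float]:
        """Split-flux view of the ground truth over all mapped reactions."""
        out: dict[str, float] = {}
        for rid in self.transitions.reaction_ids():
            v = self.true_fluxes[rid]
            x = self.true_exchange.get(rid, 0.0)
            if self.model.reaction(rid).reversible:
                out[rid + "_f"] = max(v, 0.0) + x
                out[rid + "_b"] = max(-v, 0.0) + x
            else:
                out[rid] = v
        return out

    def true_mdvs(self) -> dict[str, np.ndarray]:
        """Ground-truth MDVs from the exhaustive isotopomer oracle, using
        the full mapped reaction set (core and not-yet-core alike)."""
        trans = {}
        for rid in self.transitions.reaction_ids():
            maps = self.transitions[rid].maps
            if self.model.reaction(rid).reversible:
                trans[rid + "_f"] = list(maps)
                trans[rid + "_b"] = [m.reversed() for m in maps]
            else:
                trans[rid] = list(maps)
        carbons = {m.id: m.n_carbons for m in self.model.metabolites}
        return brute_force_oracle(
            trans,
            self.true_split_fluxes(),
            {self.feed.substrate_id: self.feed.isotopomer_distribution()},
            carbons,
        )


def _check_steady_state(scn: SyntheticScenario, tol: float = 1e-9) -> None:
    A, ids = scn.model.balance_matrix()
    v = np.array([scn.true_fluxes[r] for r in scn.model.reaction_ids])
    resid = A @ v
    if np.abs(resid).max() > tol:
        bad = ids[int(np.abs(resid).argmax())]
        raise ValueError(f"{scn.name}: true fluxes violate steady state at {bad}")


# ---------------------------------------------------------------------------
# the exemplary 20-reaction network
# ---------------------------------------------------------------------------

def exemplary_network() -> SyntheticScenario:
    """The 20-reaction illustrative network.

    Core box (initially): uptake, A->B(+W), B->D, D->C, C->E(+W),
    A+NADP->F+NADPH, F->G+V, G<=>E, E+NADPH->I+NADP.  The non-core reaction
    F -> D + M produces the growth-essential species M, so "limit flux to
    core" cannot clamp it to zero and ELVA later forces it into the core.
    Measured: MDVs of A, C, E; extracellular fluxes of the reactions
    producing T, U, Y and Z; growth.
    """
    mets = [
        Metabolite("S_e", 4, boundary=True, compartment="e"),
        Metabolite("A", 4), Metabolite("B", 3), Metabolite("C", 3),
        Metabolite("D", 3), Metabolite("E", 2), Metabolite("F", 4),
        Metabolite("G", 2), Metabolite("I", 2), Metabolite("M", 1),
        Metabolite("V", 2), Metabolite("W", 1), Metabolite("P", 2),
        Metabolite("NADP", 0), Metabolite("NADPH", 0),
        Metabolite("NAD", 0), Metabolite("NADH", 0),
        Metabolite("T_e", 2, boundary=True, compartment="e"),
        Metabolite("U_e", 2, boundary=True, compartment="e"),
        Metabolite("Y_e", 2, boundary=True, compartment="e"),
        Metabolite("Z_e", 1, boundary=True, compartment="e"),
        Metabolite("X_e", 0, boundary=True, compartment="e"),
        Metabolite("BIO_e", 0, boundary=True, compartment="e"),
    ]
    rxns = [
        Reaction("upt", {"S_e": -1, "A": 1}, 0, 500),
        Reaction("R_AB", {"A": -1, "B": 1, "W": 1}, 0, 500),
        Reaction("R_BD", {"B": -1, "D": 1}, 0, 500),
        Reaction("R_DC", {"D": -1, "C": 1}, 0, 500),
        Reaction("R_CE", {"C": -1, "E": 1, "W": 1}, 0, 500),
        Reaction("R_AF", {"A": -1, "NADP": -1, "F": 1, "NADPH": 1}, 0, 500),
        Reaction("R_FG", {"F": -1, "G": 1, "V": 1}, 0, 500),
        Reaction("R_GE", {"G": -1, "E": 1}, -500, 500),
        Reaction("R_EI", {"E": -1, "NADPH": -1, "I": 1, "NADP": 1}, 0, 500),
        Reaction("R_FDM", {"F": -1, "D": 1, "M": 1}, 0, 500),
        Reaction("R_IT", {"I": -1, "T_e": 1}, 0, 500),
        Reaction("R_EU", {"E": -1, "U_e": 1}, 0, 500),
        Reaction("R_VY", {"V": -1, "Y_e": 1}, 0, 500),
        Reaction("R_VX", {"V": -1, "X_e": 1}, 0, 500),
        Reaction("R_WZ", {"W": -1, "Z_e": 1}, 0, 500),
        Reaction("R_EP", {"E": -1, "P": 1}, -500, 500),
        Reaction("R_PX", {"P": -1, "X_e": 1}, 0, 500),
        # transhydrogenase-like, reversible: lets either redox pair cover
        # for the other (the compensation route for reconstruction errors)
        Reaction("R_NOX", {"NADPH": -1, "NAD": -1, "NADP": 1, "NADH": 1}, -500, 500),
        Reaction("R_NADHX", {"NADH": -1, "NAD": 1}, 0, 500),
        Reaction("BIOMASS", {"M": -1, "I": -2, "BIO_e": 1}, 0, 500),
    ]
    model = StoichiometricModel(
        mets, rxns, biomass_reaction="BIOMASS", substrate_uptake_reaction="upt",
        id="exemplary20",
    )
    t = AtomTransitionTable()
    t.add(AtomTransition("upt", [AtomMap((("S_e", "abcd"),), (("A", "abcd"),))]))
    t.add(AtomTransition("R_AB", [AtomMap((("A", "abcd"),), (("B", "abc"), ("W", "d")))]))
    t.add(AtomTransition("R_BD", [AtomMap((("B", "abc"),), (("D", "abc"),))]))
    t.add(AtomTransition("R_DC", [AtomMap((("D", "abc"),), (("C", "abc"),))]))
    t.add(AtomTransition("R_CE", [AtomMap((("C", "abc"),), (("E", "ab"), ("W", "c")))]))
    t.add(AtomTransition("R_AF", [AtomMap((("A", "abcd"),), (("F", "abcd"),))]))
    t.add(AtomTransition("R_FG", [AtomMap((("F", "abcd"),), (("G", "cd"), ("V", "ab")))]))
    t.add(AtomTransition("R_GE", [AtomMap((("G", "ab"),), (("E", "ab"),))]))
    t.add(AtomTransition("R_EI", [AtomMap((("E", "ab"),), (("I", "ab"),))]))
    # map for the initially non-core reaction; used once the core expands
    t.add(AtomTransition("R_FDM", [AtomMap((("F", "abcd"),), (("D", "abc"), ("M", "d")))]))
    t.validate(model)
    core = ["upt", "R_AB", "R_BD", "R_DC", "R_CE", "R_AF", "R_FG", "R_GE", "R_EI"]
    feed = FeedSpec("S_e", [("1100", 0.5), ("0000", 0.5)])
    truth = {
        "upt": 10.0, "R_AB": 4.0, "R_BD": 4.0, "R_DC": 4.3, "R_CE": 4.3,
        "R_AF": 6.0, "R_FG": 5.7, "R_GE": 5.7, "R_EI": 5.0, "R_FDM": 0.3,
        "R_IT": 4.4, "R_EU": 5.0, "R_VY": 5.2, "R_VX": 0.5, "R_WZ": 8.3,
        "R_EP": 0.0, "R_PX": 0.0, "R_NOX": 1.0, "R_NADHX": 1.0, "BIOMASS": 0.3,
    }
    scn = SyntheticScenario(
        name="exemplary",
        model=model,
        transitions=t,
        core_reactions=core,
        feed=feed,
        true_fluxes=truth,
        measured_metabolites=["A", "C", "E"],
        measured_extracellular=["R_IT", "R_EU", "R_VY", "R_WZ"],
        true_exchange={"R_GE": 0.5},
    )
    _check_steady_state(scn)
    return scn


# ---------------------------------------------------------------------------
# small randomized network for parameter-recovery studies
# ---------------------------------------------------------------------------

def recovery_scenario(seed: int = 0, reversible_join: bool = True) -> SyntheticScenario:
    """Branch-point network whose split is identifiable only through
    labeling: a direct route A->B versus a cleave-and-recombine route
    A->C2+W, C2+W->B that scrambles carbon 3 through the shared W pool.
    The recombination step is reversible (aldolase-like), so its exchange
    flux is a nuisance degree of freedom, as in real networks.  The branch
    fraction is drawn from U(0.2, 0.8) per seed."""
    rng = np.random.default_rng(seed)
    mets = [
        Metabolite("S_e", 3, boundary=True, compartment="e"),
        Metabolite("A", 3), Metabolite("B", 3), Metabolite("C2", 2), Metabolite("W", 1),
        Metabolite("X_e", 0, boundary=True, compartment="e"),
        Metabolite("BIO_e", 0, boundary=True, compartment="e"),
    ]
    rxns = [
        Reaction("upt", {"S_e": -1, "A": 1}, 0, 500),
        Reaction("R_direct", {"A": -1, "B": 1}, 0, 500),
        Reaction("R_split", {"A": -1, "C2": 1, "W": 1}, 0, 500),
        Reaction("R_join", {"C2": -1, "W": -1, "B": 1}, -500 if reversible_join else 0, 500),
        Reaction("R_BX", {"B": -1, "X_e": 1}, 0, 500),
        Reaction("R_Bbio", {"B": -1, "BIO_e": 1}, 0, 500),
    ]
    model = StoichiometricModel(
        mets, rxns, biomass_reaction="R_Bbio", substrate_uptake_reaction="upt",
        id=f"recovery{seed}",
    )
    t = AtomTransitionTable()
    t.add(AtomTransition("upt", [AtomMap((("S_e", "abc"),), (("A", "abc"),))]))
    t.add(AtomTransition("R_direct", [AtomMap((("A", "abc"),), (("B", "abc"),))]))
    t.add(AtomTransition("R_split", [AtomMap((("A", "abc"),), (("C2", "ab"), ("W", "c")))]))
    t.add(AtomTransition("R_join", [AtomMap((("C2", "ab"), ("W", "c")), (("B", "abc"),))]))
    t.validate(model)
    s = 10.0 * rng.uniform(0.2, 0.8)
    truth = {
        "upt": 10.0, "R_direct": s, "R_split": 10.0 - s, "R_join": 10.0 - s,
        "R_BX": 7.0, "R_Bbio": 3.0,
    }
    scn = SyntheticScenario(
        name=f"recovery-{seed}",
        model=model,
        transitions=t,
        core_reactions=["upt", "R_direct", "R_split", "R_join"],
        feed=FeedSpec("S_e", [("111", 0.5), ("000", 0.5)]),
        true_fluxes=truth,
        measured_metabolites=["A", "B"],
        measured_extracellular=["R_BX"],
        true_exchange={"R_join": 1.0} if reversible_join else {},
        seed=seed,
    )
    _check_steady_state(scn)
    return scn


# ---------------------------------------------------------------------------
# futile-cycle fixture
# ---------------------------------------------------------------------------

def futile_cycle_scenario() -> SyntheticScenario:
    """A labeled pass-through chain plus the nucleotide futile cycle
    NDPK1/ADK1/ADK2 with +-500 bounds, which labeling cannot constrain."""
    mets = [
        Metabolite("S_e", 2, boundary=True, compartment="e"),
        Metabolite("A", 2),
        Metabolite("X_e", 0, boundary=True, compartment="e"),
        Metabolite("atp", 0), Metabolite("adp", 0), Metabolite("amp", 0),
        Metabolite("gtp", 0), Metabolite("gdp", 0),
    ]
    rxns = [
        Reaction("upt", {"S_e": -1, "A": 1}, 0, 500),
        Reaction("R_AX", {"A": -1, "X_e": 1}, 0, 500),
        Reaction("NDPK1", {"gdp": -1, "atp": -1, "gtp": 1, "adp": 1}, -500, 500),
        Reaction("ADK1", {"amp": -1, "atp": -1, "adp": 2}, -500, 500),
        Reaction("ADK2", {"gtp": -1, "amp": -1, "gdp": 1, "adp": 1}, -500, 500),
    ]
    model = StoichiometricModel(
        mets, rxns, substrate_uptake_reaction="upt", id="futile"
    )
    t = AtomTransitionTable()
    t.add(AtomTransition("upt", [AtomMap((("S_e", "ab"),), (("A", "ab"),))]))
    t.validate(model)
    truth = {"upt": 10.0, "R_AX": 10.0, "NDPK1": 7.0, "ADK1": -7.0, "ADK2": 7.0}
    scn = SyntheticScenario(
        name="futile-cycle",
        model=model,
        transitions=t,
        core_reactions=["upt"],
        feed=FeedSpec("S_e", [("11", 0.3), ("00", 0.7)]),
        true_fluxes=truth,
        measured_metabolites=["A"],
        measured_extracellular=["R_AX"],
    )
    _check_steady_state(scn)
    return scn


# ---------------------------------------------------------------------------
# wild-type / knockout prediction pair
# ---------------------------------------------------------------------------

def knockout_pair_scenario() -> SyntheticScenario:
    """Three distinguishable routes from A to the biomass precursor B.

    R1 (efficient, 1 B per A) is the FBA favourite; R2 and R3 each burn a
    second A and differ in which carbons reach B.  The ground-truth wild
    type runs mostly through R1/R2 and is deliberately *not* FBA-optimal,
    so adjustment predictions referenced on the true (13C-fitted) profile
    beat those referenced on FBA."""
    mets = [
        Metabolite("S_e", 3, boundary=True, compartment="e"),
        Metabolite("A", 3), Metabolite("B", 2), Metabolite("W1", 1), Metabolite("W4", 4),
        Metabolite("X1_e", 0, boundary=True, compartment="e"),
        Metabolite("X4_e", 0, boundary=True, compartment="e"),
        Metabolite("BIO_e", 0, boundary=True, compartment="e"),
    ]
    rxns = [
        Reaction("upt", {"S_e": -1, "A": 1}, 0, 500),
        Reaction("R1", {"A": -1, "B": 1, "W1": 1}, 0, 500),
        Reaction("R2", {"A": -2, "B": 1, "W4": 1}, 0, 500),
        Reaction("R3", {"A": -2, "B": 1, "W4": 1}, 0, 500),
        Reaction("R_W1X", {"W1": -1, "X1_e": 1}, 0, 500),
        Reaction("R_W4X", {"W4": -1, "X4_e": 1}, 0, 500),
        Reaction("R_Bbio", {"B": -1, "BIO_e": 1}, 0, 500),
    ]
    model = StoichiometricModel(
        mets, rxns, biomass_reaction="R_Bbio", substrate_uptake_reaction="upt",
        id="kopair",
    )
    t = AtomTransitionTable()
    t.add(AtomTransition("upt", [AtomMap((("S_e", "abc"),), (("A", "abc"),))]))
    t.add(AtomTransition("R1", [AtomMap((("A", "abc"),), (("B", "ab"), ("W1", "c")))]))
    t.add(AtomTransition("R2", [AtomMap((("A", "abc"), ("A", "def")), (("B", "bc"), ("W4", "adef")))]))
    t.add(AtomTransition("R3", [AtomMap((("A", "abc"), ("A", "def")), (("B", "ca"), ("W4", "bdef")))]))
    t.validate(model)
    truth = {
        "upt": 10.0, "R1": 4.0, "R2": 2.9, "R3": 0.1,
        "R_W1X": 4.0, "R_W4X": 3.0, "R_Bbio": 7.0,
    }
    scn = SyntheticScenario(
        name="knockout-pair",
        model=model,
        transitions=t,
        core_reactions=["upt", "R1", "R2", "R3"],
        feed=FeedSpec("S_e", [("100", 0.4), ("010", 0.3), ("000", 0.3)]),
        true_fluxes=truth,
        measured_metabolites=["A", "B"],
        measured_extracellular=[],
    )
    _check_steady_state(scn)
    return scn


# ---------------------------------------------------------------------------
# dataset generation, resampling, perturbation
# ---------------------------------------------------------------------------

def generate_dataset(
    scenario: SyntheticScenario,
    noise_sd: float = 0.01,
    seed: int = 0,
    flux_interval_rel: float = 0.01,
    growth_interval_rel: float = 0.01,
    true_fluxes: dict[str, float] | None = None,
) -> LabelingDataset:
    """Forward-simulate the ground truth and add measurement noise.

    MDVs come from the exhaustive isotopomer oracle; each element receives
    independent N(0, noise_sd^2) noise, is clipped to [0, 1] and the vector
    renormalized; noise_sd is stored as the measurement error Delta.
    Extracellular fluxes and growth get symmetric relative intervals around
    their true values.
    """
    rng = np.random.default_rng(seed)
    if true_fluxes is not None:
        scenario = SyntheticScenario(
            **{**scenario.__dict__, "true_fluxes": dict(true_fluxes)}
        )
    mdvs = scenario.true_mdvs()
    meas = []
    for mid in scenario.measured_metabolites:
        f = mdvs[mid].copy()
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=f.shape)
            f = np.clip(f, 0.0, None)
            f = f / f.sum()
        delta = np.full(f.shape, max(noise_sd, 1e-3))
        meas.append(MDVMeasurement(mid, f, delta))
    extracellular = []
    v_upt = scenario.true_fluxes[scenario.model.substrate_uptake_reaction]
    extracellular.append(
        (
            scenario.model.substrate_uptake_reaction,
            v_upt * (1 - flux_interval_rel),
            v_upt * (1 + flux_interval_rel),
        )
    )
    for rid in scenario.measured_extracellular:
        v = scenario.true_fluxes[rid]
        lo, hi = sorted((v * (1 - flux_interval_rel), v * (1 + flux_interval_rel)))
        extracellular.append((rid, lo, hi))
    growth = None
    if scenario.model.biomass_reaction is not None:
        mu = scenario.true_fluxes[scenario.model.biomass_reaction]
        growth = (mu * (1 - growth_interval_rel), mu * (1 + growth_interval_rel))
    ds = LabelingDataset(meas, extracellular, growth)
    scenario.dataset = ds
    scenario.seed = seed
    return ds


def resample_within_error(
    dataset: LabelingDataset, n_sets: int, seed: int = 0
) -> list[LabelingDataset]:
    """New datasets with each labeling value redrawn uniformly within
    f_exp +- Delta (clipped to [0,1], renormalized); fluxes unchanged."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        meas = []
        for m in dataset.mdv_measurements:
            f = m.f_exp + rng.uniform(-1.0, 1.0, size=m.f_exp.shape) * m.delta
            f = np.clip(f, 0.0, 1.0)
            f = f / f.sum()
            meas.append(MDVMeasurement(m.metabolite_id, f, m.delta.copy(), m.atoms))
        out.append(
            LabelingDataset(meas, list(dataset.extracellular_measurements), dataset.growth_rate)
        )
    return out


def oracle_validation_cases() -> list[dict]:
    """Five small networks (<= 8 tracked carbons each) for validating the
    EMU engine against the exhaustive isotopomer oracle.

    Each case carries split-level transitions, carbon counts, the feed
    metabolite, and a ``sample_fluxes(rng)`` callable drawing random
    steady-state-consistent nonnegative split fluxes.
    """
    cases = []

    # 1. pass-through chain S -> A -> B -> out
    def chain_fluxes(rng):
        v = float(rng.uniform(1.0, 10.0))
        return {"upt": v, "R_AB": v, "R_Bout": v}

    cases.append(
        {
            "name": "chain",
            "transitions": {
                "upt": [AtomMap((("S", "ab"),), (("A", "ab"),))],
                "R_AB": [AtomMap((("A", "ab"),), (("B", "ab"),))],
                "R_Bout": [AtomMap((("B", "ab"),), ())],
            },
            "carbons": {"S": 2, "A": 2, "B": 2},
            "feed": "S",
            "sample_fluxes": chain_fluxes,
        }
    )

    # 2. cleave and recombine through a shared one-carbon pool
    def cleave_fluxes(rng):
        v = float(rng.uniform(1.0, 10.0))
        return {"upt": v, "R_cut": v, "R_glue": v, "R_Bout": v}

    cases.append(
        {
            "name": "cleave-join",
            "transitions": {
                "upt": [AtomMap((("S", "ab"),), (("A", "ab"),))],
                "R_cut": [AtomMap((("A", "ab"),), (("C", "a"), ("W", "b")))],
                "R_glue": [AtomMap((("C", "a"), ("W", "b")), (("B", "ab"),))],
                "R_Bout": [AtomMap((("B", "ab"),), ())],
            },
            "carbons": {"S": 2, "A": 2, "C": 1, "W": 1, "B": 2},
            "feed": "S",
            "sample_fluxes": cleave_fluxes,
        }
    )

    # 3. symmetric intermediate: two equiprobable orientations
    def sym_fluxes(rng):
        v = float(rng.uniform(1.0, 10.0))
        return {"upt": v, "R_sym": v, "R_out": v}

    cases.append(
        {
            "name": "symmetric",
            "transitions": {
                "upt": [AtomMap((("S", "ab"),), (("A", "ab"),))],
                "R_sym": [
                    AtomMap((("A", "ab"),), (("Q", "ab"),)),
                    AtomMap((("A", "ab"),), (("Q", "ba"),)),
                ],
                "R_out": [AtomMap((("Q", "ab"),), ())],
            },
            "carbons": {"S": 2, "A": 2, "Q": 2},
            "feed": "S",
            "sample_fluxes": sym_fluxes,
        }
    )

    # 4. reversible position-swapping isomerase A <=> B
    def rev_fluxes(rng):
        v = float(rng.uniform(1.0, 8.0))
        x = float(rng.uniform(0.0, 10.0))  # exchange flux
        return {"upt": v, "iso_f": v + x, "iso_b": x, "R_out": v}

    cases.append(
        {
            "name": "reversible-isomerase",
            "transitions": {
                "upt": [AtomMap((("S", "ab"),), (("A", "ab"),))],
                "iso_f": [AtomMap((("A", "ab"),), (("B", "ba"),))],
                "iso_b": [AtomMap((("B", "ba"),), (("A", "ab"),))],
                "R_out": [AtomMap((("B", "ab"),), ())],
            },
            "carbons": {"S": 2, "A": 2, "B": 2},
            "feed": "S",
            "sample_fluxes": rev_fluxes,
        }
    )

    # 5. cleave + swapped recombination inside a recycling loop
    def loop_fluxes(rng):
        v = float(rng.uniform(1.0, 6.0))
        r = float(rng.uniform(0.0, 8.0))  # recycled flux through the loop
        return {
            "upt": v, "R_cut": v + r, "R_swap": v + r,
            "R_back": r, "R_out": v,
        }

    cases.append(
        {
            "name": "scramble-loop",
            "transitions": {
                "upt": [AtomMap((("S", "ab"),), (("A", "ab"),))],
                "R_cut": [AtomMap((("A", "ab"),), (("X", "a"), ("Y", "b")))],
                "R_swap": [AtomMap((("X", "a"), ("Y", "b")), (("Z", "ba"),))],
                "R_back": [AtomMap((("Z", "ab"),), (("A", "ab"),))],
                "R_out": [AtomMap((("Z", "ab"),), ())],
            },
            "carbons": {"S": 2, "A": 2, "X": 1, "Y": 1, "Z": 2},
            "feed": "S",
            "sample_fluxes": loop_fluxes,
        }
    )
    return cases


COFACTOR_PAIRS = {
    "nadph": ("NADP", "NADPH"),
    "nadh": ("NAD", "NADH"),
}


def perturb_cofactor(
    model: StoichiometricModel,
    reaction_id: str,
    swap: str = "nadph->nadh",
    pairs: dict[str, tuple[str, str]] = COFACTOR_PAIRS,
) -> StoichiometricModel:
    """Simulate a reconstruction error by swapping a reaction's cofactor
    dependence (e.g. NADPH -> NADH); applying the swap twice restores the
    original model."""
    src_name, dst_name = swap.split("->")
    src_ox, src_red = pairs[src_name.strip()]
    dst_ox, dst_red = pairs[dst_name.strip()]
    out = model.copy()
    rxn = out.reaction(reaction_id)
    if src_red not in rxn.stoichiometry and src_ox not in rxn.stoichiometry:
        raise ValueError(f"{reaction_id} does not use the {src_name} pair")
    for old, new in ((src_ox, dst_ox), (src_red, dst_red)):
        if old in rxn.stoichiometry:
            c = rxn.stoichiometry.pop(old)
            rxn.stoichiometry[new] = rxn.stoichiometry.get(new, 0.0) + c
    return out


def save_scenario(scenario: SyntheticScenario, directory: str | Path) -> None:
    """Write the scenario bundle: model JSON, transitions TSV, measurement
    CSVs, feed CSV, core list, truth CSV and a manifest."""
    from . import io as mio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mio.write_model(scenario.model, d / "model.json")
    mio.write_atom_transitions(scenario.transitions, d / "transitions.tsv")
    mio.write_core_set(scenario.core_reactions, d / "core.txt")
    mio.write_feed(scenario.feed, d / "feed.csv")
    if scenario.dataset is not None:
        mio.write_measurements(
            scenario.dataset, d / "mdv.csv", d / "extracellular.csv",
            biomass_reaction=scenario.model.biomass_reaction or "growth",
        )
    import pandas as pd

    pd.DataFrame(
        [{"reaction_id": r, "flux": v} for r, v in scenario.true_fluxes.items()]
    ).to_csv(d / "truth.csv", index=False)
    (d / "manifest.json").write_text(
        json.dumps({"name": scenario.name, "seed": scenario.seed}, indent=1)
    )
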