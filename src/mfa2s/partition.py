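"""Core/non-core partition bookkeeping and the "limiting flux to core"
procedure.

The two-scale approximation assumes carbon flows from the core outward and
not back.  It is enforced on the genome-scale model by clamping every
non-core reaction that flows *into* the core to zero — or, where that
breaks the measured growth rate, to the smallest of {0, 0.05, 0.2} times
the substrate uptake rate that keeps the model feasible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import lp
from .model import AtomTransitionTable, LabelingDataset, StoichiometricModel

log = logging.getLogger(__name__)

__all__ = ["CorePartition", "LimitRecord", "LimitReport", "limit_flux_to_core", "expand_core", "apply_measurements"]

#: escalation ladder of Algorithm-style core-inflow limits, as fractions of
#: the substrate uptake rate
LIMIT_FRACTIONS = (0.0, 0.05, 0.2)


@dataclass
class CorePartition:
    """The core reaction/metabolite split.

    ``core_metabolites`` are the species whose labeling is tracked;
    ``provenance`` records whether a reaction was in the initial core or
    added by an ELVA-driven expansion.
    """

    core_reactions: list[str]
    core_metabolites: set[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid in self.core_reactions:
            self.provenance.setdefault(rid, "initial")

    @classmethod
    def from_transitions(
        cls,
        model: StoichiometricModel,
        core_reactions: list[str],
        transitions: AtomTransitionTable,
    ) -> "CorePartition":
        """Derive the tracked-metabolite set from the core reactions' carbon
        maps (boundary species stay inputs, not tracked)."""
        mets: set[str] = set()
        for rid in core_reactions:
            if rid not in transitions:
                raise ValueError(f"core reaction {rid} has no atom map")
            for am in transitions[rid].maps:
                for mid, _ in list(am.reactants) + list(am.products):
                    if not model.metabolite(mid).boundary:
                        mets.add(mid)
        return cls(list(core_reactions), mets)

    def is_core(self, rid: str) -> bool:
        return rid in self.core_reactions

    def copy(self) -> "CorePartition":
        return CorePartition(
            list(self.core_reactions), set(self.core_metabolites), dict(self.provenance)
        )


@dataclass
class LimitRecord:
    reaction_id: str
    direction: str  # "forward" or "backward"
    trials: list[tuple[float, bool]]  # (limit value, FBA feasible)
    chosen_limit: float | None  # None = left unlimited (flagged)
    flagged: bool = False


@dataclass
class LimitReport:
    records: list[LimitRecord] = field(default_factory=list)
    order: list[str] = field(default_factory=list)

    @property
    def flagged_reactions(self) -> list[str]:
        return [r.reaction_id for r in self.records if r.flagged]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "reaction_id": r.reaction_id,
                    "direction": r.direction,
                    "chosen_limit": "unlimited" if r.chosen_limit is None else r.chosen_limit,
                    "n_trials": len(r.trials),
                    "trials": ";".join(f"{l:g}:{'ok' if f else 'infeasible'}" for l, f in r.trials),
                    "flagged": r.flagged,
                }
            )
        return pd.DataFrame(rows)


def apply_measurements(
    model: StoichiometricModel, dataset: LabelingDataset
) -> StoichiometricModel:
    """Intersect model bounds with the measured extracellular-flux and
    growth intervals (measurements act as bound pairs, not equalities)."""
    out = model.copy()
    for rid, lo, hi in dataset.extracellular_measurements:
        r = out.reaction(rid)
        r.lb, r.ub = max(r.lb, lo), min(r.ub, hi)
        if r.lb > r.ub:
            raise ValueError(f"measured bounds for {rid} conflict with model bounds")
    if dataset.growth_rate is not None:
        if out.biomass_reaction is None:
            raise ValueError("growth measured but model has no biomass reaction")
        r = out.reaction(out.biomass_reaction)
        r.lb, r.ub = max(r.lb, dataset.growth_rate[0]), min(r.ub, dataset.growth_rate[1])
    return out


def _flows_into_core(model: StoichiometricModel, partition: CorePartition, rid: str):
    """(has_forward_inflow, has_backward_inflow) for a non-core reaction:
    evaluated on the signed stoichiometry per direction."""
    rxn = model.reaction(rid)
    fwd = rxn.ub > 0 and any(m in partition.core_metabolites for m in rxn.products())
    bwd = rxn.lb < 0 and any(m in partition.core_metabolites for m in rxn.reactants())
    return fwd, bwd


def limit_flux_to_core(
    model: StoichiometricModel,
    partition: CorePartition,
    glucupt: float | None = None,
    limit_fractions: tuple[float, ...] = LIMIT_FRACTIONS,
) -> tuple[StoichiometricModel, LimitReport]:
    """Clamp non-core flux into the core, escalating each reaction's limit
    through ``limit_fractions * glucupt`` until the model stays feasible.

    ``model`` must already carry the measured extracellular and growth
    bounds (see :func:`apply_measurements`); feasibility is checked by LP
    with the growth rate constrained to its measured interval, never
    maximized.  Clamps are applied cumulatively in model order and the
    exact order is recorded for reproducibility.
    """
    if glucupt is None:
        glucupt = model.glucose_uptake_rate()
    if not lp.feasible(model):
        raise ValueError(
            "model infeasible before limiting: measurements are inconsistent"
        )
    out = model.copy()
    report = LimitReport()
    limits = [f * glucupt for f in limit_fractions]
    for rid in out.reaction_ids:
        if partition.is_core(rid):
            continue
        fwd, bwd = _flows_into_core(out, partition, rid)
        rxn = out.reaction(rid)
        if fwd:
            orig_ub = rxn.ub
            trials = []
            chosen = None
            for limit in limits:
                rxn.ub = min(orig_ub, limit)
                ok = lp.feasible(out)
                trials.append((limit, ok))
                if ok:
                    chosen = limit
                    break
            flagged = chosen is None
            if flagged:  # never feasible: left at the largest tried limit
                chosen = limits[-1]
                rxn.ub = min(orig_ub, chosen)
            report.records.append(LimitRecord(rid, "forward", trials, chosen, flagged))
            report.order.append(rid)
        if bwd:
            orig_lb = rxn.lb
            trials = []
            chosen = None
            for limit in limits:
                # sign(lb) * min(|lb|, limit)
                rxn.lb = -min(abs(orig_lb), limit) if orig_lb < 0 else orig_lb
                ok = lp.feasible(out)
                trials.append((limit, ok))
                if ok:
                    chosen = limit
                    break
            flagged = chosen is None
            if flagged:
                chosen = limits[-1]
                rxn.lb = -min(abs(orig_lb), chosen) if orig_lb < 0 else orig_lb
            report.records.append(LimitRecord(rid, "backward", trials, chosen, flagged))
            if rid not in report.order:
                report.order.append(rid)
    return out, report


def expand_core(
    partition: CorePartition,
    reactions: list[str],
    transitions: AtomTransitionTable,
    model: StoichiometricModel,
) -> CorePartition:
    """Add reactions (with their mapped metabolites) to the core.

    Every added reaction needs an atom map; already-core reactions are
    skipped with a warning.
    """
    missing = [rid for rid in reactions if rid not in transitions]
    if missing:
        raise ValueError(f"cannot expand core: no atom maps for {missing}")
    out = partition.copy()
    for rid in reactions:
        if out.is_core(rid):
            log.warning("expand_core: %s already in core, skipping", rid)
            continue
        out.core_reactions.append(rid)
        out.provenance[rid] = "elva-added"
        for am in transitions[rid].maps:
            for mid, _ in list(am.reactants) + list(am.products):
                if not model.metabolite(mid).boundary:
                    out.core_metabolites.add(mid)
    return out
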