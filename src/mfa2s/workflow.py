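"""End-to-end recursive workflow and report surfaces.

``run_two_scale`` drives the loop: limit flux to core -> fit -> ELVA ->
(expand core, repeat) until the core choice is self-consistent or the
round budget is exhausted.  Report helpers summarize cofactor balances and
predicted extracellular metabolites from the fitted fluxes and their
confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import elva as elva_mod
from . import fva13c as fva_mod
from .fit import FitResult, TwoScaleProgram, fit
from .lp import FluxInterval
from .model import (
    AtomTransitionTable,
    FeedSpec,
    LabelingDataset,
    StoichiometricModel,
)
from .partition import (
    CorePartition,
    LimitReport,
    apply_measurements,
    expand_core,
    limit_flux_to_core,
)

log = logging.getLogger(__name__)

__all__ = ["RunResult", "RoundResult", "run_two_scale", "cofactor_balance", "exchange_prediction", "CofactorBalance"]


@dataclass
class RoundResult:
    round_index: int
    partition: CorePartition
    limit_report: LimitReport
    fit: FitResult
    elva_intervals: list
    decision: elva_mod.ELVADecision
    program: TwoScaleProgram


@dataclass
class RunResult:
    status: str  # "self-consistent" | "max-rounds" | "halted"
    rounds: list[RoundResult]
    model_measured: StoichiometricModel
    model_limited: StoichiometricModel
    comparisons: list | None = None
    tolerances: fva_mod.ToleranceSet | None = None
    audit: list[str] = field(default_factory=list)

    @property
    def final(self) -> RoundResult:
        return self.rounds[-1]

    @property
    def expansion_rounds(self) -> int:
        return len(self.rounds) - 1


def run_two_scale(
    model: StoichiometricModel,
    transitions: AtomTransitionTable,
    dataset: LabelingDataset,
    feed: FeedSpec,
    core_reactions: list[str],
    n_restarts: int = 5,
    seed: int = 0,
    elva_factor: float = 1.0,
    max_expansion_rounds: int = 5,
    compute_intervals: bool = False,
    interval_reactions: list[str] | None = None,
) -> RunResult:
    """The recursive two-scale procedure.

    Each round re-limits the original model bounds under the current core
    partition, fits the labeling data, and tests self-consistency through
    ELVA; failing rounds expand the core with the reactions behind the
    offending inflow dummies (requiring atom maps for them).
    """
    audit: list[str] = []
    partition = CorePartition.from_transitions(model, core_reactions, transitions)
    model_measured = apply_measurements(model, dataset)
    rounds: list[RoundResult] = []
    status = "max-rounds"
    model_limited = model_measured
    for rnd in range(max_expansion_rounds + 1):
        model_limited, limit_report = limit_flux_to_core(model_measured, partition)
        for rec in limit_report.records:
            audit.append(
                f"round {rnd}: limit {rec.reaction_id} ({rec.direction}) -> "
                f"{'unlimited' if rec.chosen_limit is None else rec.chosen_limit:g}"
                + (" FLAGGED" if rec.flagged else "")
            )
        program = TwoScaleProgram(model_limited, partition, transitions, dataset, feed)
        fitres = fit(program, n_restarts=n_restarts, seed=seed + rnd)
        audit.append(f"round {rnd}: fit OF={fitres.of:.4g} SSR={fitres.ssr:.4g}")
        network = elva_mod.build_extended_network(program, fitres)
        intervals = elva_mod.elva_intervals(network, dataset, seed=seed)
        decision = elva_mod.check_self_consistency(network, intervals, factor=elva_factor, seed=seed)
        audit.append(
            f"round {rnd}: ELVA {'PASS' if decision.passed else 'FAIL'} "
            f"(worst half-width / allowance = {decision.worst_ratio:.3g})"
        )
        rounds.append(
            RoundResult(rnd, partition.copy(), limit_report, fitres, intervals, decision, program)
        )
        if decision.passed:
            status = "self-consistent"
            break
        if rnd == max_expansion_rounds:
            status = "max-rounds"
            break
        candidates = decision.candidate_reactions
        missing = [r for r in candidates if r not in transitions]
        if missing:
            audit.append(f"round {rnd}: HALT, no atom maps for {missing}")
            status = "halted"
            break
        if not candidates:
            status = "max-rounds"
            break
        audit.append(f"round {rnd}: expanding core with {candidates}")
        partition = expand_core(partition, candidates, transitions, model)

    result = RunResult(
        status=status,
        rounds=rounds,
        model_measured=model_measured,
        model_limited=model_limited,
        audit=audit,
    )
    if compute_intervals and rounds:
        last = rounds[-1]
        tol = fva_mod.compute_tolerances(last.fit, dataset)
        result.tolerances = tol
        result.comparisons = fva_mod.compare_modes(
            model_measured, model_limited, last.program, last.fit, tol,
            reactions=interval_reactions,
        )
        audit.append("computed 13C FVA intervals")
    return result


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class CofactorBalance:
    metabolite_id: str
    producers: list[tuple[str, float, tuple[float, float] | None]]
    consumers: list[tuple[str, float, tuple[float, float] | None]]

    @property
    def total_production(self) -> float:
        return sum(f for _, f, _ in self.producers)

    @property
    def total_consumption(self) -> float:
        return sum(f for _, f, _ in self.consumers)

    def production_shares(self) -> dict[str, float]:
        tot = self.total_production
        return {r: f / tot for r, f, _ in self.producers} if tot else {}

    def consumption_shares(self) -> dict[str, float]:
        tot = self.total_consumption
        return {r: f / tot for r, f, _ in self.consumers} if tot else {}


def cofactor_balance(
    model: StoichiometricModel,
    fluxes: dict[str, float],
    metabolite_id: str,
    intervals: dict[str, FluxInterval] | None = None,
    tol: float = 1e-9,
) -> CofactorBalance:
    """Partition reactions into producers and consumers of a metabolite by
    their signed stoichiometric contribution at the fitted fluxes."""
    if metabolite_id not in model.metabolite_ids:
        raise KeyError(f"metabolite {metabolite_id} not in model")
    i = model.met_index(metabolite_id)
    S = model.S
    producers, consumers = [], []
    for rid in model.reaction_ids:
        s = S[i, model.rxn_index(rid)]
        if not s:
            continue
        contrib = s * fluxes.get(rid, 0.0)
        iv = None
        if intervals and rid in intervals:
            raw = intervals[rid]
            lo, hi = sorted((s * raw.v_min, s * raw.v_max))
            iv = (lo, hi)
        if contrib > tol:
            producers.append((rid, contrib, iv))
        elif contrib < -tol:
            consumers.append((rid, -contrib, iv))
    producers.sort(key=lambda t: -t[1])
    consumers.sort(key=lambda t: -t[1])
    return CofactorBalance(metabolite_id, producers, consumers)


def exchange_prediction(
    model: StoichiometricModel,
    intervals: dict[str, FluxInterval],
    measured_reactions: set[str] | None = None,
) -> pd.DataFrame:
    """Rank unmeasured exchanged metabolites expected in the medium: those
    whose exchange-flux interval has strictly positive minimum and maximum
    (net excretion under every flux profile compatible with the data)."""
    measured_reactions = measured_reactions or set()
    rows = []
    for rid in sorted(model.exchange_reactions):
        if rid in measured_reactions or rid not in intervals:
            continue
        iv = intervals[rid]
        rxn = model.reaction(rid)
        boundary_mets = [
            m for m in rxn.stoichiometry if model.metabolite(m).boundary
        ]
        # sign convention: positive flux excretes iff the boundary species
        # is a product
        sign = 1.0 if all(rxn.stoichiometry[m] > 0 for m in boundary_mets) else -1.0
        lo, hi = sorted((sign * iv.v_min, sign * iv.v_max))
        rows.append(
            {
                "reaction_id": rid,
                "metabolites": ";".join(boundary_mets),
                "excretion_min": lo,
                "excretion_max": hi,
                "expected_in_medium": lo > 0 and hi > 0,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("excretion_min", ascending=False).reset_index(drop=True)
    return df
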