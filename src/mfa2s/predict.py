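"""Knockout flux and labeling prediction.

Implements the COBRA prediction battery used to benchmark flux methods:
FBA maximizing growth or ATP production, MOMA (minimization of metabolic
adjustment, a convex QP), ROOM (regulatory on/off minimization, a MILP),
and their 13C-referenced variants, which run the same objectives against a
reference flux profile obtained from a two-scale 13C fit instead of an FBA
solution.  Predicted flux profiles can then be pushed through the EMU
simulator to predict the labeling a knockout experiment would measure,
scored with the same OF statistic as the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp, minimize

from . import lp
from .emu import decompose, make_emu
from .fit import TwoScaleProgram, compute_of
from .model import (
    AtomTransitionTable,
    FeedSpec,
    LabelingDataset,
    StoichiometricModel,
)
from .partition import CorePartition

log = logging.getLogger(__name__)

__all__ = [
    "ReferenceProfile",
    "PredictionResult",
    "knockout",
    "predict_fluxes",
    "predict_labeling",
]

#: published ROOM significance thresholds (relative, absolute)
ROOM_DELTA = 0.03
ROOM_EPSILON = 0.001


@dataclass
class ReferenceProfile:
    """A flux profile used as the adjustment reference for MOMA/ROOM."""

    fluxes: dict[str, float]
    provenance: str  # "fba" or "2s13c-fit"
    fit_id: str = ""


@dataclass
class PredictionResult:
    method: str
    fluxes: dict[str, float]
    mode: str = "full"
    partial_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective_value: float | None = None
    mdvs: list[np.ndarray] | None = None
    of: float | None = None
    gap: float | None = None  # MILP gap for ROOM


def knockout(model: StoichiometricModel, targets: list[str]) -> StoichiometricModel:
    """Zero out the named reactions (or every reaction whose gene rule
    mentions a named gene)."""
    out = model.copy()
    for t in targets:
        hits = []
        if out.has_reaction(t):
            hits = [t]
        else:
            hits = [r.id for r in out.reactions if t and t in (r.genes or "")]
        if not hits:
            raise KeyError(f"unknown knockout target {t}")
        for rid in hits:
            r = out.reaction(rid)
            r.lb, r.ub = 0.0, 0.0
    return out


def _moma(model: StoichiometricModel, v_ref: dict[str, float]) -> dict[str, float]:
    """min ||v - v_ref||^2 s.t. S v = 0, bounds: solved as a QP by SLSQP
    with analytic gradient."""
    A, _ = model.balance_matrix()
    lb, ub = model.bounds_array()
    ref = np.array([v_ref.get(rid, 0.0) for rid in model.reaction_ids])
    x0 = np.clip(ref, lb, ub)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    rank = int(np.sum(s > max(A.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)))
    R = vt[:rank]
    cons = [{"type": "eq", "fun": lambda x: R @ x, "jac": lambda x: R}]
    res = minimize(
        lambda x: float(np.sum((x - ref) ** 2)),
        x0,
        jac=lambda x: 2.0 * (x - ref),
        method="SLSQP",
        bounds=list(zip(lb, ub)),
        constraints=cons,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if np.abs(A @ res.x).max() > 1e-6:
        raise RuntimeError(f"MOMA QP failed: {res.message}")
    return {rid: float(v) for rid, v in zip(model.reaction_ids, res.x)}


def _room(
    model: StoichiometricModel,
    v_ref: dict[str, float],
    delta: float = ROOM_DELTA,
    epsilon: float = ROOM_EPSILON,
) -> tuple[dict[str, float], float]:
    """min number of significantly changed fluxes, as a MILP.

    Flux j counts as changed iff it leaves
    [v_ref - delta*|v_ref| - epsilon, v_ref + delta*|v_ref| + epsilon].
    """
    n = len(model.reactions)
    A, _ = model.balance_matrix()
    lb, ub = model.bounds_array()
    ref = np.array([v_ref.get(rid, 0.0) for rid in model.reaction_ids])
    w_u = ref + delta * np.abs(ref) + epsilon
    w_l = ref - delta * np.abs(ref) - epsilon
    # variables: [v (n), y (n binary)]
    c = np.concatenate([np.zeros(n), np.ones(n)])
    cons = [
        LinearConstraint(np.hstack([A, np.zeros((A.shape[0], n))]), 0.0, 0.0)
    ]
    # v_j - y_j (ub_j - w_u_j) <= w_u_j
    M1 = np.hstack([np.eye(n), -np.diag(ub - w_u)])
    cons.append(LinearConstraint(M1, -np.inf, w_u))
    # v_j + y_j (w_l_j - lb_j) >= w_l_j
    M2 = np.hstack([np.eye(n), np.diag(w_l - lb)])
    cons.append(LinearConstraint(M2, w_l, np.inf))
    integrality = np.concatenate([np.zeros(n), np.ones(n)])
    bounds_lo = np.concatenate([lb, np.zeros(n)])
    bounds_hi = np.concatenate([ub, np.ones(n)])
    from scipy.optimize import Bounds

    res = milp(
        c,
        constraints=cons,
        integrality=integrality,
        bounds=Bounds(bounds_lo, bounds_hi),
        options={"time_limit": 60},
    )
    if res.status not in (0, 1) or res.x is None:
        raise RuntimeError(f"ROOM MILP failed: {res.message}")
    fluxes = {rid: float(v) for rid, v in zip(model.reaction_ids, res.x[:n])}
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    return fluxes, gap


def predict_fluxes(
    model_ko: StoichiometricModel,
    method: str,
    reference: ReferenceProfile | None = None,
    mode: str = "full",
    partial_bounds: dict[str, tuple[float, float]] | None = None,
    atp_reaction: str | None = None,
) -> PredictionResult:
    """Predict the knockout flux profile.

    full mode uses no measurement from the target experiment (substrate
    bounds carried over from the reference condition are assumed already on
    the model); partial mode additionally clamps the given reactions to
    measured target values.
    """
    model = model_ko.copy()
    applied: dict[str, tuple[float, float]] = {}
    if mode == "partial":
        for rid, (lo, hi) in (partial_bounds or {}).items():
            r = model.reaction(rid)
            r.lb, r.ub = max(r.lb, lo), min(r.ub, hi)
            applied[rid] = (lo, hi)
    elif partial_bounds:
        raise ValueError("partial_bounds given but mode is 'full'")

    if method in ("13c-moma", "13c-room"):
        if reference is None or reference.provenance != "2s13c-fit":
            raise ValueError(f"{method} requires a 2s13c-fit reference profile")
    if method in ("moma", "room") and reference is None:
        raise ValueError(f"{method} requires a reference profile")

    gap = None
    if method == "fba-growth":
        if model.biomass_reaction is None:
            raise ValueError("fba-growth needs a biomass reaction")
        res = lp.fba(model, model.biomass_reaction, "max")
        if not res.feasible:
            raise RuntimeError("knockout model infeasible under FBA")
        fluxes, obj = res.fluxes, res.objective_value
    elif method == "fba-atp":
        rid = atp_reaction
        if rid is None:
            raise ValueError("fba-atp needs the ATP maintenance reaction id")
        res = lp.fba(model, rid, "max")
        if not res.feasible:
            raise RuntimeError("knockout model infeasible under FBA")
        fluxes, obj = res.fluxes, res.objective_value
    elif method in ("moma", "13c-moma"):
        fluxes = _moma(model, reference.fluxes)
        obj = float(
            sum((fluxes[r] - reference.fluxes.get(r, 0.0)) ** 2 for r in fluxes)
        )
    elif method in ("room", "13c-room"):
        fluxes, gap = _room(model, reference.fluxes)
        obj = None
    else:
        raise ValueError(f"unknown prediction method {method!r}")
    return PredictionResult(
        method=method,
        fluxes=fluxes,
        mode=mode,
        partial_bounds=applied,
        objective_value=obj,
        gap=gap,
    )


def predict_labeling(
    prediction: PredictionResult,
    model: StoichiometricModel,
    partition: CorePartition,
    transitions: AtomTransitionTable,
    feed: FeedSpec,
    dataset_target: LabelingDataset,
) -> PredictionResult:
    """Simulate the labeling the predicted flux profile implies and score
    it against the target experiment's measurements.

    Net fluxes are split with zero exchange (LP/QP predictions carry no
    exchange information).
    """
    from .fluxes import split_reversible

    splitsys = split_reversible(model, partition.core_reactions)
    trans = splitsys.split_transitions(transitions)
    fluxes: dict[str, float] = {}
    for rid, (f, b) in splitsys.pairs.items():
        v = prediction.fluxes.get(rid, 0.0)
        fluxes[f] = max(v, 0.0)
        if b is not None:
            fluxes[b] = max(-v, 0.0)
    carbons = {m.id: m.n_carbons for m in model.metabolites}
    measured = []
    for meas in dataset_target.mdv_measurements:
        atoms = meas.atoms or tuple(range(1, carbons[meas.metabolite_id] + 1))
        measured.append(make_emu(meas.metabolite_id, atoms))
    net = decompose(trans, measured, {feed.substrate_id: feed.n_carbons}, carbons)
    mdv = net.simulate(fluxes, {feed.substrate_id: feed.isotopomer_distribution()})
    sims = [mdv[e] for e in measured]
    of, _ = compute_of(sims, dataset_target)
    prediction.mdvs = sims
    prediction.of = of
    return prediction
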