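"""Linear-programming layer: FBA and FVA over a :class:`StoichiometricModel`.

Solved with HiGHS through :func:`scipy.optimize.linprog` behind a minimal
solve contract (status flag, primal values, objective), so the engine is
swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import StoichiometricModel

__all__ = ["FBAResult", "FluxInterval", "fba", "feasible", "fva", "dump_lp"]


@dataclass
class FBAResult:
    feasible: bool
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None
    status: str = ""


@dataclass
class FluxInterval:
    """[v_min, v_max] for one reaction under one constraint mode."""

    reaction_id: str
    v_min: float
    v_max: float
    mode: str = ""
    flagged: bool = False

    @property
    def width(self) -> float:
        return self.v_max - self.v_min


def _bounds(model: StoichiometricModel, extra_bounds: dict[str, tuple[float, float]] | None):
    lb, ub = model.bounds_array()
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.rxn_index(rid)
            lb[j] = max(lb[j], lo)
            ub[j] = min(ub[j], hi)
    return lb, ub


def _solve(model, c, lb, ub):
    A_eq, _ = model.balance_matrix()
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res


def fba(
    model: StoichiometricModel,
    objective: str | None = None,
    sense: str = "max",
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> FBAResult:
    """Optimize one reaction's flux (or just test feasibility when
    ``objective`` is None) subject to S v = 0 and bounds."""
    lb, ub = _bounds(model, extra_bounds)
    if np.any(lb > ub + 1e-12):
        return FBAResult(False, status="inconsistent bounds")
    c = np.zeros(len(model.reactions))
    if objective is not None:
        c[model.rxn_index(objective)] = -1.0 if sense == "max" else 1.0
    res = _solve(model, c, lb, ub)
    if res.status != 0:
        return FBAResult(False, status=res.message)
    fluxes = {rid: float(v) for rid, v in zip(model.reaction_ids, res.x)}
    obj = float(res.x[model.rxn_index(objective)]) if objective is not None else 0.0
    return FBAResult(True, obj, fluxes, "optimal")


def feasible(
    model: StoichiometricModel,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> bool:
    return fba(model, None, extra_bounds=extra_bounds).feasible


def fva(
    model: StoichiometricModel,
    reactions: list[str] | None = None,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    fixed_fraction: tuple[str, float] | None = None,
    mode: str = "",
) -> list[FluxInterval]:
    """Per-reaction flux ranges [min, max] under S v = 0 and bounds.

    ``fixed_fraction = (objective_id, gamma)`` additionally pins the named
    reaction to at least gamma times its optimum before scanning.
    """
    lb, ub = _bounds(model, extra_bounds)
    if np.any(lb > ub + 1e-12):
        raise ValueError("infeasible bounds in FVA")
    if fixed_fraction is not None:
        oid, gamma = fixed_fraction
        opt = fba(model, oid, "max", extra_bounds)
        if not opt.feasible:
            raise ValueError("FVA reference optimum infeasible")
        j = model.rxn_index(oid)
        lb[j] = max(lb[j], gamma * opt.objective_value)
    reactions = reactions if reactions is not None else model.reaction_ids
    out = []
    for rid in reactions:
        c = np.zeros(len(model.reactions))
        c[model.rxn_index(rid)] = 1.0
        lo = _solve(model, c, lb, ub)
        hi = _solve(model, -c, lb, ub)
        if lo.status != 0 or hi.status != 0:
            raise ValueError(f"FVA infeasible for {rid}: {lo.message} / {hi.message}")
        out.append(
            FluxInterval(
                rid,
                float(lo.x[model.rxn_index(rid)]),
                float(hi.x[model.rxn_index(rid)]),
                mode=mode,
            )
        )
    return out


def dump_lp(
    model: StoichiometricModel,
    objective: str | None = None,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> str:
    """LP-format text of the FBA problem, for debugging."""
    lb, ub = _bounds(model, extra_bounds)
    lines = ["\\ FBA problem for " + model.id, "Maximize", f" obj: {objective or '0'}"]
    lines.append("Subject To")
    A, met_ids = model.balance_matrix()
    for i, mid in enumerate(met_ids):
        terms = [
            f"{'+' if A[i, j] >= 0 else '-'} {abs(A[i, j]):g} {rid}"
            for j, rid in enumerate(model.reaction_ids)
            if A[i, j]
        ]
        if terms:
            lines.append(f" {mid}: " + " ".join(terms) + " = 0")
    lines.append("Bounds")
    for j, rid in enumerate(model.reaction_ids):
        lines.append(f" {lb[j]:g} <= {rid} <= {ub[j]:g}")
    lines.append("End")
    return "\n".join(lines)
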