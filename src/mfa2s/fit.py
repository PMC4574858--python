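"""The two-scale 13C-MFA data fit.

Finds the genome-scale flux vector that best reproduces the measured
mass-distribution vectors, subject to full-network stoichiometry (S v = 0),
flux bounds carrying the measured extracellular rates and growth interval,
and steady-state EMU labeling balances over the core reaction set.

The problem is solved in reduced form: the decision variables are the
nonnegative split core fluxes plus the net fluxes of all non-core
reactions; the EMU cascade is solved exactly (linear algebra) inside the
objective, so labeling never appears as an explicit nonlinear constraint.
Stoichiometry and bounds stay as linear constraints handled by SLSQP, and
the nonconvexity in the fluxes is addressed by multistart from random
interior points of the flux polytope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog, minimize

from .emu import EMU, EMUSimulationError, decompose, make_emu
from .fluxes import SplitFluxSystem, SplitFluxVector, split_reversible
from .model import (
    AtomTransitionTable,
    FeedSpec,
    LabelingDataset,
    StoichiometricModel,
)
from .partition import CorePartition

log = logging.getLogger(__name__)

__all__ = ["TwoScaleProgram", "FitResult", "compute_of", "fit"]

#: objective value returned when a trial point makes the EMU system singular
PENALTY_OF = 1.0e6


def compute_of(
    simulated: list[np.ndarray], dataset: LabelingDataset
) -> tuple[float, float]:
    """Fit statistic OF and the sum of squared residuals SSR.

    OF is the average over measured EMUs of the per-EMU mean squared
    deviation between simulated and measured MDV elements, in units of the
    experimental error: OF = mean_e [ mean_m ((f_exp - f)/Delta)^2 ].
    """
    if len(simulated) != len(dataset.mdv_measurements):
        raise ValueError("simulated MDVs do not match the measurement list")
    per_emu = []
    ssr = 0.0
    for f_sim, meas in zip(simulated, dataset.mdv_measurements):
        if np.any(meas.delta == 0):
            raise ValueError(f"{meas.metabolite_id}: zero measurement error")
        z = (meas.f_exp - np.asarray(f_sim)) / meas.delta
        per_emu.append(float(np.mean(z**2)))
        ssr += float(np.sum(z**2))
    return float(np.mean(per_emu)), ssr


class TwoScaleProgram:
    """Shared constraint/objective assembly for the fit and for 13C FVA.

    Variables: x = [u_l for split core fluxes (absolute, >= 0)] ++
    [v_j for non-core reactions].  Net core fluxes are recovered through
    v_j = u_f - u_b.
    """

    def __init__(
        self,
        model: StoichiometricModel,
        partition: CorePartition,
        transitions: AtomTransitionTable,
        dataset: LabelingDataset,
        feed: FeedSpec,
        exchange_cap_factor: float = 10.0,
    ) -> None:
        self.model = model
        self.partition = partition
        self.dataset = dataset
        self.feed = feed
        self.splitsys: SplitFluxSystem = split_reversible(model, partition.core_reactions)
        self.glucupt = self.splitsys.glucupt
        self.split_transitions = self.splitsys.split_transitions(transitions)

        carbons = {m.id: m.n_carbons for m in model.metabolites}
        self.measured_emus: list[EMU] = []
        for meas in dataset.mdv_measurements:
            atoms = meas.atoms or tuple(range(1, carbons[meas.metabolite_id] + 1))
            self.measured_emus.append(make_emu(meas.metabolite_id, atoms))
        self.network = decompose(
            self.split_transitions,
            self.measured_emus,
            {feed.substrate_id: feed.n_carbons},
            carbons,
        )
        self.feed_iso = feed.isotopomer_distribution()

        # variable layout
        self.split_ids = list(self.splitsys.split_ids)
        self.noncore_ids = [
            rid for rid in model.reaction_ids if not partition.is_core(rid)
        ]
        self.var_names = self.split_ids + self.noncore_ids
        n = len(self.var_names)

        cap = exchange_cap_factor * self.glucupt
        lo = np.zeros(n)
        hi = np.zeros(n)
        for k, lid in enumerate(self.split_ids):
            rid, sign = self.splitsys.parent_of(lid)
            rxn = model.reaction(rid)
            f, b = self.splitsys.pairs[rid]
            if b is None:  # irreversible: the split flux is the net flux
                lo[k], hi[k] = max(rxn.lb, 0.0), rxn.ub
            elif sign > 0:
                lo[k], hi[k] = 0.0, max(rxn.ub, 0.0) + cap
            else:
                lo[k], hi[k] = 0.0, max(-rxn.lb, 0.0) + cap
        for k, rid in enumerate(self.noncore_ids, start=len(self.split_ids)):
            rxn = model.reaction(rid)
            lo[k], hi[k] = rxn.lb, rxn.ub
        self.lower, self.upper = lo, hi

        # linear mass balance: rows = internal metabolites, columns = x
        S = model.S
        bal_rows = [model.met_index(m) for m in model.internal_metabolite_ids]
        A = np.zeros((len(bal_rows), n))
        for k, lid in enumerate(self.split_ids):
            rid, sign = self.splitsys.parent_of(lid)
            A[:, k] = sign * S[bal_rows, model.rxn_index(rid)]
        for k, rid in enumerate(self.noncore_ids, start=len(self.split_ids)):
            A[:, k] = S[bal_rows, model.rxn_index(rid)]
        self.A_eq = A
        # orthonormal basis of the row space: equivalent equality system
        # without redundant rows (SLSQP requires independent constraints)
        if A.size:
            _, s, vt = np.linalg.svd(A, full_matrices=False)
            rank = int(np.sum(s > max(A.shape) * np.finfo(float).eps * (s[0] if len(s) else 1.0)))
            self.A_eq_reduced = vt[:rank]
        else:
            self.A_eq_reduced = A

        # net-flux bounds for split reversible core reactions
        rows_ub, rhs_ub = [], []
        for rid, (f, b) in self.splitsys.pairs.items():
            if b is None:
                continue
            rxn = model.reaction(rid)
            row = np.zeros(n)
            row[self.var_names.index(f)] = 1.0
            row[self.var_names.index(b)] = -1.0
            rows_ub.append(row)
            rhs_ub.append(rxn.ub)
            rows_ub.append(-row)
            rhs_ub.append(-rxn.lb)
        self.A_ub = np.array(rows_ub) if rows_ub else np.zeros((0, n))
        self.b_ub = np.array(rhs_ub) if rhs_ub else np.zeros(0)

    # -- conversions ----------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def split_values(self, x: np.ndarray) -> dict[str, float]:
        return {lid: max(float(x[k]), 0.0) for k, lid in enumerate(self.split_ids)}

    def net_fluxes(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for rid, (f, b) in self.splitsys.pairs.items():
            v = float(x[self.var_names.index(f)])
            if b is not None:
                v -= float(x[self.var_names.index(b)])
            out[rid] = v
        for k, rid in enumerate(self.noncore_ids, start=len(self.split_ids)):
            out[rid] = float(x[k])
        return out

    def net_objective_row(self, rid: str) -> np.ndarray:
        """Linear row c with c . x = v_rid."""
        c = np.zeros(self.n_vars)
        if self.partition.is_core(rid):
            f, b = self.splitsys.pairs[rid]
            c[self.var_names.index(f)] = 1.0
            if b is not None:
                c[self.var_names.index(b)] = -1.0
        else:
            c[self.var_names.index(rid)] = 1.0
        return c

    # -- labeling -------------------------------------------------------
    def simulate_measurements(self, x: np.ndarray) -> list[np.ndarray]:
        mdv = self.network.simulate(
            self.split_values(x), {self.feed.substrate_id: self.feed_iso}
        )
        return [mdv[e] for e in self.measured_emus]

    def objective(self, x: np.ndarray) -> float:
        try:
            sim = self.simulate_measurements(x)
        except EMUSimulationError:
            return PENALTY_OF
        return compute_of(sim, self.dataset)[0]

    # -- feasible points ------------------------------------------------
    def constraints(self):
        R = self.A_eq_reduced
        cons = [{"type": "eq", "fun": lambda x: R @ x, "jac": lambda x: R}]
        if len(self.b_ub):
            cons.append(
                {
                    "type": "ineq",
                    "fun": lambda x: self.b_ub - self.A_ub @ x,
                    "jac": lambda x: -self.A_ub,
                }
            )
        return cons

    def random_vertex(self, rng: np.random.Generator) -> np.ndarray:
        c = rng.standard_normal(self.n_vars)
        res = linprog(
            c,
            A_eq=self.A_eq,
            b_eq=np.zeros(self.A_eq.shape[0]),
            A_ub=self.A_ub if len(self.b_ub) else None,
            b_ub=self.b_ub if len(self.b_ub) else None,
            bounds=list(zip(self.lower, self.upper)),
            method="highs",
        )
        if res.status != 0:
            raise RuntimeError(f"no feasible flux sample: {res.message}")
        return res.x

    def analytic_center(self) -> np.ndarray:
        """A max-slack point of the flux polytope: maximizes the smallest
        relative distance to the variable bounds subject to the linear
        constraints (variables with pinned bounds are exempt)."""
        if getattr(self, "_center", None) is not None:
            return self._center
        n = self.n_vars
        w = self.upper - self.lower  # per-variable slack scale
        c = np.zeros(n + 1)
        c[-1] = -1.0  # maximize s
        A_eq = np.hstack([self.A_eq, np.zeros((self.A_eq.shape[0], 1))])
        rows, rhs = [], []
        for j in range(n):
            if w[j] <= 0:
                continue
            r = np.zeros(n + 1)
            r[j], r[-1] = -1.0, w[j]
            rows.append(r)  # lb_j + s*w_j <= x_j
            rhs.append(-self.lower[j])
            r = np.zeros(n + 1)
            r[j], r[-1] = 1.0, w[j]
            rows.append(r)  # x_j <= ub_j - s*w_j
            rhs.append(self.upper[j])
        if len(self.b_ub):
            A_extra = np.hstack([self.A_ub, np.zeros((self.A_ub.shape[0], 1))])
            rows.extend(A_extra)
            rhs.extend(self.b_ub)
        res = linprog(
            c,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]),
            A_ub=np.array(rows),
            b_ub=np.array(rhs),
            bounds=[(lo, hi) for lo, hi in zip(self.lower, self.upper)] + [(0, 0.5)],
            method="highs",
        )
        if res.status != 0:
            raise RuntimeError(f"no feasible interior point: {res.message}")
        self._center = res.x[:-1]
        return self._center

    def interior_start(self, rng: np.random.Generator, n_mix: int = 3) -> np.ndarray:
        """Random interior point: a blend of the max-slack center with a
        Dirichlet mixture of random vertices.

        Strictly interior starts keep every carbon route active, which the
        EMU balance needs, and avoid parking unidentifiable flux directions
        at their bounds.
        """
        verts = [self.random_vertex(rng) for _ in range(n_mix)]
        w = rng.dirichlet(np.ones(n_mix))
        mix = np.einsum("i,ij->j", w, np.array(verts))
        return 0.5 * self.analytic_center() + 0.5 * mix

    def max_violation(self, x: np.ndarray) -> float:
        v = float(np.abs(self.A_eq @ x).max()) if self.A_eq.size else 0.0
        if len(self.b_ub):
            v = max(v, float((self.A_ub @ x - self.b_ub).max()))
        v = max(v, float((self.lower - x).max()), float((x - self.upper).max()))
        return v


@dataclass
class FitResult:
    """Best-of-N-restarts solution of the two-scale fit."""

    fluxes: dict[str, float]  # net fluxes v_j over all reactions
    split: SplitFluxVector  # split core fluxes, normalized to glucupt
    mdvs: list[np.ndarray]  # simulated MDVs, aligned with the dataset
    of: float
    ssr: float
    restart_log: list[dict] = field(default_factory=list)
    x: np.ndarray | None = None  # raw variable vector (warm starts)
    epsilon: list[np.ndarray] = field(default_factory=list)  # |f_fit - f_exp|

    def to_dict(self) -> dict:
        return {
            "of": self.of,
            "ssr": self.ssr,
            "fluxes": self.fluxes,
            "split_fluxes": self.split.values,
            "glucupt": self.split.glucupt,
            "restarts": self.restart_log,
        }


def fit(
    program: TwoScaleProgram,
    n_restarts: int = 10,
    seed: int = 0,
    maxiter: int = 300,
    ftol: float = 1e-10,
) -> FitResult:
    """Multistart SLSQP fit; the restart with the lowest objective wins.

    Restart k draws its starting point from a generator seeded with
    (master seed, k), so individual restarts are reproducible.
    """
    best_x = None
    best_of = np.inf
    restart_log: list[dict] = []
    for k in range(n_restarts):
        rng = np.random.default_rng([seed, k])
        try:
            x0 = program.interior_start(rng)
        except RuntimeError as exc:
            restart_log.append({"restart": k, "status": f"no start: {exc}"})
            continue
        res = minimize(
            program.objective,
            x0,
            method="SLSQP",
            bounds=list(zip(program.lower, program.upper)),
            constraints=program.constraints(),
            options={"maxiter": maxiter, "ftol": ftol},
        )
        viol = program.max_violation(res.x)
        entry = {
            "restart": k,
            "of": float(res.fun),
            "status": res.message,
            "violation": viol,
        }
        restart_log.append(entry)
        if viol < 1e-6 and np.isfinite(res.fun) and res.fun < best_of:
            best_of = float(res.fun)
            best_x = res.x.copy()
    if best_x is None:
        raise RuntimeError(
            f"no restart converged to a feasible point; log: {restart_log}"
        )
    sim = program.simulate_measurements(best_x)
    of, ssr = compute_of(sim, program.dataset)
    eps = [
        np.abs(np.asarray(f) - meas.f_exp)
        for f, meas in zip(sim, program.dataset.mdv_measurements)
    ]
    split = SplitFluxVector.from_absolute(program.split_values(best_x), program.glucupt)
    return FitResult(
        fluxes=program.net_fluxes(best_x),
        split=split,
        mdvs=[np.asarray(f) for f in sim],
        of=of,
        ssr=ssr,
        restart_log=restart_log,
        x=best_x,
        epsilon=eps,
    )
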