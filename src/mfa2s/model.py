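"""Core data structures for two-scale 13C metabolic flux analysis.

A :class:`StoichiometricModel` is a lightweight constraint-based model:
metabolites, reactions with flux bounds, a designated biomass reaction and a
designated substrate-uptake reaction.  Carbon labeling is described
separately, by an :class:`AtomTransitionTable` that assigns letter-coded
carbon maps (``abc --> ab + c``) to the subset of reactions over which
labeling is tracked (the *core*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "AtomMap",
    "AtomTransition",
    "AtomTransitionTable",
    "MDVMeasurement",
    "LabelingDataset",
    "FeedSpec",
    "ModelValidationError",
]


class ModelValidationError(ValueError):
    """Raised when a model, atom map or dataset violates its invariants."""


@dataclass
class Metabolite:
    """A chemical species.

    ``n_carbons`` may be 0 for carbon-free cofactors (ATP, NADPH, ...).
    ``boundary`` marks species that sit outside the mass balance (feed
    substrate, secreted products, biomass sink); their rows are excluded
    from the steady-state constraint S v = 0.
    """

    id: str
    n_carbons: int = 0
    name: str = ""
    compartment: str = "c"
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise ModelValidationError(f"metabolite {self.id}: negative carbon count")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds (mmol/gdw/h)."""

    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = 500.0
    name: str = ""
    genes: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id}: lb {self.lb} > ub {self.ub}"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


class StoichiometricModel:
    """A (possibly genome-scale) stoichiometric model.

    Parameters
    ----------
    metabolites, reactions:
        Model contents; ids must be unique.
    biomass_reaction:
        Id of the growth reaction (growth-rate bounds are applied to it).
    substrate_uptake_reaction:
        Id of the reaction through which all substrate enters (glucose
        transport in the organism studied here); the substrate uptake rate
        *glucupt* used to normalize split fluxes is read off its bounds.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        biomass_reaction: str | None = None,
        substrate_uptake_reaction: str | None = None,
        id: str = "model",
    ) -> None:
        self.id = id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id} references undeclared metabolite {m}"
                    )
        if biomass_reaction is not None and biomass_reaction not in self._rxn_index:
            raise ModelValidationError(f"biomass reaction {biomass_reaction} not in model")
        if (
            substrate_uptake_reaction is not None
            and substrate_uptake_reaction not in self._rxn_index
        ):
            raise ModelValidationError(
                f"substrate uptake reaction {substrate_uptake_reaction} not in model"
            )
        self.biomass_reaction = biomass_reaction
        self.substrate_uptake_reaction = substrate_uptake_reaction

    # -- lookup ---------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def met_index(self, mid: str) -> int:
        return self._met_index[mid]

    def rxn_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_reactions(self) -> set[str]:
        """Reactions that move matter across the system boundary."""
        out = set()
        for r in self.reactions:
            if any(self.metabolite(m).boundary for m in r.stoichiometry):
                out.add(r.id)
        return out

    # -- matrices -------------------------------------------------------
    @property
    def S(self) -> np.ndarray:
        """Full |I| x |J| stoichiometric matrix (boundary rows included)."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[self._met_index[m], j] = c
        return S

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.boundary]

    def balance_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Rows of S for internal metabolites, i.e. the S v = 0 constraint."""
        ids = self.internal_metabolite_ids
        rows = [self._met_index[m] for m in ids]
        return self.S[rows, :], ids

    def bounds_array(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions], dtype=float)
        ub = np.array([r.ub for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "StoichiometricModel":
        mets = [Metabolite(m.id, m.n_carbons, m.name, m.compartment, m.boundary) for m in self.metabolites]
        rxns = [
            Reaction(r.id, dict(r.stoichiometry), r.lb, r.ub, r.name, r.genes)
            for r in self.reactions
        ]
        return StoichiometricModel(
            mets, rxns, self.biomass_reaction, self.substrate_uptake_reaction, self.id
        )

    def glucose_uptake_rate(self) -> float:
        """Substrate uptake rate (midpoint of the uptake reaction's bounds)."""
        if self.substrate_uptake_reaction is None:
            raise ModelValidationError("no substrate uptake reaction designated")
        r = self.reaction(self.substrate_uptake_reaction)
        return 0.5 * (abs(r.lb) + abs(r.ub)) if r.lb * r.ub >= 0 else max(abs(r.lb), abs(r.ub))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<StoichiometricModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# atom transitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomMap:
    """One letter-coded carbon map for a reaction.

    ``reactants`` / ``products`` are ordered lists of ``(metabolite_id,
    letters)`` pairs, one entry per molecule *instance* (a coefficient of 2
    appears as two instances).  Every product letter must come from exactly
    one reactant letter; reactant letters missing from all products flow to
    untracked sinks.
    """

    reactants: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]

    def reversed(self) -> "AtomMap":
        return AtomMap(self.products, self.reactants)


@dataclass
class AtomTransition:
    """Carbon maps for one reaction; symmetric molecules contribute several
    equiprobable alternate maps."""

    reaction_id: str
    maps: list[AtomMap]

    @property
    def n_alternates(self) -> int:
        return len(self.maps)


class AtomTransitionTable:
    """Mapping reaction id -> :class:`AtomTransition`, validated against a model."""

    def __init__(self, entries: dict[str, AtomTransition] | None = None) -> None:
        self.entries: dict[str, AtomTransition] = dict(entries or {})

    def __contains__(self, rid: str) -> bool:
        return rid in self.entries

    def __getitem__(self, rid: str) -> AtomTransition:
        return self.entries[rid]

    def add(self, transition: AtomTransition) -> None:
        self.entries[transition.reaction_id] = transition

    def reaction_ids(self) -> list[str]:
        return list(self.entries)

    def validate(self, model: StoichiometricModel) -> None:
        for rid, tr in self.entries.items():
            if not model.has_reaction(rid):
                raise ModelValidationError(f"atom map for unknown reaction {rid}")
            rxn = model.reaction(rid)
            for am in tr.maps:
                seen: list[str] = []
                for mid, letters in am.reactants:
                    met = model.metabolite(mid)
                    if len(letters) != met.n_carbons:
                        raise ModelValidationError(
                            f"{rid}: reactant {mid} map '{letters}' has "
                            f"{len(letters)} letters, metabolite has {met.n_carbons} carbons"
                        )
                    seen.extend(letters)
                if len(set(seen)) != len(seen):
                    raise ModelValidationError(f"{rid}: duplicate reactant letters")
                prod_letters: list[str] = []
                for mid, letters in am.products:
                    met = model.metabolite(mid)
                    if len(letters) != met.n_carbons:
                        raise ModelValidationError(
                            f"{rid}: product {mid} map '{letters}' has "
                            f"{len(letters)} letters, metabolite has {met.n_carbons} carbons"
                        )
                    prod_letters.extend(letters)
                if len(set(prod_letters)) != len(prod_letters):
                    raise ModelValidationError(f"{rid}: product letter used twice")
                unknown = set(prod_letters) - set(seen)
                if unknown:
                    raise ModelValidationError(
                        f"{rid}: product letters {sorted(unknown)} have no reactant source"
                    )
                # instance counts must match stoichiometric coefficients for
                # carbon-bearing metabolites
                for side, entries in (("reactant", am.reactants), ("product", am.products)):
                    counts: dict[str, int] = {}
                    for mid, _ in entries:
                        counts[mid] = counts.get(mid, 0) + 1
                    for mid, n in counts.items():
                        coeff = abs(rxn.stoichiometry.get(mid, 0.0))
                        if coeff and not math.isclose(coeff, n, abs_tol=1e-9):
                            raise ModelValidationError(
                                f"{rid}: {side} {mid} has {n} map instance(s) but "
                                f"stoichiometric coefficient {coeff}"
                            )


# ---------------------------------------------------------------------------
# measurements and feed
# ---------------------------------------------------------------------------

@dataclass
class MDVMeasurement:
    """A measured mass-distribution vector for one metabolite (full-carbon
    EMU by default), with per-element measurement errors Delta."""

    metabolite_id: str
    f_exp: np.ndarray
    delta: np.ndarray
    atoms: tuple[int, ...] | None = None  # 1-based carbon positions; None = all

    def __post_init__(self) -> None:
        self.f_exp = np.asarray(self.f_exp, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.f_exp.shape != self.delta.shape:
            raise ModelValidationError(
                f"{self.metabolite_id}: f_exp and delta lengths differ"
            )
        if np.any(self.delta <= 0):
            raise ModelValidationError(f"{self.metabolite_id}: Delta must be > 0")
        if np.any((self.f_exp < -1e-12) | (self.f_exp > 1 + 1e-12)):
            raise ModelValidationError(f"{self.metabolite_id}: f outside [0, 1]")

    @property
    def size(self) -> int:
        return len(self.f_exp) - 1


@dataclass
class LabelingDataset:
    """Measured MDVs plus extracellular-flux and growth-rate intervals."""

    mdv_measurements: list[MDVMeasurement]
    extracellular_measurements: list[tuple[str, float, float]] = field(default_factory=list)
    growth_rate: tuple[float, float] | None = None

    def normalize(self, tolerance: float = 0.05) -> list[tuple[str, float]]:
        """Rescale each MDV to sum to 1; returns the applied factors.

        Deviations beyond ``tolerance`` (relative) are rejected.
        """
        factors = []
        for m in self.mdv_measurements:
            s = float(m.f_exp.sum())
            if abs(s - 1.0) > tolerance:
                raise ModelValidationError(
                    f"{m.metabolite_id}: MDV sums to {s:.4f}, beyond tolerance"
                )
            if abs(s - 1.0) > 1e-6:
                m.f_exp = m.f_exp / s
                factors.append((m.metabolite_id, 1.0 / s))
        return factors

    def measurement(self, mid: str) -> MDVMeasurement:
        for m in self.mdv_measurements:
            if m.metabolite_id == mid:
                return m
        raise KeyError(mid)

    @property
    def measured_metabolites(self) -> list[str]:
        return [m.metabolite_id for m in self.mdv_measurements]


@dataclass
class FeedSpec:
    """Isotopic composition of the feed substrate.

    ``components`` is a list of ``(pattern, fraction)`` where ``pattern`` is a
    positional 13C string such as ``"1100"`` ([1,2-13C]) and fractions sum
    to 1.
    """

    substrate_id: str
    components: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ModelValidationError("feed needs at least one component")
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ModelValidationError(f"feed fractions sum to {total}, expected 1")
        n = len(self.components[0][0])
        for p, _ in self.components:
            if len(p) != n or set(p) - {"0", "1"}:
                raise ModelValidationError(f"bad feed pattern '{p}'")

    @property
    def n_carbons(self) -> int:
        return len(self.components[0][0])

    def isotopomer_distribution(self) -> np.ndarray:
        """Distribution over positional isotopomers, indexed by bitmask
        (bit k set = carbon position k+1 is 13C)."""
        dist = np.zeros(2 ** self.n_carbons)
        for pattern, frac in self.components:
            mask = 0
            for k, ch in enumerate(pattern):
                if ch == "1":
                    mask |= 1 << k
            dist[mask] += frac
        return dist
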