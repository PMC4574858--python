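"""Reversible-flux splitting and the core/genome-scale flux mapping.

Every reversible core reaction j is represented by a nonnegative
forward/backward pair (``j_f``, ``j_b``); irreversible core reactions keep
a single split flux under their own id.  Net fluxes relate to split fluxes
through ``v_j = glucupt * (V_f - V_b)`` where V are split fluxes normalized
to the substrate uptake rate *glucupt*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import AtomMap, AtomTransition, AtomTransitionTable, StoichiometricModel

__all__ = ["SplitFluxSystem", "SplitFluxVector", "split_reversible", "map_split_to_net"]


@dataclass
class SplitFluxSystem:
    """The split-flux description of a core reaction set.

    ``pairs`` maps each core reaction to its (forward, backward-or-None)
    split ids; ``map_sign`` carries the Eq-style mapping coefficients
    (+glucupt for forward, -glucupt for backward).  ``S_star`` has one
    column per split flux with the sign relation S*_il = +/- S_ij.
    """

    model: StoichiometricModel
    core_reactions: list[str]
    split_ids: list[str]
    pairs: dict[str, tuple[str, str | None]]
    glucupt: float

    @property
    def n_split(self) -> int:
        return len(self.split_ids)

    def split_index(self, lid: str) -> int:
        return self.split_ids.index(lid)

    @property
    def S_star(self) -> np.ndarray:
        S = self.model.S
        cols = []
        for lid in self.split_ids:
            rid, sign = self.parent_of(lid)
            cols.append(sign * S[:, self.model.rxn_index(rid)])
        return np.column_stack(cols)

    def parent_of(self, lid: str) -> tuple[str, float]:
        """(reaction id, +1 forward / -1 backward) for a split flux."""
        for rid, (f, b) in self.pairs.items():
            if lid == f:
                return rid, 1.0
            if lid == b:
                return rid, -1.0
        raise KeyError(lid)

    def map_sign(self, rid: str, lid: str) -> float:
        """map_jl: +glucupt if l is the forward version of j, -glucupt if
        backward, 0 otherwise."""
        f, b = self.pairs[rid]
        if lid == f:
            return self.glucupt
        if lid == b:
            return -self.glucupt
        return 0.0

    def split_transitions(self, table: AtomTransitionTable) -> dict[str, list[AtomMap]]:
        """Carbon maps per split flux; the backward direction uses the
        reversed maps."""
        out: dict[str, list[AtomMap]] = {}
        for rid, (f, b) in self.pairs.items():
            maps = table[rid].maps
            out[f] = list(maps)
            if b is not None:
                out[b] = [m.reversed() for m in maps]
        return out


@dataclass
class SplitFluxVector:
    """Nonnegative split fluxes, normalized to the substrate uptake rate."""

    values: dict[str, float]
    glucupt: float

    def __post_init__(self) -> None:
        for lid, v in self.values.items():
            if v < -1e-9:
                raise ValueError(f"split flux {lid} negative: {v}")

    def absolute(self) -> dict[str, float]:
        return {lid: v * self.glucupt for lid, v in self.values.items()}

    @classmethod
    def from_absolute(cls, values: Mapping[str, float], glucupt: float) -> "SplitFluxVector":
        return cls({lid: v / glucupt for lid, v in values.items()}, glucupt)


def split_reversible(
    model: StoichiometricModel,
    core_reactions: list[str],
    glucupt: float | None = None,
) -> SplitFluxSystem:
    """Build the forward/backward split-flux system for the core set."""
    if glucupt is None:
        glucupt = model.glucose_uptake_rate()
    split_ids: list[str] = []
    pairs: dict[str, tuple[str, str | None]] = {}
    for rid in core_reactions:
        rxn = model.reaction(rid)
        if rxn.reversible:
            pairs[rid] = (rid + "_f", rid + "_b")
            split_ids.extend([rid + "_f", rid + "_b"])
        else:
            pairs[rid] = (rid, None)
            split_ids.append(rid)
    return SplitFluxSystem(model, list(core_reactions), split_ids, pairs, glucupt)


def map_split_to_net(V: SplitFluxVector, system: SplitFluxSystem) -> dict[str, float]:
    """Net fluxes v_j = sum_l map_jl V_l for the core reactions."""
    out = {}
    for rid, (f, b) in system.pairs.items():
        if f not in V.values:
            raise KeyError(f"missing split flux {f}")
        v = system.glucupt * V.values[f]
        if b is not None:
            if b not in V.values:
                raise KeyError(f"missing split flux {b}")
            v -= system.glucupt * V.values[b]
        out[rid] = v
    return out
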