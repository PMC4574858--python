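"""Elementary Metabolite Unit (EMU) decomposition and steady-state MDV
simulation.

An EMU is a specific subset of a metabolite's carbon atoms.  The EMU method
reduces isotopomer balancing to a cascade of linear systems, one per EMU
size: the mass-distribution vector (MDV) of a size-k EMU depends only on
EMUs of size <= k, with condensation reactions entering through discrete
convolution of the source MDVs.

The balance convention used throughout is *production-weighted*: the MDV of
each tracked EMU is the flux-weighted mixture of the MDVs delivered by its
tracked producers.  For a metabolite whose tracked production equals its
tracked consumption this is exactly the standard steady-state EMU balance;
when part of the turnover is untracked (the two-scale setting, where small
non-core flows into the core are permitted), it amounts to assuming the
untracked inflow carries the same labeling as the tracked production mix.
External Labeling Variability Analysis bounds the worst-case error of that
assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .model import AtomMap, AtomTransition, ModelValidationError

__all__ = [
    "EMU",
    "EMUProducer",
    "EMUNetwork",
    "EMUSimulationError",
    "decompose",
    "convolve",
    "mdv_from_isotopomers",
]


class EMUSimulationError(RuntimeError):
    pass


class EMU(NamedTuple):
    """An EMU: metabolite id plus a canonical (sorted, 1-based) atom tuple."""

    metabolite: str
    atoms: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:  # e.g. "mal_1_2_3"
        return self.metabolite + "_" + "".join(str(a) for a in self.atoms)


def make_emu(metabolite: str, atoms: Iterable[int]) -> EMU:
    return EMU(metabolite, tuple(sorted(atoms)))


@dataclass(frozen=True)
class EMUProducer:
    """One production route into a target EMU.

    ``sources`` has one entry per contributing reactant molecule; more than
    one entry marks a condensation (the contribution is the convolution of
    the source MDVs).  ``weight`` is the map multiplicity factor (1/k for k
    equiprobable alternate maps of a symmetric molecule).
    """

    flux_id: str
    weight: float
    sources: tuple[EMU, ...]


def convolve(mdvs: list[np.ndarray]) -> np.ndarray:
    """Convolution of MDVs: the MDV of a molecule assembled from independent
    parts.  Output length is the sum of the part sizes plus one."""
    out = np.asarray(mdvs[0], dtype=float)
    for m in mdvs[1:]:
        out = np.convolve(out, np.asarray(m, dtype=float))
    return out


def mdv_from_isotopomers(dist: np.ndarray, atoms: tuple[int, ...], n_carbons: int) -> np.ndarray:
    """Marginal MDV of an atom subset, from a positional-isotopomer
    distribution indexed by bitmask (bit k = carbon k+1 labeled)."""
    atom_mask = 0
    for a in atoms:
        atom_mask |= 1 << (a - 1)
    mdv = np.zeros(len(atoms) + 1)
    for mask in range(2 ** n_carbons):
        p = dist[mask]
        if p:
            mdv[bin(mask & atom_mask).count("1")] += p
    return mdv


@dataclass
class EMUNetwork:
    """Size-ordered EMU balance system for a set of tracked metabolites.

    ``producers`` maps every non-input EMU to its production routes;
    ``production_counts`` gives, per metabolite, the number of product
    instances each split flux creates (the production-flux coefficient).
    ``input_metabolites`` (feed and any dummy inflow species) carry known or
    externally supplied isotopomer distributions.
    """

    producers: dict[EMU, list[EMUProducer]]
    production_counts: dict[str, dict[str, float]]
    input_metabolites: dict[str, int]  # id -> n_carbons
    measured: list[EMU]
    tracked_metabolites: set[str] = field(default_factory=set)

    # -- introspection --------------------------------------------------
    @property
    def emus(self) -> list[EMU]:
        return sorted(self.producers, key=lambda e: (e.size, e.metabolite, e.atoms))

    @property
    def levels(self) -> dict[int, list[EMU]]:
        out: dict[int, list[EMU]] = {}
        for e in self.emus:
            out.setdefault(e.size, []).append(e)
        return out

    @property
    def combined_emus(self) -> list[tuple[EMU, ...]]:
        """Source tuples of condensation routes (each simulated by Eq-6 style
        convolution of the member MDVs)."""
        out = []
        for terms in self.producers.values():
            for t in terms:
                if len(t.sources) > 1:
                    out.append(t.sources)
        return out

    def input_emus(self) -> set[EMU]:
        ins = set()
        for terms in self.producers.values():
            for t in terms:
                for s in t.sources:
                    if s.metabolite in self.input_metabolites:
                        ins.add(s)
        return ins

    # -- simulation -----------------------------------------------------
    def simulate(
        self,
        fluxes: Mapping[str, float],
        input_isotopomers: Mapping[str, np.ndarray],
        atol: float = 1e-10,
    ) -> dict[EMU, np.ndarray]:
        """Solve the steady-state EMU cascade at the given split fluxes.

        ``fluxes`` maps split-flux id -> nonnegative flux; ``input_isotopomers``
        maps each input metabolite to its positional-isotopomer distribution.
        Returns MDVs for every EMU in the network.
        """
        for lid, v in fluxes.items():
            if v < -1e-9:
                raise EMUSimulationError(f"negative split flux {lid} = {v}")
        missing = set(self.input_metabolites) - set(input_isotopomers)
        if missing:
            raise EMUSimulationError(f"no isotopomer distribution for inputs {sorted(missing)}")

        mdv: dict[EMU, np.ndarray] = {}

        def source_mdv(e: EMU) -> np.ndarray:
            if e.metabolite in self.input_metabolites:
                return mdv_from_isotopomers(
                    np.asarray(input_isotopomers[e.metabolite], dtype=float),
                    e.atoms,
                    self.input_metabolites[e.metabolite],
                )
            return mdv[e]

        for size, emus in sorted(self.levels.items()):
            n = len(emus)
            index = {e: i for i, e in enumerate(emus)}
            A = np.zeros((n, n))
            B = np.zeros((n, size + 1))
            for e, i in index.items():
                prod_total = sum(
                    fluxes.get(lid, 0.0) * cnt
                    for lid, cnt in self.production_counts.get(e.metabolite, {}).items()
                )
                if prod_total <= atol:
                    raise EMUSimulationError(
                        f"EMU {e} has zero tracked production; balance is singular"
                    )
                A[i, i] += prod_total
                for term in self.producers[e]:
                    v = fluxes.get(term.flux_id, 0.0) * term.weight
                    if v == 0.0:
                        continue
                    src = term.sources
                    if (
                        len(src) == 1
                        and src[0].metabolite not in self.input_metabolites
                        and src[0].size == size
                    ):
                        A[i, index[src[0]]] -= v
                    else:
                        B[i, :] += v * convolve([source_mdv(s) for s in src])
            try:
                X = np.linalg.solve(A, B)
            except np.linalg.LinAlgError as exc:
                raise EMUSimulationError(f"singular EMU balance at size {size}: {exc}")
            resid = A @ X - B
            if np.abs(resid).max() > 1e-10:  # one step of iterative refinement
                X = X + np.linalg.solve(A, B - A @ X)
            for e, i in index.items():
                row = np.clip(X[i], 0.0, None)
                s = row.sum()
                if not np.isfinite(s) or s <= 0:
                    raise EMUSimulationError(f"EMU {e}: degenerate MDV")
                mdv[e] = row / s
        return mdv

    def to_dot(self) -> str:
        """GraphViz DOT export of the EMU dependency graph."""
        lines = ["digraph emu {", "  rankdir=LR;"]
        for e, terms in self.producers.items():
            for t in terms:
                label = f"{t.flux_id}" + (f" (w={t.weight:g})" if t.weight != 1 else "")
                if len(t.sources) > 1:
                    join = '"' + "+".join(str(s) for s in t.sources) + '"'
                    lines.append(f"  {join} [shape=box];")
                    for s in t.sources:
                        lines.append(f'  "{s}" -> {join};')
                    lines.append(f'  {join} -> "{e}" [label="{label}"];')
                else:
                    lines.append(f'  "{t.sources[0]}" -> "{e}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def _map_sources(am: AtomMap, instance_letters: str, atoms: tuple[int, ...]) -> tuple[tuple[str, tuple[int, ...]], ...]:
    """Trace the target atoms of one product instance back to reactant EMUs."""
    wanted = [instance_letters[a - 1] for a in atoms]
    per_source: dict[int, list[int]] = {}
    for letter in wanted:
        for ridx, (mid, letters) in enumerate(am.reactants):
            pos = letters.find(letter)
            if pos >= 0:
                per_source.setdefault(ridx, []).append(pos + 1)
                break
        else:  # validated tables cannot reach this
            raise ModelValidationError(f"letter {letter} has no reactant source")
    out = []
    for ridx in sorted(per_source):
        mid = am.reactants[ridx][0]
        out.append((mid, tuple(sorted(per_source[ridx]))))
    return tuple(out)


def decompose(
    transitions: Mapping[str, AtomTransition | list[AtomMap]],
    measured: Iterable[EMU],
    input_metabolites: Mapping[str, int],
    metabolite_carbons: Mapping[str, int],
) -> EMUNetwork:
    """Build the minimal EMU network needed to express the measured MDVs.

    ``transitions`` maps *split-flux* ids (one entry per flow direction) to
    their carbon maps.  ``input_metabolites`` (id -> carbon count) are
    sources with externally supplied labeling (the feed, dummy inflows);
    their EMUs terminate the recursion.
    """
    maps_by_flux: dict[str, list[AtomMap]] = {}
    for lid, tr in transitions.items():
        maps_by_flux[lid] = list(tr.maps) if isinstance(tr, AtomTransition) else list(tr)

    production_counts: dict[str, dict[str, float]] = {}
    for lid, maps in maps_by_flux.items():
        counts: dict[str, int] = {}
        for mid, _ in maps[0].products:
            counts[mid] = counts.get(mid, 0) + 1
        for mid, c in counts.items():
            production_counts.setdefault(mid, {})[lid] = float(c)

    measured = [make_emu(e.metabolite, e.atoms) for e in measured]
    producers: dict[EMU, list[EMUProducer]] = {}
    stack = list(measured)
    while stack:
        emu = stack.pop()
        if emu in producers:
            continue
        if emu.metabolite in input_metabolites:
            continue
        terms: list[EMUProducer] = []
        for lid, maps in maps_by_flux.items():
            w = 1.0 / len(maps)
            for am in maps:
                for mid, letters in am.products:
                    if mid != emu.metabolite:
                        continue
                    srcs = _map_sources(am, letters, emu.atoms)
                    src_emus = tuple(make_emu(m, a) for m, a in srcs)
                    terms.append(EMUProducer(lid, w, src_emus))
                    for s in src_emus:
                        if s.metabolite not in input_metabolites and s not in producers:
                            stack.append(s)
        if not terms:
            raise EMUSimulationError(
                f"measured EMU {emu} is unreachable from the feed: no tracked producer"
            )
        producers[emu] = terms

    tracked = {e.metabolite for e in producers}
    for mid in tracked:
        if mid not in metabolite_carbons:
            raise ModelValidationError(f"unknown carbon count for metabolite {mid}")
    return EMUNetwork(
        producers=producers,
        production_counts=production_counts,
        input_metabolites=dict(input_metabolites),
        measured=measured,
        tracked_metabolites=tracked,
    )
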