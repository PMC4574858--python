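"""Exhaustive isotopomer simulator over the full positional state space.

Independent ground truth for the EMU engine: every tracked metabolite
carries all 2^n positional states.  The steady-state balances are solved
exactly in cumomer coordinates (the probability that a given carbon subset
is fully labeled), in which the balance system is linear weight level by
weight level under the well-mixed-pool assumption, then inverted to
positional-isotopomer fractions by Moebius transform and summed into MDVs.
Unlike the EMU engine there is no minimal decomposition and no MDV
convolution; condensations reduce to scalar products of cumomer fractions.

Intended for small validation networks; refuses when the state space
exceeds a configurable cap.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .emu import EMUSimulationError, mdv_from_isotopomers
from .model import AtomMap, AtomTransition

__all__ = ["brute_force_oracle"]


def _cumomers_from_isotopomers(dist: np.ndarray) -> np.ndarray:
    """Zeta transform: x[mask] = P(all carbons in mask labeled)."""
    x = np.asarray(dist, dtype=float).copy()
    n = x.size.bit_length() - 1
    for b in range(n):
        bit = 1 << b
        for mask in range(x.size):
            if not mask & bit:
                x[mask] += x[mask | bit]
    return x


def _isotopomers_from_cumomers(x: np.ndarray) -> np.ndarray:
    """Moebius transform: inverse of :func:`_cumomers_from_isotopomers`."""
    d = np.asarray(x, dtype=float).copy()
    n = d.size.bit_length() - 1
    for b in range(n):
        bit = 1 << b
        for mask in range(d.size):
            if not mask & bit:
                d[mask] -= d[mask | bit]
    return d


def brute_force_oracle(
    transitions: Mapping[str, AtomTransition | list[AtomMap]],
    fluxes: Mapping[str, float],
    input_isotopomers: Mapping[str, np.ndarray],
    metabolite_carbons: Mapping[str, int],
    state_cap: int = 2 ** 20,
) -> dict[str, np.ndarray]:
    """Steady-state MDVs of every tracked metabolite by full-state
    cumomer balancing.

    ``transitions`` maps split-flux ids to carbon maps (same convention as
    :func:`mfa2s.emu.decompose`); ``input_isotopomers`` fixes the labeling
    of feed metabolites.  Returns metabolite -> full-molecule MDV.
    """
    maps_by_flux: dict[str, list[AtomMap]] = {}
    for lid, tr in transitions.items():
        maps_by_flux[lid] = list(tr.maps) if isinstance(tr, AtomTransition) else list(tr)

    tracked: set[str] = set()
    for maps in maps_by_flux.values():
        for am in maps:
            for mid, _ in am.products:
                if mid not in input_isotopomers:
                    tracked.add(mid)
    total_states = sum(2 ** metabolite_carbons[m] for m in tracked)
    if total_states > state_cap:
        raise EMUSimulationError(
            f"isotopomer state space {total_states} exceeds cap {state_cap}"
        )

    production: dict[str, float] = {m: 0.0 for m in tracked}
    for lid, maps in maps_by_flux.items():
        v = fluxes.get(lid, 0.0)
        if v < -1e-9:
            raise EMUSimulationError(f"negative split flux {lid}")
        w = 1.0 / len(maps)
        for am in maps:
            for mid, _ in am.products:
                if mid in production:
                    production[mid] += v * w

    input_cumomers = {
        m: _cumomers_from_isotopomers(d) for m, d in input_isotopomers.items()
    }
    # cumomer state; weight-0 entries are 1 by definition
    cum: dict[str, np.ndarray] = {}
    for m in tracked:
        c = np.zeros(2 ** metabolite_carbons[m])
        c[0] = 1.0
        cum[m] = c

    # producer bookkeeping: (flux id, map weight, map, product instance)
    producers: dict[str, list[tuple[str, float, AtomMap, int]]] = {m: [] for m in tracked}
    for lid, maps in maps_by_flux.items():
        w = 1.0 / len(maps)
        for am in maps:
            for k, (mid, _) in enumerate(am.products):
                if mid in producers:
                    producers[mid].append((lid, w, am, k))

    def source_masks(am: AtomMap, k: int, mask: int) -> list[tuple[str, int, bool]]:
        """Split a product-instance cumomer mask across its reactant
        instances: list of (metabolite, mask, is_input)."""
        letters = am.products[k][1]
        per: dict[int, int] = {}
        for bit in range(len(letters)):
            if not mask >> bit & 1:
                continue
            letter = letters[bit]
            for ridx, (rmid, rletters) in enumerate(am.reactants):
                pos = rletters.find(letter)
                if pos >= 0:
                    per[ridx] = per.get(ridx, 0) | (1 << pos)
                    break
        out = []
        for ridx, smask in per.items():
            rmid = am.reactants[ridx][0]
            out.append((rmid, smask, rmid not in tracked))
        return out

    max_weight = max((metabolite_carbons[m] for m in tracked), default=0)
    for weight in range(1, max_weight + 1):
        unknowns: list[tuple[str, int]] = []
        for m in sorted(tracked):
            if production[m] <= 0:
                continue  # no carbon flux: stays unlabeled (cumomers 0)
            for mask in range(1, 2 ** metabolite_carbons[m]):
                if bin(mask).count("1") == weight:
                    unknowns.append((m, mask))
        if not unknowns:
            continue
        index = {u: i for i, u in enumerate(unknowns)}
        A = np.zeros((len(unknowns), len(unknowns)))
        b = np.zeros(len(unknowns))
        for (m, mask), i in index.items():
            A[i, i] += production[m]
            for lid, w, am, k in producers[m]:
                v = fluxes.get(lid, 0.0) * w
                if v == 0.0:
                    continue
                parts = source_masks(am, k, mask)
                # product of known (lower-weight or input) factors; at most
                # one same-weight tracked factor stays symbolic
                coeff = v
                symbolic = None
                for rmid, smask, is_input in parts:
                    if is_input:
                        coeff *= input_cumomers[rmid][smask]
                    elif bin(smask).count("1") == weight and len(parts) == 1:
                        symbolic = (rmid, smask)
                    else:
                        coeff *= cum[rmid][smask]
                if symbolic is not None:
                    A[i, index[symbolic]] -= coeff
                else:
                    b[i] += coeff
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise EMUSimulationError(f"singular cumomer balance at weight {weight}: {exc}")
        resid = A @ x - b
        if np.abs(resid).max() > 1e-10:
            x = x + np.linalg.solve(A, b - A @ x)
        for (m, mask), i in index.items():
            cum[m][mask] = x[i]

    out = {}
    for m in tracked:
        n = metabolite_carbons[m]
        iso = np.clip(_isotopomers_from_cumomers(cum[m]), 0.0, None)
        s = iso.sum()
        if not np.isfinite(s) or s <= 0:
            raise EMUSimulationError(f"metabolite {m}: degenerate isotopomer solve")
        out[m] = mdv_from_isotopomers(iso / s, tuple(range(1, n + 1)), n)
    return out
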