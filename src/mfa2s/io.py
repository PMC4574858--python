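"""Readers and writers for models, atom-transition tables, measurements,
feeds and core-set lists.

Stoichiometric models are exchanged as SBML (Level 3 + FBC) or
constraint-based JSON through cobrapy; carbon counts ride on the metabolite
formula (``C6H12O6`` or a bare ``C6``) and boundary species on a metabolite
note.  Atom transitions use a TSV with letter-coded maps in stoichiometric
order; measurements and extracellular fluxes are plain CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AtomMap,
    AtomTransition,
    AtomTransitionTable,
    FeedSpec,
    LabelingDataset,
    MDVMeasurement,
    Metabolite,
    ModelValidationError,
    Reaction,
    StoichiometricModel,
)

log = logging.getLogger(__name__)

__all__ = [
    "load_model",
    "write_model",
    "parse_atom_transitions",
    "write_atom_transitions",
    "load_measurements",
    "write_measurements",
    "load_feed",
    "write_feed",
    "load_core_set",
    "write_core_set",
]

#: bounds assigned to reactions whose source file leaves them unspecified
#: (cobrapy's |1000| convention is mapped onto these)
DEFAULT_BOUND = 500.0


def _carbons_from_formula(formula: str | None) -> int:
    if not formula:
        return 0
    import re

    m = re.search(r"C(\d*)(?![a-z])", formula)
    if not m:
        return 0
    return int(m.group(1)) if m.group(1) else 1


def _from_cobra(cmodel, default_bound: float) -> StoichiometricModel:
    mets = []
    for cm in cmodel.metabolites:
        notes = cm.notes or {}
        n_c = notes.get("n_carbons")
        if n_c is None:
            n_c = _carbons_from_formula(cm.formula)
        mets.append(
            Metabolite(
                id=cm.id,
                n_carbons=int(n_c),
                name=cm.name or "",
                compartment=cm.compartment or "c",
                boundary=bool(notes.get("boundary", False)),
            )
        )
    rxns = []
    for cr in cmodel.reactions:
        lb, ub = cr.lower_bound, cr.upper_bound
        # cobra's |1000| default means "unspecified" in the source file
        if lb <= -1000:
            lb = -default_bound
        if ub >= 1000:
            ub = default_bound
        rxns.append(
            Reaction(
                id=cr.id,
                stoichiometry={m.id: c for m, c in cr.metabolites.items()},
                lb=lb,
                ub=ub,
                name=cr.name or "",
                genes=cr.gene_reaction_rule or "",
            )
        )
    notes = getattr(cmodel, "notes", {}) or {}
    biomass = notes.get("biomass_reaction")
    if biomass is None:
        objs = [r.id for r in cmodel.reactions if r.objective_coefficient]
        biomass = objs[0] if objs else None
    return StoichiometricModel(
        mets,
        rxns,
        biomass_reaction=biomass,
        substrate_uptake_reaction=notes.get("substrate_uptake_reaction"),
        id=cmodel.id or "model",
    )


def _to_cobra(model: StoichiometricModel):
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        c = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment or "c",
            formula=f"C{m.n_carbons}" if m.n_carbons else "",
        )
        c.notes = {"n_carbons": m.n_carbons, "boundary": m.boundary}
        cmets[m.id] = c
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cm.add_reactions([cr])
        cr.add_metabolites({cmets[m]: v for m, v in r.stoichiometry.items()})
        cr.bounds = (r.lb, r.ub)
        if r.genes:
            cr.gene_reaction_rule = r.genes
    cm.notes = {
        "biomass_reaction": model.biomass_reaction,
        "substrate_uptake_reaction": model.substrate_uptake_reaction,
    }
    if model.biomass_reaction:
        cm.objective = model.biomass_reaction
    return cm


def load_model(
    path: str | Path,
    dialect: str = "cobra-json",
    default_bound: float = DEFAULT_BOUND,
    biomass_reaction: str | None = None,
    substrate_uptake_reaction: str | None = None,
) -> StoichiometricModel:
    """Load an SBML or constraint-based-JSON model.

    ``biomass_reaction`` / ``substrate_uptake_reaction`` override whatever
    the file designates (SBML objective, model notes).
    """
    import cobra.io

    path = Path(path)
    if dialect == "cobra-json":
        raw = json.loads(path.read_text())
        declared = {m["id"] for m in raw.get("metabolites", [])}
        for r in raw.get("reactions", []):
            for mid in r.get("metabolites", {}):
                if mid not in declared:
                    raise ModelValidationError(
                        f"reaction {r.get('id')} references undeclared metabolite {mid}"
                    )
        cmodel = cobra.io.load_json_model(str(path))
    elif dialect == "sbml":
        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml errors are not a stable type
            raise ModelValidationError(f"cannot parse SBML {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown model dialect {dialect!r}")
    model = _from_cobra(cmodel, default_bound)
    if biomass_reaction is not None:
        model.biomass_reaction = biomass_reaction
    if substrate_uptake_reaction is not None:
        model.substrate_uptake_reaction = substrate_uptake_reaction
    return model


def write_model(model: StoichiometricModel, path: str | Path, dialect: str = "cobra-json") -> None:
    import cobra.io

    path = Path(path)
    cm = _to_cobra(model)
    if dialect == "cobra-json":
        cobra.io.save_json_model(cm, str(path))
    elif dialect == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise ValueError(f"unknown model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# atom transitions: TSV with columns reaction_id, reactant_maps, product_maps
# ---------------------------------------------------------------------------

def _ordered_instances(model: StoichiometricModel, rid: str, side: str) -> list[str]:
    """Molecule instances of one reaction side, in deterministic
    (id-sorted, coefficient-expanded) order; carbon-free species skipped."""
    rxn = model.reaction(rid)
    coeffs = rxn.reactants() if side == "reactants" else rxn.products()
    out = []
    for mid in sorted(coeffs):
        if model.metabolite(mid).n_carbons == 0:
            continue
        n = coeffs[mid]
        if abs(n - round(n)) > 1e-9:
            raise ModelValidationError(
                f"{rid}: non-integer coefficient {n} for carbon-bearing {mid}"
            )
        out.extend([mid] * int(round(n)))
    return out


def parse_atom_transitions(path: str | Path, model: StoichiometricModel) -> AtomTransitionTable:
    """Parse a transition TSV.  Several rows with the same reaction id are
    equiprobable alternate maps (symmetric molecules)."""
    table = AtomTransitionTable()
    rows: dict[str, list[AtomMap]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if parts[0] == "reaction_id":
            continue
        if len(parts) != 3:
            raise ModelValidationError(f"{path}:{lineno}: expected 3 TSV columns")
        rid, rmaps, pmaps = parts
        if not model.has_reaction(rid):
            raise ModelValidationError(f"{path}:{lineno}: unknown reaction {rid}")
        r_ids = _ordered_instances(model, rid, "reactants")
        p_ids = _ordered_instances(model, rid, "products")
        r_strings = [s for s in rmaps.split(";") if s] if rmaps else []
        p_strings = [s for s in pmaps.split(";") if s] if pmaps else []
        if len(r_strings) != len(r_ids) or len(p_strings) != len(p_ids):
            raise ModelValidationError(
                f"{path}:{lineno}: {rid} expects {len(r_ids)} reactant and "
                f"{len(p_ids)} product map(s), got {len(r_strings)}/{len(p_strings)}"
            )
        am = AtomMap(
            tuple(zip(r_ids, r_strings)),
            tuple(zip(p_ids, p_strings)),
        )
        rows.setdefault(rid, []).append(am)
    for rid, maps in rows.items():
        table.add(AtomTransition(rid, maps))
    table.validate(model)
    return table


def write_atom_transitions(table: AtomTransitionTable, path: str | Path) -> None:
    lines = ["reaction_id\treactant_maps\tproduct_maps"]
    for rid in table.reaction_ids():
        for am in table[rid].maps:
            rstr = ";".join(s for _, s in am.reactants)
            pstr = ";".join(s for _, s in am.products)
            lines.append(f"{rid}\t{rstr}\t{pstr}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def _parse_carbon_range(text: str) -> tuple[int, ...] | None:
    text = str(text).strip()
    if not text or text.lower() in {"all", "nan"}:
        return None
    if "-" in text:
        a, b = text.split("-")
        return tuple(range(int(a), int(b) + 1))
    return tuple(int(x) for x in text.split(","))


def load_measurements(
    mdv_path: str | Path,
    model: StoichiometricModel,
    extracellular_path: str | Path | None = None,
    sum_tolerance: float = 0.05,
) -> LabelingDataset:
    """Load measured MDVs (CSV: metabolite_id, carbon_range, m, f_exp, delta)
    plus optional extracellular fluxes (CSV: reaction_id, lb, ub; a row for
    the biomass reaction or literal ``growth`` sets the growth interval).

    MDVs are renormalized to sum 1 up to ``sum_tolerance``; the factor is
    logged.
    """
    df = pd.read_csv(mdv_path)
    meas = []
    for (mid, crange), grp in df.groupby(["metabolite_id", "carbon_range"], sort=False, dropna=False):
        if mid not in model.metabolite_ids:
            raise ModelValidationError(f"measured metabolite {mid} not in model")
        atoms = _parse_carbon_range(crange if isinstance(crange, str) else "")
        grp = grp.sort_values("m")
        size = model.metabolite(mid).n_carbons if atoms is None else len(atoms)
        if list(grp["m"]) != list(range(size + 1)):
            raise ModelValidationError(
                f"{mid}: expected m = 0..{size}, got {list(grp['m'])}"
            )
        meas.append(
            MDVMeasurement(
                metabolite_id=mid,
                f_exp=grp["f_exp"].to_numpy(dtype=float),
                delta=grp["delta"].to_numpy(dtype=float),
                atoms=atoms,
            )
        )
    extracellular: list[tuple[str, float, float]] = []
    growth = None
    if extracellular_path is not None:
        ef = pd.read_csv(extracellular_path)
        for _, row in ef.iterrows():
            rid = str(row["reaction_id"])
            lo, hi = float(row["lb"]), float(row["ub"])
            if rid == "growth" or rid == model.biomass_reaction:
                growth = (lo, hi)
                if rid != "growth":
                    extracellular.append((rid, lo, hi))
            else:
                if not model.has_reaction(rid):
                    raise ModelValidationError(f"measured flux for unknown reaction {rid}")
                extracellular.append((rid, lo, hi))
    ds = LabelingDataset(meas, extracellular, growth)
    for mid, factor in ds.normalize(sum_tolerance):
        log.info("renormalized MDV of %s by factor %.6f", mid, factor)
    return ds


def write_measurements(
    dataset: LabelingDataset,
    mdv_path: str | Path,
    extracellular_path: str | Path | None = None,
    biomass_reaction: str = "growth",
) -> None:
    rows = []
    for m in dataset.mdv_measurements:
        crange = "all" if m.atoms is None else "-".join(
            [str(m.atoms[0]), str(m.atoms[-1])]
        )
        for k in range(len(m.f_exp)):
            rows.append(
                {
                    "metabolite_id": m.metabolite_id,
                    "carbon_range": crange,
                    "m": k,
                    "f_exp": m.f_exp[k],
                    "delta": m.delta[k],
                }
            )
    pd.DataFrame(rows).to_csv(mdv_path, index=False)
    if extracellular_path is not None:
        erows = [
            {"reaction_id": rid, "lb": lo, "ub": hi}
            for rid, lo, hi in dataset.extracellular_measurements
        ]
        if dataset.growth_rate is not None:
            erows.append(
                {
                    "reaction_id": biomass_reaction,
                    "lb": dataset.growth_rate[0],
                    "ub": dataset.growth_rate[1],
                }
            )
        pd.DataFrame(erows).to_csv(extracellular_path, index=False)


def load_feed(path: str | Path) -> FeedSpec:
    """Feed CSV: substrate_id, pattern, fraction."""
    df = pd.read_csv(path, dtype={"pattern": str})
    subs = df["substrate_id"].unique()
    if len(subs) != 1:
        raise ModelValidationError("feed file must describe exactly one substrate")
    comps = [(str(r["pattern"]), float(r["fraction"])) for _, r in df.iterrows()]
    return FeedSpec(str(subs[0]), comps)


def write_feed(feed: FeedSpec, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"substrate_id": feed.substrate_id, "pattern": p, "fraction": f}
            for p, f in feed.components
        ]
    ).to_csv(path, index=False)


def load_core_set(path: str | Path) -> list[str]:
    """Core reaction ids, one per line; '#' starts a comment."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_core_set(reactions: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(reactions) + "\n")
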