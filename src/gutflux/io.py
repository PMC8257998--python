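"""Readers and writers for the plain-text interchange formats.

Taxon models travel either as SBML Level 3 + FBC (via cobrapy/libsbml) or
as a human-auditable tab-separated reaction table; abundance tables, diets,
cluster assignments and differential results are TSV.
"""

from __future__ import annotations

from pathlib import Path

import cobra.io
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .containers import AbundanceTable, DietSpec

_HEADER = "# gutflux reaction table v1"


def write_reaction_table(model: Model, path: str | Path) -> None:
    """Plain-text model dump: MET lines then RXN lines (id, equation, bounds)."""
    lines = [_HEADER, f"# taxon: {model.id}"]
    for met in sorted(model.metabolites, key=lambda m: m.id):
        lines.append(
            f"MET\t{met.id}\t{met.formula or '-'}\t{met.compartment or '-'}"
        )
    for rxn in model.reactions:
        eq = rxn.build_reaction_string(use_metabolite_names=False)
        lines.append(f"RXN\t{rxn.id}\t{eq}\t{rxn.lower_bound:g}\t{rxn.upper_bound:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reaction_table(path: str | Path) -> Model:
    path = Path(path)
    taxon = path.stem
    mets: list[Metabolite] = []
    rxn_specs: list[tuple[str, str, float, float]] = []
    for line in path.read_text().splitlines():
        if line.startswith("# taxon:"):
            taxon = line.split(":", 1)[1].strip()
        elif line.startswith("MET\t"):
            _, mid, formula, comp = line.split("\t")
            mets.append(Metabolite(
                mid,
                formula=None if formula == "-" else formula,
                compartment=None if comp == "-" else comp,
            ))
        elif line.startswith("RXN\t"):
            _, rid, eq, lb, ub = line.split("\t")
            rxn_specs.append((rid, eq, float(lb), float(ub)))
    model = Model(taxon)
    model.add_metabolites(mets)
    reactions = []
    for rid, eq, lb, ub in rxn_specs:
        rxn = Reaction(rid)
        reactions.append(rxn)
    model.add_reactions(reactions)
    for rxn, (rid, eq, lb, ub) in zip(reactions, rxn_specs):
        rxn.build_reaction_from_string(eq)
        rxn.bounds = (lb, ub)
    if "biomass" in model.reactions:
        model.objective = "biomass"
    return model


def write_sbml(model: Model, path: str | Path) -> None:
    cobra.io.write_sbml_model(model, str(path))


def read_sbml(path: str | Path) -> Model:
    return cobra.io.read_sbml_model(str(path))


def load_taxon_models(directory: str | Path) -> dict[str, Model]:
    """Load every ``*.tsv`` reaction table and ``*.xml`` SBML model in a dir."""
    directory = Path(directory)
    models: dict[str, Model] = {}
    for p in sorted(directory.glob("*.tsv")):
        m = read_reaction_table(p)
        models[m.id] = m
    for p in sorted(directory.glob("*.xml")):
        m = read_sbml(p)
        models[m.id] = m
    if not models:
        raise FileNotFoundError(f"no taxon models (*.tsv, *.xml) in {directory}")
    return models


def write_community_model(community, path: str | Path) -> None:
    """Dump an assembled community model: SBML for the stoichiometric part
    plus a JSON sidecar with the pieces SBML cannot carry (abundances, diet,
    biomass window, coupling factor)."""
    import json

    path = Path(path)
    cobra.io.write_sbml_model(community.model, str(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "sample_id": community.sample_id,
        "abundances": community.abundances,
        "diet": {"name": community.diet.name, "bounds": community.diet.bounds},
        "biomass_window": list(community.biomass_window),
        "coupling_factor": community.coupling_factor,
        "lumen_metabolites": community.lumen_metabolites,
        "note": "coupling constraints are not representable in SBML; rebuild "
                "with build_community_model to restore them",
    }, indent=2) + "\n")


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t")


def read_abundance_table(path: str | Path) -> AbundanceTable:
    return AbundanceTable.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def write_diet(diet: DietSpec, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(diet.bounds.items()),
        columns=["metabolite_id", "max_uptake_mmol_per_day"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_diet(path: str | Path, name: str | None = None) -> DietSpec:
    frame = pd.read_csv(path, sep="\t")
    bounds = dict(zip(frame["metabolite_id"], frame["max_uptake_mmol_per_day"].astype(float)))
    return DietSpec(name or Path(path).stem, bounds)
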