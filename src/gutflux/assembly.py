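"""Pan-taxon model merging and sample-specific community model assembly.

A community model joins per-taxon metabolic models through a shared lumen
compartment ``[u]`` fed by a diet compartment ``[d]`` and drained into a
fecal compartment ``[fe]``:

* each taxon's metabolites and reactions are tagged with the taxon label;
* each taxon exchange reaction becomes a taxon-lumen (IEX) reaction with
  the taxon's original bounds (flux > 0 = secretion into the lumen);
* every lumen metabolite gets a diet transport ``[d] -> [u]`` capped by the
  diet's maximum uptake rate (zero for metabolites absent from the diet), a
  boundary diet exchange (1 met -> nothing, bounded below by minus the diet
  rate), a fecal transport ``[u] -> [fe]`` and a boundary fecal exchange;
* a community biomass reaction drains each taxon's biomass metabolite with
  that taxon's relative abundance as coefficient, and its flux is confined
  to a fixed window (default 0.4-1.0 mmol/day), so the taxon biomass flux
  equals abundance x community biomass flux;
* optional linear coupling constraints |v_j| <= kappa * v_biomass,taxon tie
  every taxon reaction flux to that taxon's biomass flux (default kappa =
  400), which forces zero-abundance taxa to carry zero flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from cobra import Metabolite, Model, Reaction

from ._lp import configure_solver, flux_range, optimize_reaction
from .containers import AbundanceTable, DietSpec
from .synthetic import BIOMASS_ID, BIOMASS_MET
from .universe import METABOLITES as METABOLITES_FORMULA

COMMUNITY_BIOMASS_ID = "community_biomass"
BIG = 10000.0
DEFAULT_BIOMASS_WINDOW = (0.4, 1.0)
DEFAULT_COUPLING_FACTOR = 400.0
DEFAULT_MODELED_FRACTION_THRESHOLD = 0.9

#: combined 16S read columns split equally between their member genera
DEFAULT_COMBINED_SPLITS: dict[str, tuple[str, str]] = {
    "escherichia/shigella": ("escherichia", "shigella"),
}


class InfeasibleCommunityError(RuntimeError):
    """Raised when a community model cannot satisfy its biomass window."""


@dataclass
class AssemblyConfig:
    """Tunable assembly options, loadable from YAML."""

    biomass_window: tuple[float, float] = DEFAULT_BIOMASS_WINDOW
    coupling_factor: float | None = DEFAULT_COUPLING_FACTOR
    modeled_fraction_threshold: float = DEFAULT_MODELED_FRACTION_THRESHOLD
    combined_splits: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_COMBINED_SPLITS)
    )
    family_bins: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssemblyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "biomass_window" in raw:
            raw["biomass_window"] = tuple(raw["biomass_window"])
        if "combined_splits" in raw:
            raw["combined_splits"] = {
                k: tuple(v) for k, v in raw["combined_splits"].items()
            }
        return cls(**raw)


def iex_id(metabolite: str, taxon: str) -> str:
    return f"IEX_{metabolite}__{taxon}"


def diet_exchange_id(metabolite: str) -> str:
    return f"EX_{metabolite}_d"


def fecal_exchange_id(metabolite: str) -> str:
    return f"EX_{metabolite}_fe"


def diet_transport_id(metabolite: str) -> str:
    return f"DT_{metabolite}"


@dataclass
class CommunityModel:
    """An assembled multi-taxon LP plus its provenance."""

    model: Model
    sample_id: str
    abundances: dict[str, float]
    diet: DietSpec
    biomass_window: tuple[float, float]
    coupling_factor: float | None
    lumen_metabolites: list[str]

    @property
    def taxa(self) -> list[str]:
        return list(self.abundances)

    def set_abundances(self, abundances: dict[str, float]) -> None:
        """Re-point the model at a new sample without rebuilding the LP.

        Only the community biomass coefficients change; a taxon given zero
        abundance is forced to zero flux by the coupling constraints (its
        biomass metabolite is no longer drained, pinning its biomass flux,
        and with it every coupled reaction, at zero).
        """
        extra = set(abundances) - set(self.abundances)
        if extra:
            raise KeyError(f"taxa not present in community model: {sorted(extra)}")
        total = sum(abundances.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"abundances sum to {total}, not 1")
        full = {t: float(abundances.get(t, 0.0)) for t in self.abundances}
        rxn = self.model.reactions.get_by_id(COMMUNITY_BIOMASS_ID)
        rxn.subtract_metabolites(dict(rxn.metabolites))
        rxn.add_metabolites({
            self.model.metabolites.get_by_id(f"{BIOMASS_MET}__{t}"): -a
            for t, a in full.items()
        })
        self.abundances = full

    def set_diet(self, diet: DietSpec) -> None:
        """Swap the diet by retightening diet transport/exchange bounds."""
        for met in self.lumen_metabolites:
            b = diet.bound(met)
            self.model.reactions.get_by_id(diet_transport_id(met)).bounds = (0.0, b)
            self.model.reactions.get_by_id(diet_exchange_id(met)).bounds = (-b, 0.0)
        self.diet = diet

    def max_community_biomass(self, relax_lower: bool = False) -> float:
        rxn = self.model.reactions.get_by_id(COMMUNITY_BIOMASS_ID)
        with self.model:
            if relax_lower:
                rxn.lower_bound = 0.0
            value, status = optimize_reaction(self.model, COMMUNITY_BIOMASS_ID, "max")
        return value if status == "optimal" else 0.0


def build_pan_model(strains: list[Model], taxon: str) -> Model:
    """Merge strain models of one taxon into a pan-reaction model.

    The pan reaction set is the union over strains (widest bounds per
    reaction id; identical stoichiometry required).  Futile cycles created
    by the union are then mitigated: with every boundary exchange closed, a
    flux variability pass finds internal reactions still able to carry flux
    (necessarily thermodynamically impossible loops); each is restricted to
    the direction it carries in at least one strain's default bounds, and a
    loop of irreversible reactions is broken by closing its alphabetically
    first member.  Every bound change is recorded in the provenance log
    (``model.notes["provenance"]``).
    """
    if not strains:
        raise ValueError("empty strain list")

    stoichs: dict[str, dict[str, float]] = {}
    bounds: dict[str, tuple[float, float]] = {}
    strain_bounds: dict[str, list[tuple[float, float]]] = {}
    met_info: dict[str, tuple[str | None, str | None]] = {}
    order: list[str] = []
    for strain in strains:
        for met in strain.metabolites:
            met_info.setdefault(met.id, (met.formula, met.compartment))
        for rxn in strain.reactions:
            stoich = {m.id: c for m, c in rxn.metabolites.items()}
            if rxn.id in stoichs:
                if stoichs[rxn.id] != stoich:
                    raise ValueError(
                        f"conflicting stoichiometry for reaction {rxn.id!r} "
                        f"across strains of {taxon!r}"
                    )
                lo, hi = bounds[rxn.id]
                bounds[rxn.id] = (min(lo, rxn.lower_bound), max(hi, rxn.upper_bound))
            else:
                order.append(rxn.id)
                stoichs[rxn.id] = stoich
                bounds[rxn.id] = (rxn.lower_bound, rxn.upper_bound)
            strain_bounds.setdefault(rxn.id, []).append((rxn.lower_bound, rxn.upper_bound))

    pan = Model(taxon)
    mets = {
        mid: Metabolite(mid, formula=f, compartment=c)
        for mid, (f, c) in met_info.items()
    }
    rxns = []
    for rid in order:
        r = Reaction(rid, lower_bound=bounds[rid][0], upper_bound=bounds[rid][1])
        r.add_metabolites({mets[m]: c for m, c in stoichs[rid].items()})
        rxns.append(r)
    pan.add_reactions(rxns)
    pan.objective = BIOMASS_ID if BIOMASS_ID in stoichs else rxns[0].id

    provenance: list[str] = [f"pan model {taxon!r} merged from {len(strains)} strain(s)"]
    _mitigate_futile_cycles(pan, strain_bounds, provenance)
    pan.notes["provenance"] = provenance
    return pan


def _mitigate_futile_cycles(
    pan: Model,
    strain_bounds: dict[str, list[tuple[float, float]]],
    provenance: list[str],
    tol: float = 1e-6,
    max_passes: int = 10,
) -> None:
    probe = pan.copy()
    configure_solver(probe)
    for rxn in probe.boundary:
        rxn.bounds = (0.0, 0.0)
    candidates = sorted(
        r.id for r in probe.reactions
        if not r.boundary and r.id != BIOMASS_ID
    )
    for _ in range(max_passes):
        changed = False
        for rid in candidates:
            vmin, vmax, *_ = flux_range(probe, rid)
            if max(abs(vmin), abs(vmax)) <= tol:
                continue
            target = pan.reactions.get_by_id(rid)
            mirror = probe.reactions.get_by_id(rid)
            sb = strain_bounds.get(rid, [])
            if target.lower_bound < 0 < target.upper_bound:
                if any(lo >= 0 for lo, _ in sb):
                    target.lower_bound = mirror.lower_bound = 0.0
                    provenance.append(f"loop mitigation: {rid} made irreversible (forward)")
                elif any(hi <= 0 for _, hi in sb):
                    target.upper_bound = mirror.upper_bound = 0.0
                    provenance.append(f"loop mitigation: {rid} made irreversible (reverse)")
                else:
                    target.lower_bound = mirror.lower_bound = 0.0
                    provenance.append(
                        f"loop mitigation: {rid} forced forward (no strain default direction)"
                    )
            else:
                target.bounds = mirror.bounds = (0.0, 0.0)
                provenance.append(f"loop mitigation: {rid} closed (irreversible loop member)")
            changed = True
            break
        if not changed:
            return
    provenance.append("loop mitigation: pass limit reached with cycles remaining")


def prepare_abundances(
    table: AbundanceTable,
    modeled_taxa: list[str],
    combined_splits: dict[str, tuple[str, str]] | None = None,
    family_bins: dict[str, str] | None = None,
    threshold: float = DEFAULT_MODELED_FRACTION_THRESHOLD,
) -> AbundanceTable:
    """Split combined columns, bin unmodelable genera, filter, normalize.

    Combined read columns (e.g. a joint Escherichia/Shigella count) are
    split equally between their member genera; genera named in
    ``family_bins`` are absorbed into their family-level column; samples
    whose modeled fraction falls below ``threshold`` are dropped; remaining
    rows are renormalized over ``modeled_taxa`` to sum to one.
    """
    reads = table.reads.copy().astype(float)
    for col, (a, b) in (combined_splits or DEFAULT_COMBINED_SPLITS).items():
        if col in reads.columns:
            half = reads[col] / 2.0
            for target in (a, b):
                reads[target] = reads.get(target, 0.0) + half
            reads = reads.drop(columns=[col])
    for genus, bin_name in (family_bins or {}).items():
        if genus in reads.columns:
            reads[bin_name] = reads.get(bin_name, 0.0) + reads[genus]
            reads = reads.drop(columns=[genus])

    missing = set(modeled_taxa) - set(reads.columns)
    if missing:
        raise KeyError(f"modeled taxa absent from table: {sorted(missing)}")
    keep = table.modeled_fraction >= threshold
    if not keep.any():
        raise ValueError(
            f"all samples fall below the modeled-fraction threshold {threshold}"
        )
    reads = reads.loc[keep, list(modeled_taxa)]
    normalized = reads.div(reads.sum(axis=1), axis=0)
    return AbundanceTable(
        reads=normalized,
        phenotype=table.phenotype.loc[keep],
        modeled_fraction=table.modeled_fraction.loc[keep],
        archetype=None if table.archetype is None else table.archetype.loc[keep],
    )


def modeled_coverage_summary(table: AbundanceTable, threshold: float = 0.9) -> dict:
    """Coverage bookkeeping: mean modeled fraction and filter counts."""
    frac = table.modeled_fraction
    keep = frac >= threshold
    by_pheno = {
        p: {
            "total": int((table.phenotype == p).sum()),
            "retained": int(((table.phenotype == p) & keep).sum()),
        }
        for p in sorted(table.phenotype.unique())
    }
    return {
        "mean_modeled_fraction": float(frac.mean()),
        "n_samples": int(len(frac)),
        "n_retained": int(keep.sum()),
        "by_phenotype": by_pheno,
    }


def build_community_model(
    pan_models: dict[str, Model],
    abundances: dict[str, float],
    diet: DietSpec,
    sample_id: str = "community",
    biomass_window: tuple[float, float] = DEFAULT_BIOMASS_WINDOW,
    coupling_factor: float | None = DEFAULT_COUPLING_FACTOR,
    keep_zero_abundance: bool = False,
    check_feasibility: bool = True,
) -> CommunityModel:
    """Assemble one sample's community LP from pan models and abundances."""
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {total}, not 1")
    missing = [t for t, a in abundances.items() if (a > 0 or keep_zero_abundance)
               and t not in pan_models]
    if missing:
        raise KeyError(f"no pan model for taxa: {missing}")
    taxa = {
        t: float(a) for t, a in abundances.items()
        if a > 0 or keep_zero_abundance
    }

    cm = Model(f"community_{sample_id}")
    configure_solver(cm)
    mets: dict[str, Metabolite] = {}

    def pool_met(mid: str, comp: str, formula: str | None = None) -> Metabolite:
        key = f"{mid}_{comp}"
        if key not in mets:
            mets[key] = Metabolite(key, formula=formula, compartment=comp)
        return mets[key]

    rxns: list[Reaction] = []
    lumen: list[str] = []
    coupled: list[tuple[str, str]] = []  # (reaction id, taxon)
    for taxon in taxa:
        source = pan_models[taxon]
        tagged = {
            m.id: Metabolite(
                f"{m.id}__{taxon}", formula=m.formula, compartment=f"c__{taxon}"
            )
            for m in source.metabolites
        }
        for rxn in source.reactions:
            if rxn.boundary:
                mid = next(iter(rxn.metabolites)).id
                if mid == BIOMASS_MET:
                    continue  # drained by the community biomass reaction instead
                iex = Reaction(
                    iex_id(mid, taxon),
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                )
                iex.add_metabolites({
                    tagged[mid]: -1.0,
                    pool_met(mid, "u", METABOLITES_FORMULA.get(mid)): 1.0,
                })
                rxns.append(iex)
                coupled.append((iex.id, taxon))
                if mid not in lumen:
                    lumen.append(mid)
            else:
                r = Reaction(
                    f"{rxn.id}__{taxon}",
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                )
                r.add_metabolites({tagged[m.id]: c for m, c in rxn.metabolites.items()})
                rxns.append(r)
                if rxn.id != BIOMASS_ID:
                    coupled.append((r.id, taxon))

    for mid in lumen:
        b = diet.bound(mid)
        formula = METABOLITES_FORMULA.get(mid)
        dt = Reaction(diet_transport_id(mid), lower_bound=0.0, upper_bound=b)
        dt.add_metabolites({
            pool_met(mid, "d", formula): -1.0, pool_met(mid, "u", formula): 1.0,
        })
        exd = Reaction(diet_exchange_id(mid), lower_bound=-b, upper_bound=0.0)
        exd.add_metabolites({pool_met(mid, "d", formula): -1.0})
        ft = Reaction(f"FT_{mid}", lower_bound=0.0, upper_bound=BIG)
        ft.add_metabolites({
            pool_met(mid, "u", formula): -1.0, pool_met(mid, "fe", formula): 1.0,
        })
        exf = Reaction(fecal_exchange_id(mid), lower_bound=0.0, upper_bound=BIG)
        exf.add_metabolites({pool_met(mid, "fe", formula): -1.0})
        rxns += [dt, exd, ft, exf]

    cbm = Reaction(
        COMMUNITY_BIOMASS_ID,
        lower_bound=biomass_window[0],
        upper_bound=biomass_window[1],
    )
    cm.add_reactions(rxns + [cbm])
    cbm.add_metabolites({
        cm.metabolites.get_by_id(f"{BIOMASS_MET}__{t}"): -a for t, a in taxa.items()
    })

    if coupling_factor is not None:
        constraints = []
        for rid, taxon in coupled:
            v = cm.reactions.get_by_id(rid).flux_expression
            vbio = cm.reactions.get_by_id(f"{BIOMASS_ID}__{taxon}").flux_expression
            constraints.append(cm.problem.Constraint(
                v - coupling_factor * vbio, ub=0.0, name=f"coup_u_{rid}"
            ))
            constraints.append(cm.problem.Constraint(
                v + coupling_factor * vbio, lb=0.0, name=f"coup_l_{rid}"
            ))
        cm.add_cons_vars(constraints)

    community = CommunityModel(
        model=cm,
        sample_id=sample_id,
        abundances=taxa,
        diet=diet,
        biomass_window=tuple(biomass_window),
        coupling_factor=coupling_factor,
        lumen_metabolites=lumen,
    )
    if check_feasibility:
        achievable = community.max_community_biomass(relax_lower=True)
        if achievable + 1e-9 < biomass_window[0]:
            raise InfeasibleCommunityError(
                f"sample {sample_id!r}: maximum community biomass "
                f"{achievable:.6g} cannot reach the biomass window lower bound "
                f"{biomass_window[0]} under diet {diet.name!r}; the biomass "
                "window or the diet bounds are the blocking constraints"
            )
    return community
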