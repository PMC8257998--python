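"""Synthetic study-condition generators.

Everything downstream of this module (pan-model merging, community assembly,
FVA/NMPC, crossfeeding, clustering statistics) is exercised on data produced
here: toy genome-scale taxon models built from mass-balanced pathway
templates, strain variants for pan-model merging, Dirichlet-sampled
abundance tables with community archetypes and phenotype labels, and diet
files.  Default sizes mirror the three-archetype study design (26
Bacteroides-dominated, 44 Faecalibacterium-elevated, 8 Prevotella-elevated
samples) but every size is a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .containers import AbundanceTable, DietSpec
from .universe import CAPABILITIES, METABOLITES, element_imbalance

BIG = 1000.0
BIOMASS_ID = "biomass"
BIOMASS_MET = "biomass_met"


@dataclass
class TaxonSpec:
    """Blueprint for one toy taxon model.

    ``capabilities`` are pathway tags from :mod:`gutflux.universe`;
    ``uptake_preferences`` are the dietary metabolites the taxon can import
    (its exchange reactions for all other metabolites are secretion-only);
    ``biomass_precursors`` maps metabolite -> consumption coefficient per
    unit biomass flux.
    """

    name: str
    capabilities: frozenset[str] = field(default_factory=frozenset)
    uptake_preferences: tuple[str, ...] = ()
    biomass_precursors: dict[str, float] = field(default_factory=lambda: {"hexose": 0.1})


@dataclass
class CommunityArchetype:
    """A compositional community type samples are drawn from."""

    name: str
    mean_abundances: dict[str, float]
    concentration: float = 60.0
    gout_probability: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.mean_abundances.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mean abundances of {self.name} sum to {total}, not 1")
        if not 0.0 <= self.gout_probability <= 1.0:
            raise ValueError("gout_probability must be in [0, 1]")


def gen_taxon_model(spec: TaxonSpec, seed: int = 0) -> Model:
    """Build a single-compartment cobra model from a taxon blueprint.

    The model has one irreversible reaction per capability, an exchange
    reaction for every uptake preference and every capability product
    (flux > 0 = secretion; uptake allowed only for preferences), and one
    biomass reaction producing a formula-free biomass metabolite.  Every
    capability reaction is verified to be elementally balanced.
    """
    for tag in sorted(spec.capabilities):
        if tag not in CAPABILITIES:
            raise KeyError(f"unknown capability {tag!r} in spec {spec.name!r}")
        bad = element_imbalance(CAPABILITIES[tag])
        if bad:
            raise ValueError(f"capability {tag!r} unbalanced in elements {bad}")

    model = Model(spec.name)
    mets: dict[str, Metabolite] = {}

    def met(mid: str) -> Metabolite:
        if mid not in mets:
            mets[mid] = Metabolite(mid, formula=METABOLITES.get(mid), compartment="c")
        return mets[mid]

    reactions = []
    products: set[str] = set()
    for tag in sorted(spec.capabilities):
        stoich = CAPABILITIES[tag]
        rxn = Reaction(f"CAP_{tag}", lower_bound=0.0, upper_bound=BIG)
        rxn.add_metabolites({met(m): c for m, c in stoich.items()})
        reactions.append(rxn)
        products.update(m for m, c in stoich.items() if c > 0)

    for mid in sorted(products | set(spec.uptake_preferences)):
        ex = Reaction(
            f"EX_{mid}",
            lower_bound=-BIG if mid in spec.uptake_preferences else 0.0,
            upper_bound=BIG,
        )
        ex.add_metabolites({met(mid): -1.0})
        reactions.append(ex)

    biomass = Reaction(BIOMASS_ID, lower_bound=0.0, upper_bound=BIG)
    biomass.add_metabolites({met(m): -c for m, c in spec.biomass_precursors.items()})
    biomass.add_metabolites({met(BIOMASS_MET): 1.0})
    reactions.append(biomass)
    # standalone drain for the biomass metabolite; in a community model the
    # abundance-weighted community biomass reaction replaces it
    drain = Reaction(f"DM_{BIOMASS_MET}", lower_bound=0.0, upper_bound=BIG)
    drain.add_metabolites({met(BIOMASS_MET): -1.0})
    reactions.append(drain)

    model.add_reactions(reactions)
    model.objective = BIOMASS_ID
    return model


def max_biomass(model: Model) -> float:
    """Maximum biomass flux under the model's current exchange bounds."""
    with model:
        model.objective = BIOMASS_ID
        value = model.slim_optimize(error_value=float("nan"))
    return 0.0 if math.isnan(value) else float(value)


def internal_reactions(model: Model) -> list[Reaction]:
    """Reactions that are neither boundary exchanges nor the biomass drain."""
    return [
        r for r in model.reactions
        if r.id != BIOMASS_ID and not r.boundary
    ]


def gen_strain_variants(
    model: Model,
    n: int,
    deletion_fraction: float,
    seed: int = 0,
    max_resamples: int = 50,
) -> list[Model]:
    """Random strain-level reaction-loss variants of a parent taxon model.

    Each variant removes a random ``deletion_fraction`` of internal (non
    exchange, non biomass) reactions; variants that lose biomass feasibility
    are resampled.  With ``deletion_fraction = 0`` every variant is an exact
    copy of the parent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= deletion_fraction < 0.5:
        raise ValueError("deletion_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    pool = [r.id for r in internal_reactions(model)]
    k = int(round(deletion_fraction * len(pool)))
    variants: list[Model] = []
    for i in range(n):
        for _ in range(max_resamples):
            drop = sorted(rng.choice(pool, size=k, replace=False)) if k else []
            variant = model.copy()
            variant.id = f"{model.id}__s{i}"
            if drop:
                variant.remove_reactions([variant.reactions.get_by_id(r) for r in drop])
            if max_biomass(variant) > 1e-9:
                variants.append(variant)
                break
        else:
            raise RuntimeError(
                f"could not sample a biomass-feasible variant of {model.id!r} "
                f"at deletion_fraction={deletion_fraction}"
            )
    return variants


# ---------------------------------------------------------------------------
# default taxon blueprints and community archetypes
# ---------------------------------------------------------------------------

_WATER = ("h2o", "co2", "nh3")


def default_taxon_specs() -> list[TaxonSpec]:
    """Blueprints for the named gut taxa the archetypes are built around."""
    return [
        TaxonSpec(
            "bacteroides",
            frozenset({
                "fiber_degradation", "hexose_mixed_acid", "hexose_to_succinate",
                "hexose_to_d_lactate", "hexose_to_pyruvate", "cysteine_to_h2s",
                "sulfate_reduction", "alanine_synthesis_d", "alanine_synthesis_l",
                "serine_synthesis", "valine_to_isobutyrate",
                "leucine_to_isovalerate", "leucine_to_isocaproate",
            }),
            ("fiber", "hexose", "l_cysteine", "l_valine", "l_leucine", "sulfate") + _WATER,
        ),
        TaxonSpec(
            "faecalibacterium",
            frozenset({
                "hexose_to_l_lactate", "hexose_to_pyruvate",
                "butyrate_from_hexose_acetate", "serine_synthesis",
                "sulfate_reduction", "cysteine_synthesis", "methionine_synthesis",
                "m2ovalerate_synthesis", "isoleucine_synthesis",
                "pyruvate_to_l_lactate",
            }),
            ("hexose", "acetate", "sulfate") + _WATER,
        ),
        # a succinate/lactate-style fiber degrader: no mixed-acid products,
        # so its communities carry a fermentation signature distinct from the
        # acetate/formate profile of the bacteroides-like taxon
        TaxonSpec(
            "prevotella",
            frozenset({
                "fiber_degradation", "hexose_to_succinate",
                "hexose_to_l_lactate", "hexose_to_pyruvate",
            }),
            ("fiber", "hexose") + _WATER,
        ),
        TaxonSpec(
            "roseburia",
            frozenset({
                "butyrate_from_hexose", "butyrate_from_hexose_acetate",
                "hexose_to_l_lactate", "m2ovalerate_synthesis",
                "isoleucine_synthesis",
            }),
            ("hexose", "acetate") + _WATER,
        ),
        TaxonSpec(
            "coprococcus",
            frozenset({
                "butyrate_from_hexose", "serine_synthesis", "sulfate_reduction",
                "cysteine_synthesis",
            }),
            ("hexose", "sulfate") + _WATER,
        ),
        TaxonSpec(
            "subdoligranulum",
            frozenset({
                "butyrate_from_hexose_acetate", "hexose_to_l_lactate",
                "hexose_to_pyruvate", "alanine_catabolism_d",
                "pyruvate_to_l_lactate",
            }),
            ("hexose", "acetate", "d_alanine") + _WATER,
        ),
        TaxonSpec(
            "lachnospiraceae",
            frozenset({
                "hexose_to_acetate", "hexose_to_pyruvate", "alanine_synthesis_d",
                "butyrate_from_hexose",
            }),
            ("hexose",) + _WATER,
        ),
        TaxonSpec(
            "escherichia",
            frozenset({"hexose_mixed_acid", "hexose_to_d_lactate", "hexose_to_pyruvate"}),
            ("hexose",) + _WATER,
        ),
        TaxonSpec(
            "shigella",
            frozenset({"hexose_mixed_acid", "hexose_to_d_lactate", "hexose_to_pyruvate"}),
            ("hexose",) + _WATER,
        ),
        TaxonSpec(
            "megamonas",
            frozenset({
                "hexose_to_pyruvate", "alanine_synthesis_l", "serine_synthesis",
                "m2ovalerate_synthesis", "isoleucine_synthesis",
            }),
            ("hexose",) + _WATER,
        ),
        TaxonSpec(
            "clostridium",
            frozenset({
                "hexose_to_acetate", "valine_to_isobutyrate", "leucine_to_isovalerate",
            }),
            ("hexose", "l_valine", "l_leucine") + _WATER,
        ),
        TaxonSpec(
            "akkermansia",
            frozenset({"hexose_to_acetate", "hexose_to_succinate"}),
            ("hexose",) + _WATER,
        ),
    ]


_FILLER_POOL = (
    "hexose_to_acetate", "hexose_mixed_acid", "hexose_to_d_lactate",
    "hexose_to_l_lactate", "hexose_to_succinate", "hexose_to_pyruvate",
)


def filler_taxon_specs(n: int, seed: int = 0) -> list[TaxonSpec]:
    """Generic low-abundance fermenters padding the taxon set to study size."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        k = int(rng.integers(2, 4))
        caps = frozenset(rng.choice(_FILLER_POOL, size=k, replace=False).tolist())
        specs.append(TaxonSpec(f"generic_{i:02d}", caps, ("hexose",) + _WATER))
    return specs


def default_taxon_models(n_taxa: int = 50, seed: int = 0) -> dict[str, Model]:
    """Toy models for the default taxon set (12 named + generic fillers)."""
    named = default_taxon_specs()
    if n_taxa < len(named):
        raise ValueError(f"n_taxa must be >= {len(named)}")
    specs = named + filler_taxon_specs(n_taxa - len(named), seed=seed)
    return {s.name: gen_taxon_model(s, seed=seed) for s in specs}


def default_archetypes(n_taxa: int = 50, seed: int = 0) -> list[CommunityArchetype]:
    """The three community archetypes (gout fractions 22/26, 11/44, 6/8)."""
    named = {
        "bacteroides_dominated": (
            {
                "bacteroides": 0.75, "faecalibacterium": 0.04, "prevotella": 0.01,
                "roseburia": 0.01, "coprococcus": 0.01, "subdoligranulum": 0.005,
                "lachnospiraceae": 0.04, "escherichia": 0.02, "shigella": 0.02,
                "megamonas": 0.01, "clostridium": 0.02, "akkermansia": 0.005,
            },
            22 / 26,
        ),
        "faecalibacterium_elevated": (
            {
                "bacteroides": 0.30, "faecalibacterium": 0.15, "prevotella": 0.02,
                "roseburia": 0.06, "coprococcus": 0.05, "subdoligranulum": 0.04,
                "lachnospiraceae": 0.08, "escherichia": 0.015, "shigella": 0.015,
                "megamonas": 0.04, "clostridium": 0.02, "akkermansia": 0.03,
            },
            11 / 44,
        ),
        "prevotella_elevated": (
            {
                "bacteroides": 0.05, "faecalibacterium": 0.05, "prevotella": 0.45,
                "roseburia": 0.02, "coprococcus": 0.01, "subdoligranulum": 0.01,
                "lachnospiraceae": 0.06, "escherichia": 0.025, "shigella": 0.025,
                "megamonas": 0.03, "clostridium": 0.04, "akkermansia": 0.01,
            },
            6 / 8,
        ),
    }
    fillers = [s.name for s in filler_taxon_specs(n_taxa - 12, seed=seed)]
    archetypes = []
    for name, (means, gout_p) in named.items():
        full = dict(means)
        remainder = 1.0 - sum(means.values())
        if fillers:
            for f in fillers:
                full[f] = remainder / len(fillers)
        else:  # no filler taxa: renormalize the named means to a composition
            full = {t: v / (1.0 - remainder) for t, v in full.items()}
        archetypes.append(CommunityArchetype(name, full, gout_probability=gout_p))
    return archetypes


def gen_abundance_table(
    archetypes: list[CommunityArchetype],
    n_per_archetype: list[int],
    modeled_fraction_range: tuple[float, float] = (0.89, 1.0),
    seed: int = 0,
    depth: int = 20000,
) -> AbundanceTable:
    """Sample an unnormalized reads table from community archetypes.

    Per sample: a Dirichlet composition around the archetype mean (an
    infinite concentration yields the mean exactly), a modeled fraction
    drawn uniformly from ``modeled_fraction_range``, and a phenotype label
    drawn with the archetype's gout probability.  Reads for the modeled taxa
    sum to ``modeled_fraction * depth`` so the coverage filter downstream is
    exercised exactly as on real 16S tables.
    """
    if not archetypes:
        raise ValueError("archetype list is empty")
    if len(archetypes) != len(n_per_archetype):
        raise ValueError("archetypes and n_per_archetype lengths differ")
    lo, hi = modeled_fraction_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("modeled_fraction_range must lie within [0, 1]")

    taxa: list[str] = []
    for arch in archetypes:
        for t in arch.mean_abundances:
            if t not in taxa:
                taxa.append(t)

    rng = np.random.default_rng(seed)
    rows, sample_ids, phenos, fracs, labels = [], [], [], [], []
    for arch, n in zip(archetypes, n_per_archetype):
        mean = np.array([arch.mean_abundances.get(t, 0.0) for t in taxa])
        for i in range(n):
            if math.isinf(arch.concentration):
                comp = mean.copy()
            else:
                alpha = np.where(mean > 0, arch.concentration * mean, 1e-9)
                comp = rng.dirichlet(alpha)
                comp[mean == 0] = 0.0
                comp = comp / comp.sum()
            frac = rng.uniform(lo, hi)
            rows.append(np.round(comp * frac * depth))
            sample_ids.append(f"{arch.name}__{i:03d}")
            phenos.append("gouty" if rng.random() < arch.gout_probability else "healthy")
            fracs.append(frac)
            labels.append(arch.name)

    index = pd.Index(sample_ids, name="sample")
    return AbundanceTable(
        reads=pd.DataFrame(rows, index=index, columns=taxa),
        phenotype=pd.Series(phenos, index=index, name="phenotype"),
        modeled_fraction=pd.Series(fracs, index=index, name="modeled_fraction"),
        archetype=pd.Series(labels, index=index, name="archetype"),
    )


# ---------------------------------------------------------------------------
# diets
# ---------------------------------------------------------------------------

#: average EU diet stand-in: maximum uptake rates in mmol/day.  The real
#: study diets are database exports without public numeric tables, so these
#: presets are structural stand-ins at physiologically plausible magnitudes.
_EUD_BOUNDS: dict[str, float] = {
    "fiber": 5.0,
    "hexose": 10.0,
    "l_valine": 3.0,
    "l_leucine": 3.0,
    "l_isoleucine": 1.0,
    "l_cysteine": 2.0,
    "l_methionine": 1.0,
    "serine": 2.0,
    "l_alanine": 1.0,
    "sulfate": 5.0,
    "nh3": 20.0,
    "co2": 50.0,
    "h2o": 1000.0,
}

_AMINO_ACIDS = (
    "l_valine", "l_leucine", "l_isoleucine", "l_cysteine", "l_methionine",
    "serine", "l_alanine",
)

#: the high fiber diet supplies 1.84x the EUD L-cysteine (84% more).
HFD_CYSTEINE_FACTOR = 1.84


def gen_diet(preset: str, scale: float = 1.0) -> DietSpec:
    """One of the three study diets: EUD, HPD (high protein), HFD (high fiber)."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    bounds = dict(_EUD_BOUNDS)
    if preset == "EUD":
        pass
    elif preset == "HPD":
        for aa in _AMINO_ACIDS:
            bounds[aa] *= 2.5
    elif preset == "HFD":
        bounds["fiber"] *= 3.0
        bounds["l_cysteine"] *= HFD_CYSTEINE_FACTOR
    else:
        raise KeyError(f"unknown diet preset {preset!r}; expected EUD, HPD or HFD")
    return DietSpec(preset, {m: b * scale for m, b in bounds.items()})


# ---------------------------------------------------------------------------
# planted-effect capability matrices for the statistical layer
# ---------------------------------------------------------------------------

def gen_nmpc_matrix(
    n_per_group: tuple[int, int] = (26, 44),
    n_metabolites: int = 40,
    n_differential: int = 12,
    effect: float = 0.5,
    noise_cv: float = 0.2,
    below_floor_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Capability matrix with planted differentially-producible metabolites.

    Two sample groups; ``n_differential`` metabolites get a relative mean
    difference of ``effect`` between groups (planted well above the 10%
    screen threshold), a ``below_floor_fraction`` of metabolites sit below
    the 10 mmol/day production floor, and all values carry gamma noise with
    coefficient of variation ``noise_cv``.  Returns the matrix, the group
    labels, and the planted ground-truth metabolite set.
    """
    rng = np.random.default_rng(seed)
    n_low = int(round(below_floor_fraction * n_metabolites))
    base = np.concatenate([
        rng.uniform(1.0, 8.0, size=n_low),           # below the 10 mmol/d floor
        rng.uniform(15.0, 80.0, size=n_metabolites - n_low),
    ])
    rng.shuffle(base)
    mets = [f"met_{i:03d}" for i in range(n_metabolites)]
    eligible = [i for i in range(n_metabolites) if base[i] > 10.0]
    if n_differential > len(eligible):
        raise ValueError("not enough above-floor metabolites to plant effects")
    planted = sorted(rng.choice(eligible, size=n_differential, replace=False))

    n1, n2 = n_per_group
    samples = [f"g1_{i:03d}" for i in range(n1)] + [f"g2_{i:03d}" for i in range(n2)]
    groups = pd.Series(["g1"] * n1 + ["g2"] * n2, index=samples, name="group")

    shape = 1.0 / noise_cv**2
    values = np.empty((n1 + n2, n_metabolites))
    for j in range(n_metabolites):
        m1 = base[j]
        m2 = base[j] * (1.0 + effect) if j in planted else base[j]
        values[:n1, j] = rng.gamma(shape, m1 / shape, size=n1)
        values[n1:, j] = rng.gamma(shape, m2 / shape, size=n2)
    df = pd.DataFrame(values, index=pd.Index(samples, name="sample"), columns=mets)
    return df, groups, {mets[i] for i in planted}
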