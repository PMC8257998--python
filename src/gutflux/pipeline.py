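"""End-to-end cohort analysis: abundances + taxon models + diet -> statistics.

Chains the stages the way the study design prescribes: coverage filtering
and normalization, community assembly, per-sample NMPC computation through a
shared community LP, capability clustering with phenotype association, and
the differential-production screen between the high- and low-gout clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from cobra import Model

from .assembly import (
    DEFAULT_BIOMASS_WINDOW,
    DEFAULT_COUPLING_FACTOR,
    DEFAULT_MODELED_FRACTION_THRESHOLD,
    CommunityModel,
    build_community_model,
    prepare_abundances,
)
from .containers import AbundanceTable, DietSpec
from .fva import NMPCMatrix, nmpc_matrix_from_abundances
from .stats import (
    AssociationResult,
    ClusterResult,
    cluster_phenotype_association,
    differential_metabolites,
    kmeans_cluster,
    select_high_low_clusters,
)
from .universe import DEFAULT_NMPC_METABOLITES


def build_cohort_model(
    pan_models: dict[str, Model],
    taxa: list[str],
    diet: DietSpec,
    biomass_window: tuple[float, float] = DEFAULT_BIOMASS_WINDOW,
    coupling_factor: float | None = DEFAULT_COUPLING_FACTOR,
) -> CommunityModel:
    """One shared community LP covering every cohort taxon (uniform
    placeholder abundances); per-sample abundances are swapped in later."""
    uniform = {t: 1.0 / len(taxa) for t in taxa}
    return build_community_model(
        {t: pan_models[t] for t in taxa}, uniform, diet,
        sample_id="cohort", biomass_window=biomass_window,
        coupling_factor=coupling_factor, keep_zero_abundance=True,
    )


@dataclass
class StudyResult:
    prepared: AbundanceTable
    nmpc: NMPCMatrix
    clusters: ClusterResult
    high_cluster: int
    low_cluster: int
    association: AssociationResult
    differential: pd.DataFrame


def run_study(
    table: AbundanceTable,
    pan_models: dict[str, Model],
    diet: DietSpec,
    metabolites: list[str] | None = None,
    k: int = 3,
    kmeans_replicates: int = 1000,
    seed: int = 0,
    modeled_fraction_threshold: float = DEFAULT_MODELED_FRACTION_THRESHOLD,
    biomass_window: tuple[float, float] = DEFAULT_BIOMASS_WINDOW,
    coupling_factor: float | None = DEFAULT_COUPLING_FACTOR,
    min_cluster_size: int = 10,
) -> StudyResult:
    """Full capability analysis of one cohort under one diet."""
    metabolites = list(metabolites or DEFAULT_NMPC_METABOLITES)
    modeled = [t for t in table.taxa if t in pan_models]
    prepared = prepare_abundances(table, modeled, threshold=modeled_fraction_threshold)
    cohort = build_cohort_model(
        pan_models, prepared.taxa, diet,
        biomass_window=biomass_window, coupling_factor=coupling_factor,
    )
    nmpc = nmpc_matrix_from_abundances(cohort, prepared, metabolites)
    clusters = kmeans_cluster(
        nmpc.values, k, replicates=kmeans_replicates, seed=seed,
        phenotype=prepared.phenotype,
    )
    high, low = select_high_low_clusters(clusters, min_size=min_cluster_size)
    association = cluster_phenotype_association(clusters, high, low)
    groups = clusters.assignments[clusters.assignments.isin([high, low])]
    differential = differential_metabolites(
        nmpc.values.loc[groups.index], groups,
    )
    return StudyResult(
        prepared=prepared, nmpc=nmpc, clusters=clusters,
        high_cluster=high, low_cluster=low,
        association=association, differential=differential,
    )
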