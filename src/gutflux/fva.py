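"""Flux variability analysis and net maximal production capabilities.

The net maximal production capability (NMPC) of a metabolite for one sample
community is computed from two LPs solved under the community biomass
window: the maximal secretion flux into the fecal compartment (v_fe_max >=
0) and the maximal uptake flux at the diet boundary exchange (v_d_min <= 0
by the secretion-positive sign convention).  NMPC = |v_fe_max + v_d_min|,
i.e. the maximal net community production after discounting what the diet
itself supplies; a metabolite the community can only pass through scores
zero.  Each NMPC is computed independently: values for different
metabolites are not simultaneously achievable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._lp import flux_range, optimize_reaction
from .assembly import (
    COMMUNITY_BIOMASS_ID,
    CommunityModel,
    diet_exchange_id,
    fecal_exchange_id,
)
from .containers import AbundanceTable, DietSpec

#: NMPC values below this are solver noise and snap to exactly zero, so the
#: "not producible" class is a clean zero for the differential screen.
NMPC_ZERO_TOLERANCE = 1e-6


@dataclass
class FVAResult:
    """Per-reaction flux ranges plus solver status per LP."""

    ranges: pd.DataFrame  # index reaction id, columns minimum / maximum
    status: dict[str, tuple[str, str]]

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        row = self.ranges.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])


@dataclass
class NMPCMatrix:
    """Samples x metabolites capability matrix (mmol/day) with provenance."""

    values: pd.DataFrame
    diet: str
    provenance: dict = field(default_factory=dict)
    failed_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)


def fva(
    community: CommunityModel,
    reactions: list[str],
    biomass_window: tuple[float, float] | None = None,
) -> FVAResult:
    """Min/max flux per listed reaction under the community biomass window.

    Results do not depend on the order of ``reactions`` (each pair of LPs is
    independent); a solver failure is recorded in the status and flagged as
    NaN rather than aborting the run.
    """
    model = community.model
    with model:
        if biomass_window is not None:
            model.reactions.get_by_id(COMMUNITY_BIOMASS_ID).bounds = biomass_window
        rows, status = {}, {}
        for rid in reactions:
            vmin, vmax, smin, smax = flux_range(model, rid)
            rows[rid] = (vmin, vmax)
            status[rid] = (smin, smax)
    ranges = pd.DataFrame.from_dict(rows, orient="index", columns=["minimum", "maximum"])
    ranges.index.name = "reaction"
    return FVAResult(ranges=ranges, status=status)


def compute_nmpc(community: CommunityModel, metabolite: str) -> float:
    """NMPC of one metabolite for one community, mmol/day (>= 0)."""
    ex_fe = fecal_exchange_id(metabolite)
    ex_d = diet_exchange_id(metabolite)
    model = community.model
    if ex_fe not in model.reactions or ex_d not in model.reactions:
        return 0.0
    v_fe_max, s1 = optimize_reaction(model, ex_fe, "max")
    v_d_min, s2 = optimize_reaction(model, ex_d, "min")
    if s1 != "optimal" or s2 != "optimal":
        raise RuntimeError(
            f"NMPC LPs failed for metabolite {metabolite!r} in sample "
            f"{community.sample_id!r}: fecal max {s1}, diet min {s2}"
        )
    nmpc = abs(v_fe_max + v_d_min)
    return 0.0 if nmpc < NMPC_ZERO_TOLERANCE else nmpc


def compute_nmpc_matrix(
    models: dict[str, CommunityModel],
    metabolites: list[str],
) -> NMPCMatrix:
    """NMPCs for a set of per-sample community models sharing one diet.

    Samples are independent (any execution order yields identical results);
    a sample whose LPs fail is flagged and its row left missing.
    """
    diets = {c.diet.name for c in models.values()}
    if len(diets) > 1:
        raise ValueError(f"models mix diets: {sorted(diets)}")
    rows, failed = {}, []
    for sample, community in models.items():
        try:
            rows[sample] = [compute_nmpc(community, m) for m in metabolites]
        except RuntimeError:
            failed.append(sample)
            rows[sample] = [math.nan] * len(metabolites)
    first = next(iter(models.values()))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(metabolites))
    values.index.name = "sample"
    return NMPCMatrix(
        values=values,
        diet=diets.pop() if diets else "",
        provenance={
            "biomass_window": list(first.biomass_window),
            "coupling_factor": first.coupling_factor,
        },
        failed_samples=failed,
    )


def nmpc_matrix_from_abundances(
    community: CommunityModel,
    abundances: AbundanceTable,
    metabolites: list[str],
) -> NMPCMatrix:
    """NMPCs for many samples through one shared community LP.

    ``community`` must have been built with every table taxon present
    (``keep_zero_abundance=True``); per sample only the community biomass
    coefficients are swapped, which is equivalent to rebuilding the model
    because coupling pins zero-abundance taxa to zero flux.  This is the
    fast path for cohort-scale screens.
    """
    rows, failed = {}, []
    saved = dict(community.abundances)
    try:
        for sample in abundances.samples:
            row = abundances.reads.loc[sample]
            community.set_abundances({t: float(row[t]) for t in abundances.taxa})
            try:
                rows[sample] = [compute_nmpc(community, m) for m in metabolites]
            except RuntimeError:
                failed.append(sample)
                rows[sample] = [math.nan] * len(metabolites)
    finally:
        community.set_abundances(saved)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(metabolites))
    values.index.name = "sample"
    return NMPCMatrix(
        values=values,
        diet=community.diet.name,
        provenance={
            "biomass_window": list(community.biomass_window),
            "coupling_factor": community.coupling_factor,
        },
        failed_samples=failed,
    )


def write_nmpc_matrix(matrix: NMPCMatrix, path: str | Path) -> None:
    """TSV of the capability matrix plus a JSON provenance sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", float_format="%.6f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "diet": matrix.diet,
        "provenance": matrix.provenance,
        "failed_samples": matrix.failed_samples,
    }, indent=2) + "\n")


def read_nmpc_matrix(path: str | Path) -> NMPCMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return NMPCMatrix(
        values=values,
        diet=meta.get("diet", ""),
        provenance=meta.get("provenance", {}),
        failed_samples=meta.get("failed_samples", []),
    )
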