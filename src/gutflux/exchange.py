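"""Per-taxon flux attribution at production optima and crossfeeding edges.

When community production of a target metabolite is maximized, the optimum
is usually degenerate: many flux patterns achieve it.  A parsimonious
secondary objective (minimize total absolute flux at the fixed optimum)
selects a single reproducible pattern, from which per-taxon secretion and
uptake fluxes on the taxon-lumen exchange reactions are read off.  A
crossfeeding edge exists for a metabolite when one taxon secretes and a
different taxon takes up at least tau mmol/day (default 5) in that pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from cobra.flux_analysis import pfba

from .assembly import CommunityModel, fecal_exchange_id
from .stats import ranksum

DEFAULT_CROSSFEEDING_THRESHOLD = 5.0  # mmol/day
_FLUX_EPS = 1e-9


@dataclass
class FluxBreakdown:
    """Taxa-level exchange fluxes at one production optimum.

    ``fluxes`` is indexed by (taxon, metabolite) with columns ``secretion``
    and ``uptake`` (both >= 0, mmol/day, read from taxon-lumen exchange
    reactions); ``diet_inflow`` and ``fecal_outflow`` are per-metabolite
    lumen boundary flows, so lumen steady state reads: secretion + diet
    inflow = uptake + fecal outflow, per metabolite.
    """

    target: str
    objective_value: float
    fluxes: pd.DataFrame
    diet_inflow: pd.Series
    fecal_outflow: pd.Series


@dataclass
class CrossfeedingEdge:
    metabolite: str
    donor: str
    receiver: str
    donor_secretion: float
    receiver_uptake: float
    threshold: float

    def __post_init__(self) -> None:
        if self.donor == self.receiver:
            raise ValueError("crossfeeding requires distinct donor and receiver")


def maximize_and_attribute(community: CommunityModel, target: str) -> FluxBreakdown:
    """Maximize fecal secretion of ``target``; attribute fluxes to taxa."""
    model = community.model
    ex_fe = fecal_exchange_id(target)
    if ex_fe not in model.reactions:
        raise KeyError(f"no fecal exchange route for metabolite {target!r}")
    with model:
        model.objective = ex_fe
        model.objective_direction = "max"
        solution = pfba(model, fraction_of_optimum=1.0)
    objective = float(solution.fluxes[ex_fe])

    records = []
    inflow: dict[str, float] = {}
    outflow: dict[str, float] = {}
    for met in community.lumen_metabolites:
        inflow[met] = float(solution.fluxes[f"DT_{met}"])
        outflow[met] = float(solution.fluxes[f"FT_{met}"])
        for taxon in community.taxa:
            rid = f"IEX_{met}__{taxon}"
            if rid not in solution.fluxes.index:
                continue
            v = float(solution.fluxes[rid])
            if abs(v) <= _FLUX_EPS:
                continue
            records.append((taxon, met, max(v, 0.0), max(-v, 0.0)))
    fluxes = pd.DataFrame(
        records, columns=["taxon", "metabolite", "secretion", "uptake"]
    ).set_index(["taxon", "metabolite"])
    return FluxBreakdown(
        target=target,
        objective_value=objective,
        fluxes=fluxes,
        diet_inflow=pd.Series(inflow, name="diet_inflow"),
        fecal_outflow=pd.Series(outflow, name="fecal_outflow"),
    )


def detect_crossfeeding(
    breakdown: FluxBreakdown,
    tau: float = DEFAULT_CROSSFEEDING_THRESHOLD,
) -> list[CrossfeedingEdge]:
    """All (metabolite, donor, receiver) edges with both fluxes >= tau.

    Edges are sorted by min(donor secretion, receiver uptake), descending,
    so the strongest exchanges come first.
    """
    edges = []
    if breakdown.fluxes.empty:
        return edges
    by_met = breakdown.fluxes.reset_index().groupby("metabolite")
    for met, grp in by_met:
        donors = grp[grp["secretion"] >= tau]
        receivers = grp[grp["uptake"] >= tau]
        for _, d in donors.iterrows():
            for _, r in receivers.iterrows():
                if d["taxon"] == r["taxon"]:
                    continue
                edges.append(CrossfeedingEdge(
                    metabolite=str(met),
                    donor=str(d["taxon"]),
                    receiver=str(r["taxon"]),
                    donor_secretion=float(d["secretion"]),
                    receiver_uptake=float(r["uptake"]),
                    threshold=tau,
                ))
    edges.sort(
        key=lambda e: (-min(e.donor_secretion, e.receiver_uptake),
                       e.metabolite, e.donor, e.receiver)
    )
    return edges


def crossfeeding_graph(edges: list[CrossfeedingEdge]) -> nx.MultiDiGraph:
    """Directed donor -> receiver multigraph, one edge per metabolite."""
    g = nx.MultiDiGraph()
    for e in edges:
        g.add_edge(
            e.donor, e.receiver, key=e.metabolite,
            metabolite=e.metabolite, secretion=e.donor_secretion,
            uptake=e.receiver_uptake,
        )
    return g


def edges_to_frame(edges: list[CrossfeedingEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.metabolite, e.donor, e.receiver, e.donor_secretion,
          e.receiver_uptake, e.threshold) for e in edges],
        columns=["metabolite", "donor", "receiver", "donor_secretion",
                 "receiver_uptake", "threshold"],
    )


def breakdowns_to_frame(breakdowns: dict[str, FluxBreakdown]) -> pd.DataFrame:
    """Long-format (sample, taxon, metabolite, secretion, uptake) table."""
    frames = []
    for sample, b in breakdowns.items():
        f = b.fluxes.reset_index()
        f.insert(0, "sample", sample)
        frames.append(f)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample", "taxon", "metabolite", "secretion", "uptake"]
    )


def compare_breakdowns(
    groups: dict[str, list[FluxBreakdown]],
    top_k: int = 5,
) -> pd.DataFrame:
    """Group means and rank-sum p per (taxon, metabolite) across two groups.

    Per (taxon, metabolite): mean secretion and uptake within each group
    (samples where the pair carries no flux count as zero), a two-sided
    rank-sum p-value on the secretion fluxes, and the taxon rank by total
    exchanged flux -- sum over groups of |mean uptake| + |mean secretion| --
    from which the figure-style top-k taxa per metabolite are chosen.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, bds in groups.items():
        if not bds:
            raise ValueError(f"group {name!r} has no breakdowns")

    names = list(groups)
    pairs: set[tuple[str, str]] = set()
    for bds in groups.values():
        for b in bds:
            pairs.update(b.fluxes.index)

    def series(b: FluxBreakdown, pair: tuple[str, str], col: str) -> float:
        return float(b.fluxes[col].get(pair, 0.0))

    rows = []
    for taxon, met in sorted(pairs):
        rec: dict[str, object] = {"taxon": taxon, "metabolite": met}
        per_group_secretion = {}
        total_exchange = 0.0
        for name in names:
            sec = [series(b, (taxon, met), "secretion") for b in groups[name]]
            upt = [series(b, (taxon, met), "uptake") for b in groups[name]]
            rec[f"mean_secretion_{name}"] = sum(sec) / len(sec)
            rec[f"mean_uptake_{name}"] = sum(upt) / len(upt)
            per_group_secretion[name] = sec
            total_exchange += abs(rec[f"mean_secretion_{name}"])
            total_exchange += abs(rec[f"mean_uptake_{name}"])
        rec["total_exchange"] = total_exchange
        if len(names) == 2:
            rec["ranksum_p"] = ranksum(
                per_group_secretion[names[0]], per_group_secretion[names[1]]
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["rank_in_metabolite"] = (
        out.groupby("metabolite")["total_exchange"]
        .rank(ascending=False, method="first")
        .astype(int)
    )
    out["top_k"] = out["rank_in_metabolite"] <= top_k
    return out.sort_values(["metabolite", "rank_in_metabolite"]).reset_index(drop=True)
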