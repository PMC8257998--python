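"""Shared tabular containers: abundance tables and diet specifications."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PHENOTYPES = ("gouty", "healthy")


@dataclass
class AbundanceTable:
    """Samples x taxa read counts with per-sample phenotype labels.

    ``reads`` holds unnormalized (or normalized, after
    :func:`gutflux.assembly.prepare_abundances`) abundances, one row per
    sample.  ``modeled_fraction`` is the fraction of each sample's total 16S
    reads covered by the modeled taxa; samples below the coverage threshold
    are dropped before community modeling.  ``archetype`` optionally records
    the generating community archetype for ground-truth recovery tests.
    """

    reads: pd.DataFrame
    phenotype: pd.Series
    modeled_fraction: pd.Series
    archetype: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.reads.values < 0).any():
            raise ValueError("abundance reads must be non-negative")
        for s in (self.phenotype, self.modeled_fraction):
            if not s.index.equals(self.reads.index):
                raise ValueError("phenotype/modeled_fraction index must match reads")
        bad = set(self.phenotype) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.reads.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.reads.columns)

    def to_frame(self) -> pd.DataFrame:
        """Single TSV-ready frame: taxa columns + phenotype + modeled_fraction."""
        out = self.reads.copy()
        out["phenotype"] = self.phenotype
        out["modeled_fraction"] = self.modeled_fraction
        if self.archetype is not None:
            out["archetype"] = self.archetype
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceTable":
        meta = [c for c in ("phenotype", "modeled_fraction", "archetype") if c in frame]
        reads = frame.drop(columns=meta).astype(float)
        return cls(
            reads=reads,
            phenotype=frame["phenotype"],
            modeled_fraction=frame["modeled_fraction"].astype(float),
            archetype=frame["archetype"] if "archetype" in frame else None,
        )


@dataclass
class DietSpec:
    """Maximum dietary uptake rates, mmol/day, one entry per metabolite."""

    name: str
    bounds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, b in self.bounds.items():
            if not (b >= 0 and b < float("inf")):
                raise ValueError(f"diet bound for {met} must be finite and >= 0, got {b}")

    def bound(self, metabolite: str) -> float:
        """Uptake bound for a metabolite; absent metabolites cannot be eaten."""
        return float(self.bounds.get(metabolite, 0.0))

    def scaled(self, factor: float) -> "DietSpec":
        return DietSpec(self.name, {m: b * factor for m, b in self.bounds.items()})
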