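"""Toy metabolite universe and mass-balanced pathway templates.

A small, hand-auditable stand-in for genome-scale gut reconstructions: ~27
named metabolites with integer elemental formulas (C/H/O/N/S) and a registry
of irreversible fermentation / amino-acid pathway templates, each of which is
elementally balanced.  The universe is deliberately large enough to cover the
metabolite classes that differ between gout-associated and healthy-associated
gut communities (short-chain fatty acids, D/L amino acids, branched-chain
catabolites, sulfur species) and small enough that every stoichiometry can be
checked by hand.
"""

from __future__ import annotations

import re
from collections import defaultdict

#: metabolite id -> elemental formula.  "fiber" is a hexose polymer
#: (10 hexose units condensed with loss of 9 waters).
METABOLITES: dict[str, str] = {
    "hexose": "C6H12O6",
    "fiber": "C60H102O51",
    "acetate": "C2H4O2",
    "butyrate": "C4H8O2",
    "formate": "CH2O2",
    "succinate": "C4H6O4",
    "d_lactate": "C3H6O3",
    "l_lactate": "C3H6O3",
    "pyruvate": "C3H4O3",
    "d_alanine": "C3H7NO2",
    "l_alanine": "C3H7NO2",
    "serine": "C3H7NO3",
    "l_cysteine": "C3H7NO2S",
    "l_methionine": "C5H11NO2S",
    "l_valine": "C5H11NO2",
    "l_leucine": "C6H13NO2",
    "l_isoleucine": "C6H13NO2",
    "isobutyrate": "C4H8O2",
    "isovalerate": "C5H10O2",
    "isocaproate": "C6H12O2",
    "m2ovalerate": "C6H10O3",  # 3-methyl-2-oxovalerate
    "h2": "H2",
    "h2s": "H2S",
    "co2": "CO2",
    "nh3": "NH3",
    "h2o": "H2O",
    "sulfate": "H2SO4",
}

#: capability tag -> stoichiometry (negative = consumed).  One reaction per
#: capability; all reactions are written irreversible left-to-right.
CAPABILITIES: dict[str, dict[str, float]] = {
    "fiber_degradation": {"fiber": -1, "h2o": -9, "hexose": 10},
    "hexose_mixed_acid": {"hexose": -1, "h2o": -2, "acetate": 2, "formate": 2, "h2": 2},
    "hexose_to_acetate": {"hexose": -1, "h2o": -2, "acetate": 2, "co2": 2, "h2": 4},
    "hexose_to_succinate": {"hexose": -1, "co2": -2, "h2": -2, "succinate": 2, "h2o": 2},
    "hexose_to_d_lactate": {"hexose": -1, "d_lactate": 2},
    "hexose_to_l_lactate": {"hexose": -1, "l_lactate": 2},
    "hexose_to_pyruvate": {"hexose": -1, "pyruvate": 2, "h2": 2},
    "butyrate_from_hexose": {"hexose": -1, "butyrate": 1, "co2": 2, "h2": 2},
    "butyrate_from_hexose_acetate": {
        "hexose": -1, "acetate": -2, "butyrate": 2, "co2": 2, "h2o": 2,
    },
    "cysteine_to_h2s": {"l_cysteine": -1, "h2o": -1, "pyruvate": 1, "nh3": 1, "h2s": 1},
    "pyruvate_to_d_lactate": {"pyruvate": -1, "h2": -1, "d_lactate": 1},
    "pyruvate_to_l_lactate": {"pyruvate": -1, "h2": -1, "l_lactate": 1},
    "sulfate_reduction": {"sulfate": -1, "h2": -4, "h2s": 1, "h2o": 4},
    "serine_synthesis": {"hexose": -1, "nh3": -2, "serine": 2, "h2": 2},
    "cysteine_synthesis": {"serine": -1, "h2s": -1, "l_cysteine": 1, "h2o": 1},
    "methionine_synthesis": {
        "l_cysteine": -1, "acetate": -1, "h2": -2, "l_methionine": 1, "h2o": 2,
    },
    "alanine_synthesis_d": {"pyruvate": -1, "nh3": -1, "h2": -1, "d_alanine": 1, "h2o": 1},
    "alanine_synthesis_l": {"pyruvate": -1, "nh3": -1, "h2": -1, "l_alanine": 1, "h2o": 1},
    "alanine_catabolism_d": {"d_alanine": -1, "h2o": -1, "pyruvate": 1, "nh3": 1, "h2": 1},
    "valine_to_isobutyrate": {
        "l_valine": -1, "h2o": -2, "isobutyrate": 1, "co2": 1, "nh3": 1, "h2": 2,
    },
    "leucine_to_isovalerate": {
        "l_leucine": -1, "h2o": -2, "isovalerate": 1, "co2": 1, "nh3": 1, "h2": 2,
    },
    "leucine_to_isocaproate": {"l_leucine": -1, "h2": -1, "isocaproate": 1, "nh3": 1},
    "isoleucine_to_m2ovalerate": {
        "l_isoleucine": -1, "h2o": -1, "m2ovalerate": 1, "nh3": 1, "h2": 1,
    },
    "m2ovalerate_synthesis": {"hexose": -1, "h2": -2, "m2ovalerate": 1, "h2o": 3},
    "isoleucine_synthesis": {
        "m2ovalerate": -1, "nh3": -1, "h2": -1, "l_isoleucine": 1, "h2o": 1,
    },
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into element counts."""
    counts: dict[str, int] = defaultdict(int)
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        if not m.group(0):
            break
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return dict(counts)


def element_imbalance(stoich: dict[str, float]) -> dict[str, float]:
    """Net elemental production of a reaction; empty dict means balanced."""
    net: dict[str, float] = defaultdict(float)
    for met, coef in stoich.items():
        for element, n in parse_formula(METABOLITES[met]).items():
            net[element] += coef * n
    return {e: v for e, v in net.items() if abs(v) > 1e-9}


def validate_universe() -> None:
    """Raise if any capability template is not elementally balanced."""
    for tag, stoich in CAPABILITIES.items():
        bad = element_imbalance(stoich)
        if bad:
            raise ValueError(f"capability {tag!r} unbalanced: {bad}")


#: metabolites usually tracked as exchangeable community products (the
#: default NMPC panel); water and the dietary polymers are excluded because
#: their "production" is not biologically meaningful in this universe.
DEFAULT_NMPC_METABOLITES: tuple[str, ...] = (
    "acetate", "butyrate", "formate", "succinate", "d_lactate", "l_lactate",
    "pyruvate", "d_alanine", "l_alanine", "serine", "l_cysteine",
    "l_methionine", "l_valine", "l_leucine", "l_isoleucine", "isobutyrate",
    "isovalerate", "isocaproate", "m2ovalerate", "h2", "h2s", "co2", "nh3",
)
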