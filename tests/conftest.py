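from __future__ import annotations

import pytest

from gutflux.assembly import build_community_model
from gutflux.containers import DietSpec
from gutflux.synthetic import (
    TaxonSpec,
    default_taxon_specs,
    gen_diet,
    gen_taxon_model,
)


@pytest.fixture(scope="session")
def toy_taxon():
    """Single-capability taxon: hexose -> 2 D-lactate, biomass 0.1 hexose."""
    spec = TaxonSpec(
        "toy", frozenset({"hexose_to_d_lactate"}), ("hexose",), {"hexose": 0.1}
    )
    return gen_taxon_model(spec)


@pytest.fixture(scope="session")
def toy_diet():
    return DietSpec("toy_diet", {"hexose": 10.0})


@pytest.fixture()
def toy_community(toy_taxon, toy_diet):
    return build_community_model(
        {"toy": toy_taxon}, {"toy": 1.0}, toy_diet, sample_id="toy_sample"
    )


@pytest.fixture(scope="session")
def named_models():
    return {s.name: gen_taxon_model(s) for s in default_taxon_specs()}


@pytest.fixture(scope="session")
def eud():
    return gen_diet("EUD")


@pytest.fixture()
def bf_community(named_models, eud):
    """Designed two-taxon crossfeeding fixture: an acetate secretor
    (bacteroides-like) plus an obligate acetate-consuming butyrate producer
    (faecalibacterium-like) at equal abundance."""
    return build_community_model(
        {t: named_models[t] for t in ("bacteroides", "faecalibacterium")},
        {"bacteroides": 0.5, "faecalibacterium": 0.5},
        eud,
        sample_id="bf",
    )
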