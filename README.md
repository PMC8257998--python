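# gutflux

Patient-specific metabolic modeling of gut bacterial communities from 16S
relative-abundance data, with the statistical layer needed to associate
community *metabolic capability* with a clinical phenotype (here: gouty
arthritis vs healthy).

Compositional 16S analyses say *who* is in a gut community; they say little
about what the community can *do*. `gutflux` bridges that gap for
microbiome researchers: it assembles an abundance-weighted, diet-constrained
community flux-balance model per stool sample, computes each sample's net
maximal production capability (NMPC) for every exchanged metabolite,
resolves which taxa secrete and consume what at a production optimum
(including crossfeeding edges), and then clusters samples by capability and
screens for differentially producible metabolites between phenotype-enriched
clusters.

## The model

Each taxon is a genome-scale (here: toy, mass-balanced) metabolic network.
For a sample with normalized abundances *a&#8305;*, the community LP joins the
taxon networks through a shared lumen compartment `[u]`, fed from a diet
compartment `[d]` (uptake bounded by the diet's maximum rates, mmol/day) and
drained into a fecal compartment `[fe]`. A community biomass reaction drains
each taxon's biomass with coefficient *a&#8305;* and is confined to the window
**0.4 ≤ b ≤ 1.0 mmol/day**; coupling constraints |v&#11388;| ≤ 400 ·
v<sub>biomass,i</sub> tie every taxon reaction flux to that taxon's biomass
flux, so zero-abundance taxa carry zero flux.

The capability of a community to produce metabolite *m* is

> NMPC(m) = | v<sup>max</sup><sub>fe</sub>(m) + v<sup>min</sup><sub>d</sub>(m) |

where the first term is the maximal fecal secretion flux and the second the
maximal dietary uptake flux (negative by the secretion-positive sign
convention), each from one LP solved under the biomass window. A metabolite
the community can only pass through scores zero. Each NMPC is computed
independently; values for different metabolites are not simultaneously
achievable.

Downstream, samples × metabolites NMPC matrices are clustered with
best-of-1000-replicates k-means++ (squared Euclidean distance; cluster
number selected by mean silhouette under L1 distance), cluster-phenotype
association is tested with Fisher's exact test, and metabolites are flagged
as differentially producible between the high- and low-phenotype clusters
when the Wilcoxon rank-sum test passes Benjamini–Hochberg FDR < 0.05, the
mean capability exceeds 10 mmol/day in at least one cluster, and the means
differ by at least 10%. Taxon–taxon crossfeeding is read off a parsimonious
optimal flux pattern: an edge exists when a donor secretes and a distinct
receiver consumes a metabolite at ≥ 5 mmol/day.

Because the real study's strain reconstructions and patient tables are not
publicly redistributable, `gutflux.synthetic` generates the full study
conditions from scratch: ~50 toy taxa built from hand-auditable,
elementally balanced pathway templates, three community archetypes
(Bacteroides-dominated, Faecalibacterium-elevated, Prevotella-elevated) with
phenotype labels, modeled-fraction coverage, and EU-average / high-protein /
high-fiber diet presets (the high-fiber diet carries 1.84× the EU-average
L-cysteine).

## Worked example

A two-taxon community: an acetate-secreting fermenter (bacteroides-like) and
a butyrate producer (faecalibacterium-like) whose butyrate pathway requires
external acetate, at equal abundance under the EU-average diet:

```python
import gutflux as gf

models = {s.name: gf.gen_taxon_model(s) for s in gf.default_taxon_specs()}
eud = gf.gen_diet("EUD")
community = gf.build_community_model(
    {t: models[t] for t in ("bacteroides", "faecalibacterium")},
    {"bacteroides": 0.5, "faecalibacterium": 0.5},
    eud,
)
for met in ("butyrate", "acetate", "h2s"):
    print(f"NMPC({met}) = {gf.compute_nmpc(community, met):.2f} mmol/day")

breakdown = gf.maximize_and_attribute(community, "butyrate")
print(f"max community butyrate = {breakdown.objective_value:.2f} mmol/day")
for e in gf.detect_crossfeeding(breakdown, tau=5.0):
    print(f"crossfeeding: {e.donor} -> {e.receiver} "
          f"({e.metabolite}, {min(e.donor_secretion, e.receiver_uptake):.2f} mmol/day)")
```

prints

```
NMPC(butyrate) = 59.96 mmol/day
NMPC(acetate) = 119.86 mmol/day
NMPC(h2s) = 7.00 mmol/day
max community butyrate = 59.96 mmol/day
crossfeeding: bacteroides -> faecalibacterium (acetate, 59.96 mmol/day)
crossfeeding: faecalibacterium -> bacteroides (h2o, 59.96 mmol/day)
crossfeeding: bacteroides -> faecalibacterium (hexose, 20.00 mmol/day)
```

The butyrate producer cannot make butyrate alone (its pathway consumes one
acetate per butyrate); the community reaches 59.96 mmol/day only because the
fermenter crossfeeds acetate — remove it and community butyrate drops to
zero. H2S capability (7 mmol/day) is capped by the diet's cysteine plus
sulfate supply. Cohort-scale runs go through `gutflux.run_study`, which
filters samples below 90% modeled-taxa coverage, computes the NMPC matrix
through one shared community LP, clusters it, and runs the differential
screen; the `gutflux` command-line tool (`nmpc`, `cluster`, `diffprod`,
`associate`) wraps the same calls for TSV-file workflows.

## Layout

- `gutflux.universe` — toy metabolite universe and balanced pathway templates
- `gutflux.synthetic` — taxon/strain/abundance/diet generators (study conditions)
- `gutflux.assembly` — pan-taxon merging, coverage filtering, community LP assembly
- `gutflux.fva` — flux variability analysis and NMPC matrices
- `gutflux.exchange` — per-taxon flux attribution and crossfeeding detection
- `gutflux.stats` — clustering, association, differential screen, diet comparison
- `gutflux.pipeline` / `gutflux.cli` — end-to-end study driver and CLI

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
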