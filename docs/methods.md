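# Methods

## Community model formulation

Each taxon model is a single-compartment stoichiometric network: one
irreversible reaction per pathway capability, an exchange reaction per
importable/secretable metabolite (flux > 0 = secretion; uptake is allowed
only for the taxon's dietary preferences), and a biomass reaction consuming
precursor metabolites (default 0.1 hexose per unit biomass flux).

A sample's community model joins the taxon networks through pooled
compartments:

- taxon metabolites and reactions are tagged `__<taxon>`;
- each taxon exchange becomes a taxon–lumen reaction
  `IEX_<met>__<taxon>: met__taxon -> met_u` carrying the taxon's original
  bounds;
- per lumen metabolite: a diet transport `DT_<met>: met_d -> met_u` with
  upper bound equal to the diet's maximum uptake rate (0 for metabolites
  absent from the diet), a boundary diet exchange `EX_<met>_d` written as
  `1 met -> (nothing)` and bounded to `[-rate, 0]`, a fecal transport
  `FT_<met>: met_u -> met_fe` and a boundary fecal exchange `EX_<met>_fe`
  bounded to `[0, 10000]`;
- a community biomass reaction drains each taxon's biomass metabolite with
  the taxon's relative abundance as coefficient, bounded to the window
  `[0.4, 1.0]`. The printed units are mmol/day, but the quantity enters
  the LP as a dimensionless flux with that window; only the window's
  numeric values matter to the optimization. With this construction the
  taxon biomass flux equals abundance × community biomass flux.

**Coupling constraints.** For each taxon reaction *j* of taxon *i* (internal
and taxon–lumen), `|v_j| <= kappa * v_biomass,i` with `kappa = 400` by
default. The convention is the one community-FBA pipelines commonly use; it
is configurable (`coupling_factor`, `None` disables it) because the exact
value is not identifiable from data. Its two roles: zero-abundance taxa are
pinned to zero flux, and a low-abundance taxon cannot dominate community
production. Abundances enter only the community biomass coefficients and,
through the taxon biomass flux, the coupling — never the reaction bounds.

**Diet.** A diet is a metabolite → maximum uptake rate map (mmol/day).
Because no public numeric tables exist for the study diets, the EU-average
(EUD), high-protein (HPD) and high-fiber (HFD) presets here are structural
stand-ins at physiologically plausible magnitudes, fixed once: EUD supplies
fiber 5, hexose 10, free amino acids 1–3, sulfate 5, ammonia 20, CO2 50 and
water 1000 mmol/day; HPD multiplies the amino-acid bounds by 2.5; HFD
triples fiber and carries 1.84× the EUD L-cysteine (84% more). Acetate is
deliberately absent from every diet so that acetate-dependent butyrate
synthesis can only be fed by crossfeeding.

## NMPC

For metabolite *m*: `NMPC(m) = |v_fe_max + v_d_min|`, with `v_fe_max >= 0`
the maximal flux of `EX_<m>_fe` and `v_d_min <= 0` the minimal (most
negative = maximal uptake) flux of `EX_<m>_d`, each from one LP under the
biomass window. "Uptake from the lumen" is bound to the diet boundary
exchange; binding it to the diet transport instead would give identical
values here because the transport and the boundary exchange carry the same
flux at steady state. A metabolite without lumen routes scores 0, and values
below 1e-6 snap to exactly 0 so the "not producible" class stays clean for
the differential screen. Each NMPC is an independent optimum; NMPCs of
different metabolites are generally not simultaneously achievable. The
production-side FVA pair is what the NMPC formula consumes; minimal
production / minimal uptake are available through the generic `fva` entry
point for completeness.

Cohort runs reuse one shared community LP containing every modeled taxon and
swap only the community biomass coefficients per sample
(`nmpc_matrix_from_abundances`); this is equivalent to rebuilding per sample
— a taxon with coefficient zero has its biomass flux, and through coupling
all its fluxes, forced to zero — and is tested against fresh builds.

## Pan-taxon merging

The pan model of a taxon is the reaction union over its strain models
(identical stoichiometry required per reaction id; widest bounds win).
Unions can create futile cycles; the exact mitigation rule of the original
pan-model builders is not published, so the heuristic here is a documented
stand-in: with all boundary exchanges closed, any internal reaction that can
still carry flux is in a thermodynamically impossible loop; each such
reaction is restricted to the direction it carries in at least one strain's
default bounds, and a loop consisting of irreversible reactions is broken by
closing its alphabetically first member. The pass repeats (bounded at 10
iterations) until closed-exchange variability is zero. Every bound change is
appended to the model's provenance log (`model.notes["provenance"]`).

## Flux attribution and crossfeeding

Production optima are degenerate, so a reported flux pattern must be chosen
deterministically: after maximizing fecal secretion of the target, the
objective is fixed at its optimum and total absolute flux is minimized
(parsimonious FBA). Per-taxon secretion and uptake are read from the
taxon–lumen reactions only — boundary exchanges belong to the community, not
to a taxon. A crossfeeding edge (metabolite, donor, receiver) requires donor
secretion and receiver uptake both ≥ τ in that pattern, with τ = 5 mmol/day
by default (configurable); edges sort by the limiting flux, descending.
Water and currency-like metabolites pass the threshold too; consumers can
filter edges by metabolite.

## Statistical layer

- **Clustering:** k-means++ with squared Euclidean distance, best of 1000
  replicates by total within-cluster sum of squares (`scikit-learn`,
  `n_init`). Cluster ids are relabeled by descending size (ties by original
  label) since raw k-means labels are arbitrary.
- **Cluster number:** mean silhouette under L1 (sum-of-absolute-differences)
  distance over candidate k, 100 replicates per k, ties broken toward the
  smallest k. The partition scored is the Euclidean k-means one; only the
  silhouette metric is L1.
- **Association:** two-sided Fisher's exact test on gouty/healthy counts of
  two clusters (hypergeometric sum of tables at fixed margins with point
  probability ≤ the observed). A zero margin returns p = 1, flagged. For a
  cluster-versus-cohort question both 2×2 orientations (cluster vs
  complement, cluster vs full set) can be formed with `fisher_exact_2x2`;
  the package does not privilege one, as the choice is a matter of taste.
- **High/low phenotype clusters:** among clusters with ≥ 10 samples
  (configurable), the highest and the lowest gouty fraction; small outlier
  clusters are excluded from the differential screen.
- **Differential screen:** per metabolite, two-sided Wilcoxon rank-sum
  between the two clusters (exact enumeration when the smaller sample has
  ≤ 10 observations and no ties; otherwise normal approximation with tie and
  continuity corrections), Benjamini–Hochberg over all tested metabolites.
  Metabolites with all-zero capability in both groups are reported untested
  and excluded from the family. Differential ⇔ q < 0.05 AND max cluster
  mean > 10 mmol/day AND relative mean difference ≥ 10%, where the relative
  difference uses the larger mean as denominator (the threshold's wording
  admits either convention; this one is the stricter and is configurable).
- **Proportionality:** ρ_p = 2·cov(log x, log y)/(var log x + var log y);
  zeros are replaced by half the smallest nonzero value across the two
  vectors (configurable pseudocount); zero total log-variance is flagged
  undefined.
- **Diet comparison:** cross-diet membership concordance is the Rand index
  between the two partitions (fraction of sample pairs co-assigned in both);
  clusters are matched across diets by maximal sample overlap (Hungarian
  assignment) and a per-metabolite rank-sum + BH screen runs between matched
  clusters.

## Synthetic study conditions

The generator reproduces the study design, not its data. Defaults, fixed a
priori:

- **Taxa:** 50 models — 12 named blueprints anchored to distinct
  fermentation strategies (a fiber-degrading acetate/formate/H2S/
  branched-chain-catabolizing bacteroides-like taxon; a faecalibacterium-like
  butyrate producer whose pathway `hexose + 2 acetate -> 2 butyrate + 2 CO2 +
  2 H2O` obligately requires external acetate; a succinate/lactate/pyruvate
  prevotella-like fiber degrader with no mixed-acid products; plus
  roseburia/coprococcus/subdoligranulum/lachnospiraceae/escherichia/shigella/
  megamonas/clostridium/akkermansia-like blueprints) and 38 seeded generic
  fermenters. All pathway templates are elementally balanced over C/H/O/N/S;
  the ~27-metabolite universe is small enough to audit by hand while covering
  every differential metabolite class the analysis screens (short-chain fatty
  acids, D/L amino acids, branched-chain catabolites, sulfur species).
- **Archetypes:** bacteroides-dominated (0.75 bacteroides, gout probability
  22/26), faecalibacterium-elevated (0.15 faecalibacterium, 11/44),
  prevotella-elevated (0.45 prevotella, 6/8). Compositions are Dirichlet
  with concentration 60 around the archetype mean — the standard
  compositional noise model; 60 gives within-archetype variability large
  enough to be visible yet small enough that archetypes remain real
  clusters. Default sample counts 26/44/8 mirror the study's cluster sizes
  but are parameters.
- **Coverage:** per-sample modeled fraction uniform on (0.89, 1.0) — mean
  0.945, with roughly a tenth of samples falling below the 0.90 filter, so
  the coverage filter is exercised on every generated cohort. Read depth
  20000.
- **Planted-effect matrices** (`gen_nmpc_matrix`) test the screen's
  operating characteristics without the LP layer: 40 metabolites, a quarter
  below the 10 mmol/day floor, 12 planted effects of +50% relative mean
  difference on gamma noise with CV 0.2 at group sizes 26/44. The +50%
  effect is a designed, comfortably detectable size — the test asks whether
  the screen's thresholds and FDR control behave, not where its detection
  boundary lies.

What the synthetic data does **not** emulate: genome-scale network size
(dozens of reactions per taxon instead of thousands), strain-level pathway
variation within genera, read-count overdispersion beyond Dirichlet,
covariate structure (age, sex, BMI), and any direct metabolic coupling
between phenotype label and composition beyond the archetype gout
probabilities. Passing tests therefore demonstrate that the pipeline's
inference machinery is correct and well-calibrated under the designed
conditions, not that the toy communities quantitatively reproduce real gut
metabolic fluxes.

## Numerical choices

- LP feasibility/optimality tolerance 1e-9 (GLPK through optlang); taxon
  model bounds ±1000, community plumbing bounds 10000.
- NMPC values < 1e-6 snap to 0; crossfeeding fluxes < 1e-9 are dropped from
  breakdowns.
- Vertex-degenerate optima are resolved by parsimonious FBA (above); k-ties
  in silhouette selection resolve to the smallest k; crossfeeding edges are
  sorted deterministically by (limiting flux, metabolite, donor, receiver).
- Diet-scaling homogeneity (scaling all diet bounds by λ ≥ 1 scales maximal
  secretion by ≤ λ) holds exactly with the biomass floor relaxed to 0; with
  the 0.4 floor active the fixed biomass cost is amortized and secretion can
  grow marginally faster than λ.
- Every stochastic step takes an explicit integer seed
  (`numpy.random.default_rng`, scikit-learn `random_state`); reruns with
  equal seeds are byte-identical in all TSV outputs.

## Problem sizes

Default analysis scale: 50 taxa, 78 samples (26/44/8), a 23-metabolite
capability panel, 1000 k-means replicates, 100 silhouette replicates per
candidate k ∈ [2, 6], 20 generator seeds for the screen's operating
characteristics. One full cohort analysis solves ~3600 LPs through the
shared community model and completes in well under a minute on one CPU.

## Known limitations

- FVA capabilities are upper bounds under steady state; no thermodynamic,
  kinetic or regulatory constraints, and no flux sampling of the optimal
  face — a single parsimonious pattern stands in for the optimum's interior.
- The coupling convention (linear, κ = 400) and the futile-cycle heuristic
  are documented stand-ins for unpublished pipeline internals.
- 16S data cannot resolve species or strains; pan-taxon models inherit this
  limit by construction.
- Diet presets are structural; absolute NMPC magnitudes track the assumed
  diet bounds and should be compared within, not across, diet definitions.
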