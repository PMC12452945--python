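# Methods

## Scope and model

`trufflenet` analyzes sample × taxon abundance tables from small amplicon
surveys of truffle ascomata (two species, surface vs gleba compartments,
3–4 replicates per group). Its core is a compositional co-occurrence
pipeline — CLR normalization, rare-taxon filtering, FDR-corrected all-pairs
Pearson correlation, signed network construction, and Zi–Pi topological
characterization — plus per-compartment composition statistics. Everything
upstream of the abundance table (read QC, ASV inference, taxonomy
assignment) is out of scope.

## Preprocessing

**Order.** The fixed, logged order is closure → prevalence filter → zero
replacement → CLR. Whether rare-taxon removal should precede or follow the
CLR transform is genuinely ambiguous in practice (dropping columns changes
every sample's geometric mean). We filter first and recompute the CLR on the
filtered composition, because correlations are then computed in the same
coordinate system that defines the tested taxa; the alternative order is
available through `preprocess_pipeline(filter_first=False)`, which keeps the
full-composition coordinates and drops rare columns afterwards (its rows no
longer sum to zero — the container records this with `centered=False`).

**Prevalence rule.** A taxon is kept iff detected (abundance > 0) in at
least 10% of samples — the rule removes "prevalence < 10%", so the boundary
case is kept. Prevalence is always computed on true zeros, never after zero
replacement. Default `min_prevalence = 0.10`.

**Zero replacement.** Default is multiplicative replacement (via
scikit-bio's `multi_replace`) with δ = 0.5 × the smallest nonzero relative
abundance in the table: zeros become δ, observed components are rescaled so
each row still closes. This preserves ratios among observed components,
which a flat pseudocount does not; pseudocount (+1 per count) remains an
option for count tables. The global (not per-sample) minimum defines δ so
that replaced values are comparable across samples.

**CLR.** Natural logarithm; entry (i,j) = ln x_ij − mean_k ln x_ik. Row
centering is validated at 1e-8. The transform is scale-invariant per sample,
so counts and percentages give identical coordinates.

## Correlation network

Pearson r on CLR columns for all unordered pairs, enumerated in
lexicographic taxon order; two-sided p from t = r√((n−2)/(1−r²)) with n−2
degrees of freedom. At |r| = 1 the p-value is 0 by convention. Pairs with a
zero-variance column (possible after aggressive filtering at n = 3–4) are
emitted as undefined with a logged warning and excluded from FDR rather than
raising, so small real datasets still run.

Benjamini–Hochberg is the FDR procedure (delegated to statsmodels; the
step-up arithmetic is independently checked in the tests). The significance
threshold of the edge rule is interpreted on the **adjusted** value
(q ≤ 0.05): applying it to raw p would make the correction inert. A
`use_raw_p` flag documents the alternative reading. Edge rule:
|r| ≥ 0.1 AND q ≤ 0.05; sign = sign(r). Nodes are all taxa that entered
testing, so isolated taxa keep the node count equal to the filtered taxon
count.

Pearson-on-CLR is the specified estimator; compositionally robust
alternatives (SparCC, SPIEC-EASI) are deliberately not implemented.

## Topology

All metrics use the unweighted, unsigned skeleton; edge sign is reporting
metadata. Density = 100·2E/(N(N−1)); average clustering is the mean local
coefficient with degree-<2 nodes contributing 0 (networkx).

**Community detection** must be deterministic and, on the small graphs this
package targets (7–24 nodes), as close to the true modularity optimum as is
affordable. `detect_communities` therefore partitions each connected
component independently — merging modules across components can only lower
Q, since it leaves e_c unchanged and grows a (d_c/2m)² term — and solves
components of ≤ 10 nodes **exactly** by enumerating set partitions
(restricted-growth strings; Bell(10) ≈ 1.2e5 candidates scored with the
global edge count m). Larger components use greedy agglomeration
(Clauset–Newman–Moore) followed by deterministic single-node hill climbing.
Ties are resolved by enumeration order (first maximum in canonical RGS
order), so runs are reproducible without any seed. The exhaustive-search
oracle in the test suite confirms the detected Q equals the global maximum
on random graphs up to 8 nodes.

**Modularity** is Newman–Girvan Q on the unweighted graph (networkx);
Q of an edgeless graph is defined as 0 with a warning.

**Zi** uses the *population* standard deviation of within-module degrees:
this convention reproduces the analytic extremes of minimal 3-node modules
exactly (center of a 2-edge star: +1.414; its leaves: −0.707; the edgeless
member beside a single edge: −1.414). Zi = 0 when the module has fewer than
2 members or zero degree spread — hence a complete graph under one module
has Zi = 0 everywhere. **Pi** = 1 − Σ_s (k_is/kᵢ)², 0 for isolated nodes;
a node with one edge into each of three modules attains 0.667.

**Roles** follow the canonical Zi–Pi quadrants at Zi = 2.5 and Pi = 0.62
(module hub / network hub / connector / peripheral); both cutoffs are
configurable since they are conventions, not estimates.

**Reporting precision:** percentages 1 d.p., modularity 4 d.p., Zi/Pi 3 d.p.

## Composition statistics

Group summaries report arithmetic mean ± sample SD (n−1 denominator; SD = 0
for n = 1) of OTU%. The Mann–Whitney U test uses midranks for ties; the
exact null distribution is enumerated when n₁+n₂ ≤ 12 with no ties —
always the case at 3–4 replicates per compartment, where the normal
approximation is poor — otherwise the tie- and continuity-corrected normal
approximation applies. All-constant input short-circuits to U = n₁n₂/2,
p = 1. No multiplicity correction is applied across taxa in this screen.
A group's presence of a taxon means abundance > 0 in ≥ 1 replicate;
`shared_unique` reports taxa present in all four groups and taxa private to
one.

## Synthetic data generator

The generator is a latent log-normal / multinomial model — the minimal
generative process that produces compositional closure, sequencing-depth
variation, and controllable inter-taxon correlation:

- latent z ~ MVN(μ, Σ) per sample, Σ unit-diagonal with planted blocks at
  `within_module_rho` plus optional cross-module entries (PSD validated at
  construction);
- per-taxon baselines μⱼ ~ N(0, `base_log_mean_spread`), default spread 1.0
  (about an order of magnitude of abundance heterogeneity, typical of
  family-level tables);
- proportions = softmax(z); counts ~ Multinomial(depth, proportions), so
  counts sum exactly to the drawn depth;
- depth ~ log-normal around `sequencing_depth` with `depth_dispersion`
  (0 ⇒ constant). Default depth 10,000 reads — the minimum per-sample output
  of the sequencing runs this emulates — with dispersion 0.3;
- a trailing `rare_taxon_fraction` (default 0.2) of non-module taxa has μ
  depressed by 12 log units, putting expected counts below one read per
  sample up to depths of ~1e5 so they fall under the 10% prevalence rule in
  expectation;
- an optional gleba-side log-mean shift (`compartment_effect`, default 0) on
  a few non-module taxa provides a planted compartment difference for the
  Mann–Whitney stage.

Defaults mirror the emulated study design: 2 species × 2 compartments × 4
replicates, 25 taxa, two planted 5-taxon modules at ρ = 0.8. All randomness
flows from a single `numpy` Generator seeded by `SimConfig.seed`; one seed
fixes tables, metadata and ground truth bit-for-bit.

What the generator does **not** emulate: taxonomic mis-assignment,
sequencing error and chimeras, overdispersion beyond the multinomial
(no Dirichlet stage), phylogenetic correlation among taxa, and
batch/extraction effects. Passing recovery tests therefore show that the
pipeline recovers latent correlation structure under clean compositional
sampling — not that it is robust to those artifacts.

`evaluate_recovery` matches inferred to planted edges sign-aware;
sensitivity = |true ∩ inferred|/|true|, precision = |true ∩ inferred|/
|inferred|, with zero inferred edges reported as precision 1.0 plus an
explicit `zero_inferred` flag (no division by zero in threshold sweeps).
Networks built after prevalence filtering legitimately lack the rare taxa,
so the node set may be a subset of the truth universe; unknown nodes raise.

## Pipeline and CLI

`run_pipeline` executes preprocess → correlations → FDR → network → topology
→ composition statistics, logging each stage's parameters and survivor
counts. Correlation networks are built per species with compartments pooled:
at 3–4 replicates per compartment, pooling is what makes Pearson p-values
usable at all, and one network per species is the natural comparison unit.
`pool="all"` merges everything into one network instead. Outputs are written
at fixed precision (`%.10g`), so identical inputs and config give
bit-identical bundles; the effective config is written into the bundle
(minus the bundle's own path). Force-directed layout coordinates are not
computed — layout is cosmetic and renderer-specific; GraphML carries the
attributes (sign, |r| weight, phylum, Zi, Pi, role) that renderers need.

## Test problem sizes

The statistical-control tests run 20 replicate simulations each: the
false-positive check at 40 independent taxa and 50 samples per network, and
the planted-module recovery at 100 samples per group and depth 1e5 — sizes
at which the expected behavior (FDR ≤ 0.05; sensitivity ≥ 0.9) is
well-separated from noise while the whole suite stays fast. Exhaustive
community-detection and triangle-count oracles cover graphs up to 8 and 12
nodes respectively.

## Known limitations

- Pearson-on-CLR still carries a mild negative compositional bias
  (≈ −1/(D−1) between independent taxa); at the default thresholds this is
  harmless, but very small taxon sets would inflate negative edges.
- With 3–4 replicates per compartment, the network stage is honest but
  near-powerless after FDR correction; this mirrors the underlying method's
  behavior at that n rather than a defect of the implementation.
- Exact community detection is limited to components of ≤ 10 nodes; beyond
  that the greedy + local-move result is a good, deterministic heuristic but
  not guaranteed optimal.
- The Mann–Whitney exact switch ignores ties (midrank + normal approximation
  is used whenever ties occur), the standard compromise.
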