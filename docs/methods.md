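# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, the numerical decisions, what the
synthetic-data generator does and does not emulate, and known
limitations.

## Data model

The central object is the long-format link table: one row per
(site, tree, host taxonomy, insect species, life stage, count).
Validation enforces a consistent taxonomy (each tree one
species/genus/family triple; species nest in genera, genera in
families), nonnegative integer counts, and known life stages; duplicate
rows aggregate by summing counts. Because the insects are sessile after
first-instar dispersal, only second instars and adult females evidence
establishment; all statistics operate on this establishment view.
Colonization is tree-wise: a species colonizes a tree if it has at least
one establishment-stage record there. Abundance on a tree pools second
instars and adult females.

Missing sequence at a locus is represented by absence from that locus's
alignment rather than an all-gap row, which makes "taxa present in a
gene tree" well defined for the concordance method. Nucleotides are
case-folded, U→T; N and IUPAC ambiguity codes are treated as missing for
both trimming and distances (conservative divergence).

## Alignment preparation

Trimming keeps exactly the columns with unambiguous nucleotides in at
least a fraction *f* of specimens (default *f* = 0.8, boundary
inclusive — a literal reading of "at least"). Trimming is idempotent and
monotone in *f*. The supermatrix concatenates loci over the union of
specimens, filling missing loci with gaps and recording 1-based
inclusive column ranges per locus.

Divergence defaults to the uncorrected p-distance on the trimmed
supermatrix: mismatches over sites where both sequences carry an
unambiguous base; pairs with no comparable sites are flagged missing
(NaN), never silently zero. Patristic distance on a supplied tree is the
config alternative. The underlying field practice does not pin down one
divergence measure; p-distance was chosen as the assumption-free default
and is documented as such, not asserted as anyone's historical choice.

## Species delimitation

Candidate clades are the union of all clades of the three gene trees.
A clade's status in a tree is computed on its restriction to the tree's
leaves: restrictions of size ≤ 1 or equal to the whole leaf set are
uninformative; otherwise present if monophyletic, else contradicted.
Independent lineages are candidates present in ≥ 2 trees and
contradicted in none. Provisional species are lineages with ≥ 3
specimens containing no qualifying (≥ 3) lineage as a proper subset;
nested lineages with < 3 members do not disqualify their parent
(otherwise any concordant cherry would veto its species). When partial
leaf overlap lets two lineages overlap without nesting, the one present
in more trees wins, ties broken by size then lexicographic specimen ids
— deterministic by construction.

The rescue threshold is the minimum pairwise divergence between members
of different provisional species. Unplaced specimens farther than the
threshold (strict >) from every other specimen become singleton species;
the rest attach greedily by single linkage, and mutually close unplaced
specimens seed new clusters. With fewer than two provisional species the
threshold is undefined; the fallback is the maximum within-species
divergence of the provisional species (or, with none, a single-linkage
clustering at infinite threshold), chosen so the procedure always yields
a total partition.

Rooting: trees carrying an explicit rooted flag are used as parsed;
plain Newick with branch lengths is midpoint-rooted before clade
enumeration inside `delimit()` (configurable); trees without branch
lengths are used as read, since midpoint rooting is undefined for them.

## Diet specificity

Simpson's reciprocal index 1/D = 1/Σpᵢ² counts effective host taxa,
with pᵢ the share of a species' colonized trees in taxon i (trees, not
specimen counts, per the tree-wise colonization definition; a
specimen-weighted variant is a config option). Species observed on a
single tree contribute 1/D = 1 and are included.

The null model randomizes the species-by-tree incidence by checkerboard
2×2 swaps (proposals draw two 1-cells; if the complementary cells are 0
the submatrix flips). This proposal is symmetric, so the walk's
stationary distribution is uniform over binary incidences with the
observed marginals; 10× the number of associations successful swaps are
performed per null table. This conserves per-tree link counts and every
species' number of colonized trees, and — critically — never places a
species twice on one tree, so null tables are exchangeable with the
observed table under random host use. A naive shuffle of the species
column across link rows lacks this property: it generates multigraph
tables that real data cannot contain and makes the test anticonservative
at realistic link densities (measured rejection rates of 0.85–1.0 at
α = 0.05 under a true null), which is why the incidence-swap
randomization is the implementation.

The test statistic is the mean 1/D over species; Z against the null
mean/SD (SD with one delta degree of freedom), two-sided normal p.
A degenerate null (SD = 0) is reported with a warning rather than a
fabricated p.

## Phylogenetic signal

The liability model is l = μ + u + e, u ~ N(0, σ²ₚ·V/s), e ~ N(0, I),
y = 1{l > 0}, where V is the Brownian covariance (MRCA depths) of the
species tree and s normalizes V to unit mean diagonal so σ²ₚ is
comparable across trees and the estimate is invariant to rescaling all
branch lengths. The residual variance is fixed at 1 — the binary
threshold model is otherwise unidentifiable — a convention, documented
as such. The signal statistic is h² = σ²ₚ/(σ²ₚ + 1) ∈ [0, 1].

Fitting is Gibbs sampling with data augmentation: truncated-normal
updates of l given (μ, u, y) via inverse-CDF sampling; the
phylogenetic effect sampled in V's eigenbasis (diagonal conditional
covariance, so each sweep is O(n) after one eigendecomposition); a flat
prior on μ; and a parameter-expanded half-Cauchy(1) prior on σₚ via an
auxiliary inverse-gamma variable, giving conjugate inverse-gamma updates
for σ²ₚ. Default chain: 13,000 iterations, 3,000 burn-in, thinning 10;
an autocorrelation-based effective-sample-size diagnostic is reported.
Eigenvalues are clipped at 1e-10; a non-PSD V or a constant y raises.

Host taxa are testable when ≥ 2 species use and ≥ 2 do not (the model
is undefined near-constant columns); this inclusion rule is a documented
choice. Null matrices come from the same checkerboard swap machinery
(10× associations), preserving diet breadths and taxon prevalences
exactly; null h² values are refit with shorter chains (default 2,600
iterations) as a fidelity/runtime trade-off, configurable. Per-taxon Z
tests are corrected by Benjamini–Hochberg FDR at q = 0.05 separately
within each host-taxonomic level, since the three levels re-express the
same data.

## Trade-off models

Abundance: one record per (species, colonized tree), response = pooled
establishment count (≥ 1 by construction), Poisson with log link.
Occupancy: one record per observed (species, host taxon) pair, response
= trees colonized out of trees surveyed in the taxon, binomial with
logit link, excluding taxa with < 3 surveyed trees. The surveyed-tree
census is a required explicit input — the link table lists only
colonized trees. Diet breadth enters untransformed on the link scale.

Fits use iteratively reweighted least squares (statsmodels GLM;
convergence at relative deviance change < 1e-10 within 50 iterations);
non-convergence flags the fit instead of raising. Significance is
permutation-based: diet breadth is shuffled across species — the
species, not the record, is the exchangeable unit, and per-record
shuffling would break within-species predictor constancy (a per-record
variant remains available) — propagated to records, and the model refit;
Z is the empirical slope against the null-slope mean/SD, two-sided
normal p. More than 10% failed null fits aborts the test.

## Synthetic-data generator

The generator emulates a single survey site shaped like a tropical
canopy survey: by default 50 insect species on 90 individual trees
spanning 53 host species grouped 1-per-genus, 2-genera-per-family
(≈ 27 families); every host species receives one tree and the remaining
trees go to random species, mimicking rounds of one-individual-per-
species sampling. The insect phylogeny is an ultrametric birth–death
tree normalized to depth 1.

Host use per taxon comes from thresholded liabilities:
√h²·(Brownian sample on V) + √(1−h²)·iid normal, with the top
`prevalence` fraction of species (default 0.15, a documented default;
no field value exists) marked as users, and any all-zero species row
repaired with its maximum-liability taxon. The `specialist` regime
confines each species to its best host family; `mixed` (the default)
applies that to half the species; default h² = 0.5, between the two
site-level signal means reported for this system. For single-trait
recovery studies a quantile-threshold variant reproduces
bivariate-normal orthant probabilities exactly and applies no row
repair.

Colonization of a usable tree is Bernoulli with logit(p) = logit(base)
+ β_occ·(breadth − mean breadth) (base 0.5); colonized trees draw
1 + Poisson(max(λ·exp(β_abund·centered breadth) − 1, 0)) adult females,
guaranteeing count ≥ 1 with mean λ (default 3) at β_abund = 0. Defaults
β_abund = 0 and β_occ = 0.2 mirror the effect directions reported for
this system (no abundance effect, modest positive occupancy effect). A
species whose colonization draws all fail is granted one tree so every
true species is observed — harmless for the permutation tests, which
condition on the observed link structure.

Gene trees: a species tree is simulated, scaled to depth 0.1, and every
species-level terminal branch raised to ≥ 0.03; species with < 3
specimens get + 0.5 extra depth so they are rescuable by the divergence
threshold. The shallow scale keeps between-cluster p-distances in the
quasi-linear substitution regime (≲ 0.25) while the singletons' extra
depth pushes them toward saturation (≳ 0.45), so rescue holds by
construction rather than by luck. Each of three gene trees clones the species tree, applies one
species-level NNI with probability 1 − concordance, and replaces each
species tip with a shallow random binary specimen subtree (branch
lengths ≤ 0.004, shared topology across loci). Sequences evolve by a
fixed-rate Jukes–Cantor-style sampler (600 bp per locus) — adequate
because only distances and topologies feed downstream. Locus dropout
(default 0.2) removes specimens from single loci while guaranteeing ≥ 2
loci per specimen, exercising the partial-overlap concordance logic.

What the generator does *not* emulate: real site-level species-abundance
distributions, spatial autocorrelation among trees, phenology,
morphology-based identification, and codon/indel sequence evolution.
Passing tests therefore validate the statistical machinery under the
stated model, not the field realism of any particular dataset.

## Validation experiment sizes

The validation suite and `scripts/acceptance.py` use these problem
sizes, chosen as the package's own desk-scale study conditions:

- Type-I calibration: 30 insect species, 60 trees, 30 host species,
  unconstrained host use (prevalence 1, colonization probability 0.15
  per tree), 200 permutations per test, 200 replicates. Rejection rates
  are judged against binomial 95% Monte-Carlo bounds around 0.05.
- Specificity power: same size, specialist regime, prevalence 0.15;
  ≥ 90% of runs must give Z < 0 with p < .05.
- h² recovery: 100-tip trees, 20 datasets (script: 8) of 5 (script: 3)
  liability traits per target h² ∈ {0, 0.4, 0.8}; chains of 4,000
  iterations. The dataset-level recovered value is the mean
  posterior-mean h² over traits: a single 100-tip binary trait carries
  so little information that its realized signal scatters ~0.18 around
  the target, which no estimator can undo, while dataset-level averaging
  isolates estimator error (MAE ≈ 0.14/0.06/0.07, monotone).
- Occupancy sign recovery: 50 species, 80 trees, β_occ = 0.5.
- Delimitation recovery: three 4-specimen clusters plus one divergent
  singleton, fully concordant loci, 100 (script: 50) seeds; exact
  partition equality is required.

## Known limitations

- The concordance method itself over-splits species whose within-species
  genealogy is concordant across all loci at ≥ 3 specimens; the
  threshold-rescue step re-attaches the fragments, so partitions are
  robust but clade `origin` labels can differ.
- The swap-based randomizations are MCMC samplers: uniformity holds in
  the limit of many swaps; 10× the association count follows standard
  practice but is not a proof of mixing for every matrix shape.
- Null h² distributions are approximated with shortened chains; Z tests
  then inherit a small extra variance component, conservative in the
  cases measured.
- The Z-test p-values assume approximate normality of the permutation
  null, reasonable at the replicate counts used (the package reports
  null mean/SD so empirical-tail p-values can be recomputed if needed).
- Delimitation assumes exactly three gene trees in the standard path
  (`independent_lineages` accepts ≥ 2 with the same "present in ≥ 2,
  contradicted in none" rule).
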