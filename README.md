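# hostnet

Analysis toolkit for host-use specificity in bipartite herbivore–plant
survey data, built around the ecology of sessile, wind-dispersed
herbivores such as armored scale insects (Diaspididae). Because a
first-instar nymph that lands on a tree either develops there or dies,
the presence of later life stages (second instars, adult females) on a
tree directly evidences performance on that host — so local abundance and
patch occupancy become usable performance indices, and host-use
specificity becomes testable from survey data alone.

The package is aimed at researchers analysing trophic-link tables from
canopy surveys (insect specimens on individually tagged, taxonomically
labelled trees) together with multi-locus sequence data for the insects.

## What it computes

1. **Species delimitation by genealogical concordance.** Clades present
   in ≥ 2 of 3 single-locus gene trees and contradicted by none are
   treated as evolutionarily independent lineages; provisional species
   are the most inclusive such lineages with ≥ 3 specimens and no nested
   qualifying lineage. The minimum divergence *d*\* between provisional
   species becomes a threshold: specimens farther than *d*\* from all
   others become distinct singleton species, the rest attach by single
   linkage.
2. **Diet specificity.** Per insect species, host diversity is Simpson's
   reciprocal index 1/D = 1/Σᵢpᵢ² over colonized trees per host taxon
   (at species, genus and family level). The mean 1/D is compared with a
   permutation null that shuffles the species-by-tree association
   incidence while conserving both marginals; Z = (empirical − null
   mean)/null SD, with a two-sided normal p.
3. **Phylogenetic signal of host use.** Binary use/nonuse of each host
   taxon follows a threshold (liability) model, l = μ + u + e with
   u ~ N(0, σ²ₚV), e ~ N(0, I) and y = 1{l > 0}, where V is the Brownian
   covariance of the insect phylogeny. The signal statistic is
   h² = σ²ₚ/(σ²ₚ + 1), estimated by Gibbs sampling; empirical h² is
   Z-tested per taxon against h² refit on checkerboard-swap null
   matrices (10× the number of associations), with Benjamini–Hochberg
   FDR at q = 0.05 within each taxonomic level.
4. **Diet-breadth trade-offs.** Poisson (log link) regression of
   per-tree abundance, and binomial (logit link) regression of trees
   colonized out of trees surveyed (taxa with < 3 surveyed trees
   excluded), each on diet breadth, with significance from 1,000
   permutations of the species-level predictor.
5. **Synthetic surveys.** A generator produces all pipeline inputs with
   known ground truth — taxonomy, census, link table, insect tree, host
   use with tunable h², and three gene trees with tunable concordance —
   so every statistic above can be validated against truth.

## Worked example

```bash
python examples/03_diet_specificity.py
```

generates a survey of forced specialists and prints

```
level      empirical 1/D  null 1/D       Z       p
species            1.056     1.198 -21.379 2.11e-101
genus              1.056     1.198 -21.379 2.11e-101
family             1.000     1.192 -14.717  5.02e-49
```

Each insect species effectively uses ~1 host taxon (empirical 1/D ≈ 1)
while random association predicts ~1.2; the strongly negative Z at every
level is the signature of diet specialization. The other examples
(`examples/01`–`05`) demonstrate the generator, delimitation (recovering
the true partition and rescuing a divergent singleton at threshold
d\* ≈ 0.098), the per-taxon h² signal test, and the trade-off models
(near-zero abundance slope, positive occupancy slope when the generator
imposes one).

A thin CLI mirrors the library:

```bash
hostnet simulate --seed 3 --out-dir sim/
hostnet specificity --links sim/links.tsv --level family --n-perm 1000 --seed 1 --out table1.tsv
hostnet tradeoff --links sim/links.tsv --census sim/census.tsv --n-perm 1000 --seed 1 --out table2.tsv
hostnet run-all --links sim/links.tsv --census sim/census.tsv --tree sim/insect_tree.nwk --out-dir results/
```

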