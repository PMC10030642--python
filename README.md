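# coevo

Statistics for community experiments that manipulate the coevolutionary
history of a predator–prey species pair inside a multi-species microbial
community — e.g. a ciliate grazer and one focal bacterial prey embedded in
a synthetic 30-species bacterial community, with replicate evolved
populations of the focal prey resequenced against their ancestor and the
whole community's transcriptome sequenced under a 2 × 2 factorial design
(predation × coevolved focal prey).

The package implements the three bespoke computational stages such an
experiment needs, plus a synthetic-data module that generates inputs with
the assumed statistical structure so everything runs and is validated
without any sequencing data:

1. **Parallel evolution** (`coevo.parallelism`).  Nucleotide multiplicity
   (number of replicate populations mutated at the same site) and gene
   multiplicity

   *m<sub>i</sub> = n<sub>i</sub> · L̄ / L<sub>i</sub>*,

   the mutation count of gene *i* across replicates rescaled by the ratio
   of the mean gene length to the gene's length, so *E[m<sub>i</sub>] =
   n<sub>tot</sub>/G* for every gene under uniform, length-proportional
   mutation.  The aggregate log-likelihood excess over that null is
   *Δℓ = Σ n<sub>i</sub> log(m<sub>i</sub>/m̄) = n<sub>tot</sub> ·
   KL(p̂ ‖ p⁰) ≥ 0*.  Per-gene p-values (Poisson tail or Monte-Carlo
   placement) are thresholded by an empirical-null critical p-value chosen
   so the estimated FDR stays below 5 %.

2. **Species-resolved differential expression** (`coevo.de`,
   `coevo.normalization`).  Within-taxon sum scaling: each gene is
   normalized by its source taxon's total counts in the sample (size factor
   *s<sub>t,s</sub> = T<sub>t,s</sub> / gmean<sub>s'</sub>
   T<sub>t,s'</sub>*), and the taxon's amplicon-derived relative abundance
   enters the per-gene negative-binomial GLM as a covariate — so a shift in
   a taxon's abundance is not mistaken for coordinate expression change.
   Wald tests on a contrast (default: the predation × coevolution
   interaction), joint BH adjustment, heavy-tailed-prior fold-change
   shrinkage, a regularized log transform, and hypergeometric KEGG-pathway
   over-representation.  A gene is differentially expressed at adjusted
   p < 0.1 and |log2 fold change| > 2.

3. **DiSTATIS compromise analysis** (`coevo.distatis`, `coevo.cluster`,
   `coevo.permtests`).  Per-taxon distance matrices between samples are
   double-centred, normalized, weighted by the first eigenvector of their
   RV-coefficient congruence matrix, and summed into the compromise
   *S⁺ = Σ α<sub>k</sub> S̃<sub>k</sub>*, whose eigendecomposition yields
   consensus factor scores and per-taxon partial scores
   (Σ α<sub>k</sub> F<sub>k</sub> = F).  Downstream: bootstrap prediction
   ellipses, k-means with Krzanowski–Lai selection of the cluster count,
   and PERMANOVA / PERMDISP on the leading compromise axes.

## Worked example

```python
from coevo import (CommunitySimSpec, EffectSpec, NegativeBinomialDE,
                   simulate_community)

planted = tuple(f"taxon_1:g{i:04d}" for i in range(1, 26))
spec = CommunitySimSpec(
    n_taxa=4, genes_per_taxon=1000, seed=11,
    effects=(EffectSpec(planted, "interaction", 3.0),),
)
em = simulate_community(spec)          # 4000 genes x 12 samples
est = NegativeBinomialDE().fit(em)     # WTSS + abundance covariate
hits = est.results_.set_index("gene_id").loc[list(planted)]
others = est.results_.set_index("gene_id").drop(list(planted))
print(round(hits["lfc_mle"].median(), 2),
      round(hits["lfc_shrunk"].median(), 2),
      round(others["lfc_shrunk"].abs().median(), 2))
```

prints

```
2.87 2.6 0.14
```

— the 25 genes planted with an interaction log2 fold change of 3 are
recovered with a median estimate of 2.87 (the small downward bias is the
compositional cost of sum scaling; see `docs/methods.md`); the
heavy-tailed prior leaves those strong signals nearly unshrunk (median
2.6) while collapsing the 3975 null genes to a median |LFC| of 0.14.

The same analyses run from the shell via a YAML config:

```bash
coevo run config.yaml --seed 7 --outdir results/
```

which simulates inputs (or reads GFF3/VCF/TSV paths named in the config),
then writes `gene_multiplicity.tsv`, `de_results.tsv`,
`compromise_scores.tsv`, permutation-test tables and a provenance
manifest; reruns with the same config and seed are byte-identical.

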