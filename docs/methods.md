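# Methods

This note documents the models, parameter choices and numerical decisions
behind `coevo`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Parallel evolution statistics

**Model.** Replicate populations evolve independently from a common
ancestor; mutations are called per population against a reference genome.
Under neutrality we take mutations to land uniformly per bp, so a gene of
length L<sub>i</sub> collects counts proportional to its length.  Gene
multiplicity m<sub>i</sub> = n<sub>i</sub>·L̄/L<sub>i</sub> rescales counts
so every gene shares the null expectation m̄ = n<sub>tot</sub>/G, and the
log-likelihood excess of the observed count vector over the null factorizes
as Δℓ = Σ n<sub>i</sub> log(m<sub>i</sub>/m̄) = n<sub>tot</sub>·KL(p̂‖p⁰),
non-negative with equality exactly at length-proportional counts.

**Filters.** Variants below 20 % frequency are dropped (`min_freq = 0.2`),
as are variants present in the ancestor at ≥ 95 % frequency ("fixed";
threshold configurable — no canonical value exists, 0.95 tolerates
frequency-estimation noise at high coverage).  Filtering is an explicit
pipeline stage: the VCF reader keeps everything.

**Gene assignment.** Coordinates are 1-based inclusive throughout.  A
variant overlapping k genes increments each gene's count; total-count
bookkeeping (n<sub>tot</sub>) uses unique genic variants.  With
non-overlapping gene models (all synthetic genomes here) the two
conventions coincide and the KL identity is exact; with overlapping genes
it is approximate.  Intergenic variants are excluded from gene-level
n<sub>tot</sub> because the gene-level null places mutations over genic
space only — m̄ = n<sub>tot</sub>/G only holds then.

**Nucleotide-level null.** A site is hit by population r with probability
1 − (1 − 1/L)<sup>n_r</sup> (uniform draws with replacement; repeated hits
in one population collapse, matching the simulator).  E[N<sub>k</sub>] is L
times the Poisson-binomial tail P(≥ k populations hit), computed by dynamic
programming; the Monte-Carlo p-value for an observed N<sub>k</sub> uses the
+1-corrected tail over B ≥ 1000 simulations.

**Per-gene p-values.** Poisson survival function at the observed count
(no mid-p correction), λ<sub>i</sub> = n<sub>tot</sub>·L<sub>i</sub>/ΣL, or
a +1-corrected Monte-Carlo tail under multinomial re-placement.  The
Poisson tail treats genes independently; the exact placement null is
multinomial (fixed total), so the two agree only where per-gene rates are
small relative to the total — the sparse regime the statistic is designed
for (few mutations spread over many genes, signal concentrated in short
heavily-hit genes).  The validation toy is constructed in that regime; at
per-gene placement probabilities ≳ 0.02 combined with rates ≳ 0.5 the
second-order gap between the binomial marginal and the Poisson tail becomes
visible against a 10⁵-replicate Monte-Carlo error.

**Critical-p FDR.** Candidate thresholds are the unique observed p-values
in increasing order; FDR(t) is the mean null discovery count at t (over a
simulated ensemble of null p-vectors sharing the observed catalog and
n<sub>tot</sub>; default B = 10⁴ in the pipeline, 400 in the timed
validation battery — the estimate's noise, not its size, is what matters
and both choices give indistinguishable realized FDP) divided by the
observed discovery count; p* is the largest t with FDR(t) < 0.05.  Under a
global null the realized per-dataset discovery probability is close to the
nominal level but can exceed it slightly (measured 4–8.5 % across seed
batches of 200 datasets) because scanning data-chosen thresholds over
heterogeneous discrete nulls is mildly optimistic; this is a property of
the procedure, not the implementation.

**Power.** With 20× enrichment on 10 of 1000 genes and 300 total mutations,
each target expects at most λ = 300·20L̄/(ΣL + 190L̄) ≈ 5.0 mutations, and
with only 10 true targets the critical-p procedure cannot afford a
3-mutation threshold (estimated FDR ≈ 0.3 there), so detection requires
≥ 4 hits and mean power is bounded by P(Pois(5.04) ≥ 4) ≈ 0.74 — measured
≈ 0.64 at 90 % coding density.  Detecting rarely-hit targets at this FDR
needs either stronger enrichment or more mutations; the validation battery
reports the measured value.

## Synthetic data

`simulate_genome` places gamma-distributed gene lengths (shape 4, mean
900 bp — a realistic bacterial gene-length distribution) left-to-right with
Dirichlet-split intergenic gaps on a single contig (multi-contig structure
adds nothing to the statistics).  `simulate_mutations` draws sites by
inverse-transform sampling over per-bp weights (target genes weighted by
the enrichment factor θ; θ = 1 is the exact uniform null), collapses
repeated within-population hits, and draws allele frequencies uniform on
(0.05, 1.0) so the 20 % filter is exercised.  Mutation classes are 80 %
substitutions, 10 % deletions, 10 % insertions; no sequence is simulated.

`simulate_community` draws NB counts with expected value
libsize<sub>s</sub> · A<sub>t(g),s</sub> · q<sub>g</sub> ·
2<sup>planted effects</sup>, where q sums to one within each taxon
(log-normal baseline, sdlog 1), per-gene dispersions are gamma (shape 4,
mean 0.1 — typical RNA-seq overdispersion), library sizes are log-normal
around 2×10⁵, and the design is the experiment's 2 × 2 factorial with 3
replicates per cell and one or two sampling days.  Abundance shifts
multiply a taxon's A (and hence all its genes' expected counts) under a
treatment indicator — the confound the normalization must remove.  Amplicon
relative abundances are Dirichlet draws around A with concentration 10⁵
(small measurement error; lower it to study covariate robustness).  All
draws flow from one `default_rng(seed)` per call, so outputs are
bit-reproducible.

What this does **not** emulate: compositional count noise across taxa
(taxon shares are fixed per sample, not multinomial), rRNA contamination,
mapping ambiguity between related genomes, batch effects, or gene-length
bias.  Passing tests demonstrate the statistics behave as designed under
their own assumptions, not that those assumptions hold in any particular
real data set.

## Differential expression

**Size factors.**  Within-taxon sum scaling:
s<sub>t,s</sub> = T<sub>t,s</sub>/gmean(T<sub>t,·</sub>).  Taxon-samples
with zero totals get NaN factors and are excluded from that taxon's tests;
an all-zero taxon is an error.  Sum scaling assumes the bulk of a taxon's
transcriptome is not differentially expressed: if planted/true DE genes
carry a fraction f of the taxon's reads at fold change 2<sup>β</sup>, all
of the taxon's estimates are biased by −log2(1 + (2<sup>β</sup> − 1)f).
The validation keeps f ≈ 2.5 % (bias ≈ 0.24 at β = 3), the regime of a few
hundred DE genes in transcriptomes of thousands.

**Dispersions.**  Method of moments φ̂ = max(0, (s² − μ)/μ²) on normalized
counts, computed within design cells and pooled by residual df so treatment
effects are not mistaken for dispersion; a/μ + b trend by Huber regression;
empirical-Bayes shrinkage of log φ̂ toward the trend with weight
(2/df)/((2/df) + σ²<sub>prior</sub>), σ²<sub>prior</sub> estimated from the
residual spread and floored at 0.01.  Zero-φ̂ genes take the trend value.
At least 3 pooled residual df are required (error instructs pooling).

**GLM and tests.**  Per-gene NB GLM (log link, offsets log s) by IRLS with
fixed φ<sub>g</sub>; Wald statistic on the contrast coefficient against a
t distribution with the residual df — the standard small-sample correction;
with three replicates per cell the plug-in SE makes a standard-normal
reference visibly anticonservative (null tail probability ≈ 0.08 at the 5 %
level), while the t reference restores uniformity (KS ≈ 0.02–0.03 over
2000 null genes).  The abundance covariate is log2(relabund + 10⁻⁶); the
pseudocount guards taxa dropping to zero amplicon share and is irrelevant
at the simulated abundances.  BH is applied jointly across all taxa within
one contrast (per-taxon mode by flag); non-converging or separated fits are
flagged untestable and excluded from the BH family.  Day 4 and day 45 are
separate model fits.

**LFC shrinkage.**  Cauchy (Student-t, df 1) prior centred at zero; scale
estimated as √mean(max(LFC² − SE², 0)) over tested genes, floored at 0.05
(the floor only binds when everything is null, and is logged).  The
shrunken LFC is the posterior mode, located by a 513-point bracket plus
bounded refinement to 10⁻¹⁰ (the posterior can be bimodal; the bracket
scan picks the global mode).  Heavy tails leave |LFC| ≫ SE essentially
unshrunk and collapse noise toward zero.

**rlog.**  y = log2((K + 0.5)/s); per-gene deviations from the intercept
(row mean) are damped by w = 1/(1 + φ·c).  The shrink strength c defaults
to 5.0, giving w ≈ 0.95 at φ = 0.01 (precisely measured genes keep their
signal, so rlog ≈ log2 normalized counts for high-count genes) and
w ≈ 0.17 at φ = 1 (noisy low-count genes collapse toward their intercept).
Tying c to library depth would shrink even precise genes to their means,
defeating the transform's purpose, so c is a dimensionless constant.
Variance never increases (w ≤ 1), and the transform is monotone within a
gene/sample.

**Selection and enrichment.**  Taxa are retained when their share of total
counts strictly exceeds 0.5 % in *every* sample (the conservative reading;
a flag relaxes to the mean).  The 500 most variable genes per taxon are
taken by across-sample rlog variance, ties broken lexicographically.
Pathway over-representation is the exact hypergeometric tail P(X ≥ x) with
BH across pathways at adjusted p < 0.05.

## DiSTATIS

Cross-products S = −½CD⁽²⁾C′ with uniform masses, normalized by the first
eigenvalue; congruence by the RV coefficient; table weights α from the
first eigenvector of the congruence matrix, sign-fixed non-negative and
rescaled to sum 1; compromise S⁺ = Σα<sub>k</sub>S̃<sub>k</sub>;
eigenvectors sign-fixed by making each axis's largest-magnitude loading
positive (reproducible plots and tests); eigenvalues below 10⁻⁹ of the
largest are dropped, and a negative eigenvalue beyond −10⁻⁹ is an error
(inputs not PSD — cannot happen for genuine distance matrices).  Partial
scores F<sub>k</sub> = S̃<sub>k</sub>VΛ<sup>−1/2</sup> satisfy
Σα<sub>k</sub>F<sub>k</sub> = F identically; with K identical tables the
whole construction reduces to classical MDS of the shared table, which the
tests verify against scikit-bio's PCoA.

**Bootstrap.**  The resampling unit is the table (a species' transcriptome):
K tables are resampled with replacement, weights and compromise recomputed,
and the bootstrap compromise projected on the reference axes; ellipses are
95 % normal contours of each sample's bootstrap cloud in the first two
dimensions (B = 1000 by default; < 100 warns).  Resampling samples instead
would break the distance geometry; resampling tables measures how sensitive
the consensus is to the species composition of the analysis.

**Clustering and permutation tests.**  k-means (25 seeded restarts per k,
candidate k from 2 to min(8, n−2)); Krzanowski–Lai index
KL(k) = |DIFF(k)/DIFF(k+1)| with DIFF(k) = (k−1)<sup>2/p</sup>W<sub>k−1</sub>
− k<sup>2/p</sup>W<sub>k</sub>; chosen k maximizes KL (smaller k wins
ties; a zero denominator with nonzero numerator counts as +∞).  PERMANOVA
runs on the leading compromise axes that cumulatively explain 99 % of
variance, with the Gower-decomposition pseudo-F, free label permutations
(999 default, +1-corrected p) or exhaustive enumeration of distinct label
assignments when requested (p is then exact, observed assignment included).
PERMDISP follows Anderson: distances to group centroids in the PCoA
embedding (negative-eigenvalue axes subtract), ANOVA F on those distances,
permutation of the residuals.

## Pipeline

One global seed; each stage derives its seed from a SHA-256 hash of
`"{seed}:{stage}"`, so stages are independently reproducible and reruns are
byte-identical (TSV floats are written with a fixed format; the manifest
hashes the scientific config, excluding the output directory).  Stage order:
simulate → parallelism → differential expression (per day) → DiSTATIS with
clustering and permutation tests.  Default thresholds: min frequency 0.2,
parallelism FDR 0.05, DE adjusted p 0.1 and |LFC| 2, enrichment adjusted
p 0.05, top-500 variable genes, 0.5 % taxon inclusion, 99 % variance cutoff.

## Validation battery sizes

The experiments in `coevo.validation` (run by `scripts/acceptance.py` and
the acceptance tests) use: 200 null datasets of 1000 genes × 150 mutations
for FDR calibration; 50 seeds × 300 mutations for power; 10⁵-replicate
Monte-Carlo for the p-value and E[N₂] agreements; 20 seeds of a 200-gene,
two-taxon community for the confound experiment; 2000 null genes for Wald
calibration and 8000 genes with 200 planted for LFC recovery; 100 seeds for
the cluster-count selection rate; and a 3-taxon end-to-end pipeline run
twice for determinism.  These sizes keep each experiment's Monte-Carlo
error well below the property being asserted while the whole battery
completes in a few minutes on one CPU.

## Known limitations

- Sum scaling's compositional bias (above) is inherent; a median-of-ratios
  variant would be robust to it but is not what the normalization specifies.
- The dispersion estimator is moments-based with trend shrinkage, not a
  full Cox–Reid adjusted-profile-likelihood scheme; the LFC shrinkage uses
  a fixed-df heavy-tailed prior, not an adaptive one; the rlog is a
  weighted shrink, not a full ridge fit.  Contracts and calibration tests
  pin the required behavior; bit-compatibility with any external
  implementation is a non-goal.
- The critical-p FDR procedure is mildly optimistic under global nulls
  (see above), and its power at weak enrichment is bounded by the discrete
  count threshold the FDR forces.
- Calibration is prioritized over flag counts: with three replicates per
  cell the t-referenced Wald p-values cannot reach the extremes a normal
  reference produces, so the joint-BH + |LFC| > 2 gate flags only very
  strong or very numerous effects at this design size.  Effect estimates
  (LFC and shrunken LFC) carry the recovery information either way.
- PERMANOVA assumes exchangeable samples under the null; with the factorial
  design the pipeline permutes freely within a day's samples.
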