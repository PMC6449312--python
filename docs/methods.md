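# Methods

## The analysis problem

A germplasm collection of a selfing crop and its wild progenitor is
genotyped on a dense SNP array.  Before population-genetic inference the
collection must be curated — duplicated or near-isogenic accessions
removed, natural wild × crop hybrids removed — and afterwards the
curated panel is used to (i) describe population structure and
diversity, (ii) map binary traits by conditional case–control GWAS, and
(iii) infer the crop's domestication origin from differentiation
statistics and phylogenetic trees, including trees rebuilt from the
subset of SNPs most strongly associated with domestication.  `soypop`
implements each of these stages as library functions plus a CLI, and
ships a generative simulator so that every stage can be scored against
planted ground truth at desk scale.

## The synthetic collection generator

### Model

Genotypes follow a hierarchical Balding–Nichols (BN) model.  Per locus
an ancestral allele frequency is drawn p ~ Uniform(0.05, 0.95).  Each
wild subpopulation i draws its frequency from
Beta(p(1−F_i)/F_i, (1−p)(1−F_i)/F_i), the BN distribution with drift
parameter F_i (unitless, 0–1; the expected Weir–Cockerham coancestry of
the subpopulation relative to the ancestor).  The domesticated
population re-drifts from the frequencies of one designated wild
*source* subpopulation with an additional bottleneck parameter, and a
fraction of its loci (selective sweeps) is then forced to a frequency
within `sweep_residual_maf` of fixation.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `wild_divergence_F` | (0.05, 0.10, 0.15, 0.20) | under BN, pairwise wild–wild FST ≈ (F_i+F_j)/2, giving the 0.05–0.21 range observed between wild subpopulations of the soybean progenitor |
| `source_subpop` | 3 (the F = 0.20 subpopulation) | the crop derives from the most diverged wild group (the Japanese-type subpopulation in soybean) |
| `dom_bottleneck_F` | 0.35 | places FST(domesticated, source) ≈ 0.2 and FST(domesticated, other wilds) ≈ 0.27–0.35, the published ordering and magnitudes |
| `sweep_fraction` | 0.07 | ~7% of a crop genome is domestication-related |
| `sweep_residual_maf` | 0.02 | swept loci are near-fixed in the crop; residual minor-allele frequency below the array-QC MAF floor |
| `inbreeding` | 0.99 | a selfing species genotyped after single-seed descent is near-homozygous; each locus is homozygous (one allele drawn, doubled) with this probability, else a Hardy–Weinberg draw.  Without this the het-rate QC filter (≤ 0.02) would be meaningless |
| `duplicate_discordance` | 0.01 | duplicate array replicates disagree at ≲ 1.2% of co-called calls; the dedup cutoff (1.25%) was chosen just above that range |
| hybrid fraction window | Uniform(0.30, 0.70) | the ancestry range observed for field-collected natural hybrids; hybrids mix alleles rather than selfing, so they are heterozygous at differentiated loci |

Two generator choices deserve explanation:

* **Sweep direction.**  The allele driven to fixation in the crop is
  the one *minor in the source wild subpopulation*.  Domestication
  alleles are standing rare variants in the progenitor; fixing the
  wild-major allele would plant a "sweep" with no wild/crop frequency
  differential and hence no recoverable signal.
* **Duplicate planting.**  A duplicate copies an existing accession and
  flips exactly `round(rate × n_snps)` randomly chosen calls (each flip
  to one of the two other dosages).  With Bernoulli per-call flips at
  rate 0.01, sampling noise would push ~13% of planted pairs past the
  1.25% cutoff, so "planted at 1% discordance" would not describe the
  data; the exact-count scheme matches how the cutoff is used (set
  above the observed duplicate discordance range).

Binary phenotypes (flower colour: 1 causal locus; seed-coat colour: 3
causal loci) are assigned deterministically from causal genotypes with
dominant encoding in domesticates; wild accessions are fixed at the
ancestral state (pigmented).  Causal loci are taken from non-sweep loci
segregating in the crop; the multigenic trait draws from a lower
frequency window (0.15–0.40) so that the all-recessive "absent" class
keeps appreciable frequency under dominance.  A misclassification rate
is exposed but defaults to 0.

### What the generator does and does not emulate

It reproduces the *frequency structure* the downstream statistics
consume: graded wild differentiation, a bottlenecked monophyletic crop
nested inside one wild group, sweeps, hybrids, duplicates, missingness,
inbreeding.  It deliberately omits linkage (loci are exchangeable; an
explicit block-copy mode, `simulate_ld_region`, exists only to exercise
LD-block calling), ascertainment bias of a real array, genotyping-error
structure beyond duplicate discordance, and any spatial/temporal
sampling model.  Passing recovery tests therefore demonstrates the
statistical machinery is correct under its stated assumptions — not
that real-array artefacts (LD, ascertainment) are handled.

## QC and curation

* Sample filter: keep call rate strictly > 0.97 (applied before any
  SNP-level work, matching the published order).
* Imputation: per-SNP modal dosage; frequency-weighted seeded draw on
  ties.  This is a deliberate stand-in for haplotype-based imputation:
  no downstream statistic here uses phase, so LD-aware imputation buys
  nothing at this scale.
* SNP filter: discard if het rate > 0.02 **or** MAF < 0.02, both
  strict, so boundary values are retained; the two conditions are
  independent disqualifiers.  The filter runs after curation, on the
  non-redundant panel.
* Dedup: pairwise inconsistency = discordant / co-called calls (any
  dosage difference counts once; computed on *unimputed* calls, since
  the published definition excludes missing genotypes).  Pairs at
  inconsistency < 0.0125 with ≥ 100 co-called sites are linked;
  single-linkage components of size ≥ 2 are redundancy groups —
  transitive chaining is the only parameter-free completion of a
  pairwise rule.  One representative is retained per group: annotated
  recurrent parent → highest call rate among those ≥ 0.99 → highest
  call rate → smallest id.
* Hybrids: a sample is a hybrid iff its domesticated-cluster ancestry
  fraction lies in the closed window [0.30, 0.70].  The pipeline
  estimates that fraction at K = 5 (the number of populations in the
  simulated world, configurable): at K = 2 the maximum-likelihood
  admixture solution genuinely assigns intermediate fractions
  (~0.3–0.45) to *pure* source-subpopulation wild accessions, because
  the crop's frequencies are a drifted copy of theirs — the same
  phenomenon seen in real data as crop-cluster fractions appearing
  inside the source wild group.  At the population-level K those
  samples resolve into their own cluster and only true hybrids remain
  in the window.  Hybrid removal precedes dedup so a duplicated hybrid
  cannot survive as a representative.

## Structure

PCA uses Patterson normalisation — centre each SNP by its mean dosage
and scale by sqrt(p̂(1−p̂)) with p̂ = (1+Σg)/(2+2n) — monomorphic
columns dropped, exact eigendecomposition (deterministic), component
signs fixed by making each component's largest-magnitude entry
positive.

The admixture model treats genotype g_ij as Binomial(2, Σ_k q_ik f_kj).
It is fitted by EM on the allele-origin latent variable: both the Q and
F updates are exact M-steps, so the log-likelihood is monotone
non-decreasing — a property the test suite asserts on every fit.
Defaults: tol 1e-6 log-likelihood units, max 2000 iterations, 5 seeded
random restarts (best kept), F clamped to [1e-6, 1−1e-6].  K = 1 uses
the closed form.  The binomial assumption is mildly misspecified for
inbred genotypes (alleles within an individual are correlated); this
halves the effective information but leaves ancestry fractions
consistent, and the recovery tests quantify the residual error under
the default inbreeding level.

K is chosen by masked-entry cross-validation: per fold, 10% of observed
entries are masked, the model refitted, masked dosages predicted as
2·Σ q f, error = mean squared deviation; 5 folds, argmin over K, ties
to the smallest K.  Masking entries (not samples) keeps every sample's
ancestry estimable in every fold.

Representative-set extraction is greedy maximin (farthest-point) in the
first 3 PCs within each label, seeded at the sample nearest the group
centroid, deterministic given input order.  This is an explicit,
reproducible stand-in for the visual "one per minicluster" selection
done by eye in practice.

## Diversity, differentiation, AMOVA

Per-site diversity uses the unbiased pairwise estimator
π = 2j(n−j)/(n(n−1)) on called haplotype counts (n = 2 × called
diploids); sites with fewer than two called haplotypes are excluded and
counted.  The Weir–Cockerham variance components a, b, c (including the
heterozygosity term c = h̄/2) are computed per site for any number of
populations; the genome-wide estimate is the ratio of sums Σa/Σ(a+b+c),
the "weighted" estimator that the standard tools report.  Negative
per-site components are kept as computed.

AMOVA is the two-level nested decomposition on allele-difference
distances (per pair: Σ|g_i − g_j| over co-called sites, normalised by
co-called count and rescaled to the full site count).  Components come
from the standard mean-square equations; for F-statistics, negative
components are floored at zero while raw values stay in the output.
Permutation schemes: F_CT permutes whole populations among groups, F_SC
permutes samples among populations within groups, F_ST permutes samples
freely; p = (hits+1)/(n_perm+1) with n_perm = 1023 by default.  Note
that with few populations the F_CT permutation space is tiny (with 4
populations in 2 groups only 3 distinct assignments exist), so its
p-value floors near 1/3 regardless of signal — an inherent property of
the design, not of the implementation.

## Conditional GWAS

Every scan is a Firth-penalised logistic regression of the binary
phenotype on the SNP's additive dosage plus conditioning-SNP dosages.
Firth's Jeffreys-prior penalty ½·log det(XᵀWX) keeps estimates finite
under complete separation, which is the *normal* situation for the
domestication phenotype.  P-values are penalised likelihood-ratio
tests in which the null fit pins the tested coefficient at zero while
keeping the full design's penalty (the profile-likelihood convention);
comparing penalised likelihoods across designs of different dimension
would inflate the statistic and is avoided.  Newton iterations use
step-halving to guarantee ascent; non-converged SNPs are flagged and
excluded from significance lists.

Conditioning SNPs are chosen per PCA/ancestry group as the
`n_per_group` (default 10) SNPs maximising |freq in group − freq
elsewhere| (ties: larger minor-allele count, then smaller id), plus one
*perfect* SNP whose alleles exactly separate crop from wild if one
exists.  The perfect SNP is dropped from the covariates when the
scanned trait is domestication itself.  Conditioning covariates scale
with panel size: the desk-scale demo uses 2 per group (10 covariates
for ~150 samples, proportional to ~20 covariates per ~3000 samples);
with 50 covariates on 150 samples the covariates absorb the entire
phenotype axis and the scan has no power left.

Significance is Bonferroni at α = 0.01 over the number of scanned SNPs;
for 117,095 tests this gives 8.54e−8, −log10 = 7.0686 (displayed to two
decimals as 7.07; both 7.06 and 7.07 appear in print depending on
rounding convention).

One calibration caveat is documented rather than hidden: with a
balanced binary phenotype and integer dosages the score statistic lies
on a lattice, so ~4–5% of null p-values are exactly 1 (zero score).
Tail quantiles and one-sided (anticonservative-direction) checks are
the meaningful calibration criteria; a two-sided KS test against
U(0,1) at large SNP counts rejects on that atom alone, for any test
statistic.

LD: haplotype frequencies for a SNP pair are estimated from unphased
genotypes by the standard two-locus EM (only double heterozygotes are
phase-ambiguous); r² = D²/(p_A p_a p_B p_b), D′ = D/D_max.  The |D′|
confidence interval is a profile likelihood on a 101-point grid over
[0, 1] with allele frequencies fixed at their MLEs; the 90% interval is
read from the normalised likelihood's CDF.  Gabriel blocks: a pair is
"strong LD" if CI ∈ [≥ 0.70, ≥ 0.98], "strong recombination" if the
upper bound < 0.90; a block is a run whose outer pair is strong LD and
in which ≥ 95% of informative pairs are strong LD; overlapping
candidates resolve longest-first (bp span, then SNP count).

The domestication-SNP partition splits SNPs at −log10 p strictly
greater than the cut (default 17; non-converged SNPs go to the neutral
side) and conserves the SNP count exactly.

## Phylogenetics

Genotype p-distance: d_ij = Σ|g_i − g_j| / (2 × co-called sites), so a
heterozygote counts half a difference against a homozygote; range 0–1.
Identity and symmetry always hold; the triangle inequality can fail
under missingness (different site sets per pair) and is not asserted.
Neighbor joining is the Saitou–Nei algorithm with the Q criterion, ties
broken toward the smallest index pair, branch lengths by the two-point
formulas and *not* truncated (negative lengths retained); the final
three lineages join at an unrooted trifurcation.  NJ is exact on
additive distances, which the tests verify against randomly generated
trees.  Bootstrap resamples SNP columns; supports are the percentage of
replicates containing each internal bipartition, written as integer
internal-node labels in Newick.  Sister groups are read from the
midpoint-rooted tree — a documented convention, since NJ trees are
unrooted.

For partition-tree comparison the package reports each focal clade's
mean terminal branch length and stem (basal branch) length in the
all-SNP, neutral-SNP and domestication-SNP trees plus pairwise
Robinson–Foulds distances.  Under this generator's sweep model the
domestication signature is carried by the **stem**: at swept loci the
crop is internally near-invariant but far from every wild group, so the
crop clade's basal branch elongates sharply in the domestication-SNP
tree while its terminal branches shorten.  (In real array data terminal
branches can also elongate because "associated" SNPs are ascertained,
partially swept and in LD with residual variation — features this
generator intentionally lacks.)

## Pipeline

Fixed stage order: sample QC → imputation → hybrid removal → dedup →
SNP filter → PCA/admixture → π/FST/AMOVA → GWAS (flower, seed-coat,
domestication) → partition → trees.  One master seed; per-stage seeds
derived by SHA-256 of `"{seed}:{stage}"`, so any stage can be re-run
in isolation.  The manifest records config, seeds, input hashes and
per-stage sample/SNP counts (monotone non-increasing through the
filters); the removal log carries one reason code per removed
accession.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
so each recovery question is answerable with comfortable margins:
collections of 60–170 accessions × 800–3000 SNPs, two-pool ancestry
panels of 110 × 3000, FST panels of 100 × 5000 with a 20-replicate
oracle, GWAS null panels of 200 × 5000 (20 replicates for family-wise
error), 40-leaf trees with 200 bootstrap replicates, and 1023/199
permutations for AMOVA.  All of these are configuration values, not
limits of the implementation.

## Known limitations

* No linkage map; LD exists only in the explicit block-copy fixture.
* Mode imputation ignores LD by design; it is adequate only because
  downstream statistics are phase-free.
* The admixture EM assumes Hardy–Weinberg within clusters; inbred data
  are handled consistently but with reduced efficiency, and no explicit
  inbreeding coefficient is estimated.
* The binomial admixture model, not the original block-relaxation
  optimiser, is used; results agree in the regimes tested but
  convergence speed differs.
* AMOVA distance is the allele-difference metric; other metrics (e.g.
  squared Euclidean on dosages) are not exposed.
* Candidate-gene interpretation of association peaks is out of scope;
  outputs stop at Manhattan-ready tables, blocks and trees.
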