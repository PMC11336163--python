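# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `radstruct`, in the order the pipeline applies them.

## Data model

Genotypes are alternate-allele dosages in {0, 1, 2} with a distinct missing
sentinel (−1), stored samples × loci with 1-based inclusive coordinates
(BED input is converted at the reader boundary). Missingness is never
conflated with the reference genotype: statistics use sitewise or pairwise
complete observations, except where an operation explicitly states mean
imputation (PCA, DAPC, outlier scan). Multiallelic and indel VCF records are
skipped, not split; phase is ignored.

## Synthetic-data generator

`simulate_dataset` emulates the statistical structure of a two-species
ddRAD study so that every analysis stage has planted ground truth:

* **Island model.** Per-locus ancestral frequencies ~ Uniform(0.05, 0.95);
  deme frequencies follow the Balding–Nichols model
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target F<sub>ST</sub> (default
  0.01, within the 0.005–0.015 band typical of weakly structured marine
  fish). The Balding–Nichols parameter maps directly onto the expected
  Weir–Cockerham θ among demes.
* **Outlier loci.** A configurable fraction of loci (default 0 in the bare
  config; 5–10% in the analysis fixtures) draws deme frequencies at an
  inflated F (default 10×). Note the draws are heterogeneous: a sizeable
  share of loci planted at the 10× level realize little divergence by
  chance, so unconditional detection power is bounded well below 1 for any
  method; tests therefore condition power on realized per-locus θ.
* **Species divergence.** A diagnostic fraction of loci (default 0.5) is
  near-fixed for opposite alleles (gap 0.96); remaining loci share
  frequencies between species. Two diagnostic mtDNA sites (one base fixed
  per species) are carried as sample-table columns and inherited maternally,
  so hybrid classes and discordant conspecifics show mito-nuclear
  discordance by construction.
* **Hybrids.** Simulated at the haplotype level with free recombination:
  F1 = one haplotype from each species; BC<sub>g</sub> = a gamete from the
  previous-generation hybrid (per-locus choice between its two haplotypes)
  × a gamete from the recurrent parent. Expected minor-parent ancestry is
  0.5^(g+1).
* **Inversions.** Each region assigns every conspecific sample a karyotype
  drawn from Hardy–Weinberg at the inversion-allele frequency. A fraction of
  region loci (default 0.8) is "divergent": each arrangement is internally
  near-monomorphic (rare-allele frequency 0.05) for opposite alleles, so AB
  individuals are heterozygous at divergent sites and homozygotes are not.
  The remaining region loci carry ordinary deme frequencies, keeping
  detection non-trivial.
* **Sex system.** XY-like: a fraction (default 0.8) of region loci is
  male-limited — present (alt-carrying) in males with probability 0.98 and
  absent (missing) in females. This mimics read-presence sex scans at the
  genotype level, since raw reads are out of scope.
* **Related pairs.** Duplicates copy a genome; parent–offspring children
  receive one allele from the parent and one from the deme frequency.
* Missingness is uniform at a configurable rate; per-locus median depth is
  lognormal (e^3.4 ≈ 30×, σ_log 0.35). All randomness flows from one seed.

What the generator does *not* emulate: linkage between neutral loci,
realistic allele-frequency spectra, genotyping-error models, batch effects,
or sequence-level artifacts (restriction-site dropout, PCR duplicates).
Passing tests therefore demonstrate correctness of the estimators and the
pipeline logic under the assumed generative models, not robustness to every
artifact of real ddRAD data.

## QC and kinship

SNP filters: MAF (strictly greater than the threshold), missing rate
(strictly less), heterozygosity ceiling (≤ 0.6; observed by default, with
expected heterozygosity available — both conventions exist in the field and
differ for loci out of Hardy–Weinberg), and a closed median-depth interval
(default 10–95×, upper bound configurable to 105×). Sample filter: missing
rate ≤ 0.30. Kinship uses the KING-robust within-pair estimator; pruning is
greedy from the highest Φ, removing the higher-missingness member (ties:
lexicographic id), which guarantees no surviving pair above threshold. The
default cutoff is the standard second-degree boundary 0.177, with the
commonly used 0.3 available.

KING caveats, both visible in the examples: (i) two F1 hybrids are both
heterozygous at every diagnostic locus, pushing their pairwise Φ toward the
duplicate value 0.5 — the estimator assumes a homogeneous population;
(ii) on small locus panels where an inversion contributes a large share of
loci, same-karyotype pairs show inflated Φ. Both effects shrink as the
panel grows; at genome scale the 0.177 default behaves as intended.

## Structure

PCA centers dosages per locus and imputes missing values to the locus mean
(equivalently zero after centering), then uses SVD; eigenvalues are squared
singular values / (n−1), and axis signs are canonicalized so each axis'
largest-magnitude loading is positive. Dosages are not variance-scaled by
default (scaling changes which loci dominate loadings; the unscaled
convention keeps loading profiles interpretable as dosage covariance).

The admixture EM performs exact block E/M updates of Q and F on
missing-excluded entries; the log-likelihood is monotone (asserted per
iteration in tests). Initialization: Q ~ Dirichlet(1), F = global
frequencies + N(0, 0.1) jitter, clipped; 5 restarts, tolerance 1e-6
relative log-likelihood. K = 1 is closed-form. Cross-validation masks 1/5
of non-missing entries per fold and scores squared error of the dosage
against 2·Σ_k q_ik f_kl.

**Cluster number.** `find_clusters` runs k-means on retained PC scores and
scores each k by BIC. The k-means WSS criterion n·ln(WSS/n)+k·ln(n) is
exposed (`selection="wss"`) but is not the default decision rule: splitting
even a homogeneous Gaussian reduces WSS by Θ(n) while the penalty grows as
ln n, so its argmin drifts upward on unstructured data and it is only
useful as an elbow curve. The default scores k with a diagonal-covariance
Gaussian-mixture BIC, which is consistent for well-separated groups and
picks k = 1 on a single blob.

DAPC retains the fewest PC axes reaching the requested variance fraction
(default 80%; the retained count is reported rather than fixed), solves the
generalized eigenproblem S_b w = λ S_w w on PC scores (ridge-regularized
when S_w is singular), and back-rotates discriminant directions to locus
space for genome-ordered loading profiles.

## LD

r² is the squared Pearson correlation of dosages over jointly non-missing
samples (composite genotypic LD), undefined below 20 joint observations or
when either locus is monomorphic in the joint subset — undefined values are
flagged, never zero-filled, and never trigger pruning. The site profile
averages r² over same-chromosome partners at 100 kbp–5 Mbp (inclusive).
Pruning is a greedy keep-first scan in genome order: drop a locus whose r²
with a retained locus within 10 Mbp on the same chromosome exceeds 0.05, or
with a retained locus on another chromosome exceeds 0.10; the retained set
is stable under re-scan (idempotence is tested).

## Inversions

Detection aggregates a per-site statistic (squared loadings of a PC axis,
or the LD profile) into fixed 1-Mbp windows per chromosome and flags
windows above median + 4 × (1.4826·MAD); flagged windows within 2 Mbp merge,
and region bounds snap to the outermost contributing sites. An explicit
rule replaces visual inspection of loading profiles so detection is
reproducible; manually supplied regions are also accepted. Chromosomes with
fewer than 10 windows are skipped.

Karyotyping restricts PCA to region SNPs, clusters PC1 with 3-means
(multi-restart, seeded), orders clusters along PC1 as AA/AB/BB, and labels
the larger homozygote cluster AA (arrangement polarity cannot be determined
from genotypes). Samples beyond 3 cluster-SDs of every center are
unassigned. A call is **confirmed** only if the middle cluster is the
strict observed-heterozygosity maximum *and* the cluster means explain
≥ 95% of PC1 variance. The separation requirement exists because the
heterozygosity condition alone is satisfied by unstructured data: samples
with more heterozygous calls lie nearer the centroid on any PC, so the
middle third of a unimodal PC1 is always slightly het-enriched. The
inversion-allele frequency is (2n_BB + n_AB)/(2n_assigned).

## Sex association

Each marker gets a 2×2 table of sex × property (default property: genotype
presence, i.e. non-missing; alt-carrier mode available) tested by
chi-square with continuity correction, replaced by Fisher's exact test when
any expected *or observed* cell is below 5 (fully sex-limited markers have
zero cells with large expectations — the exact tail is the correct
p-value there). Balanced tables short-circuit to p = 1. The Bonferroni
threshold uses the number of markers actually tested; markers failing the
per-sex minimum (default 5) are reported untested, not p = 1. Bias =
carrier fraction in males − females; a male-biased significant segment is
reported as XY-like (males heterogametic) rather than assumed.

## Differentiation and outliers

The outlier scan standardizes dosages by sqrt(p̂(1−p̂)), regresses each
locus on the first K orthonormal PC score vectors, and scales coefficients
by the residual SE into per-locus z-vectors. D² uses a coordinatewise
median location and MAD-based diagonal scatter (the z-scores are
near-uncorrelated by construction; a full robust-covariance option exists).
λ = median(D²)/median(χ²_K) corrects systematic inflation before the
χ²_K upper-tail p-value. q-values are Benjamini–Hochberg — conservative
relative to Storey-type estimators, which matters little at the observed
effect sizes. Flags: q < 0.05 (FDR set) and p < 0.05/L (Bonferroni set).

Weir–Cockerham θ uses the 1984 variance components a, b, c for biallelic
loci with unequal sample sizes, requiring ≥ 2 genotyped samples per group
per locus; the multi-locus ratio-of-sums is bootstrapped over loci (1000
replicates by default) for a one-sided departure-from-zero p and percentile
CI. Individual inbreeding F = (O_hom − E_hom)/(L − E_hom) with the
small-sample correction 2n/(2n−1) in E_hom. Group comparisons use
Kruskal–Wallis with tie correction and Dunn's post-hoc z-tests
(Bonferroni-adjusted by default).

## Species classifier

mtDNA species comes from two diagnostic sites (one base fixed per species;
both present → unclassified with a warning). Nuclear class from K = 2
ancestry: admixed when minor ancestry ≥ 0.05 — the threshold sits between
the noise level of pure individuals (< 0.02) and the lowest hybrid class of
interest (F1 backcrosses, ≥ 0.0156 only after five generations) — else the
majority cluster. Decision table: nuclear A → pure_A; admixed → admixed;
nuclear B with mtDNA A → B_with_A_mtDNA; nuclear B otherwise → pure_B.
Reported percentages round half-up to one decimal.

## Pipeline

Stage order: QC → species screen (removing the other species and admixed
individuals; mito-nuclear discordant conspecifics are retained by default)
→ MAF refilter at 0.05 → inversion detection/karyotyping → sex scan →
removal of confirmed inversion and significant sex regions → structure →
outlier partition (FDR set by default; Bonferroni via config) → LD prune →
final structure. The sex scan runs on the pre-QC matrix restricted to
current samples, because presence/absence markers are near-monomorphic and
half-missing by nature and cannot survive MAF/missingness filters — the
read-presence scan this stage stands in for operates upstream of SNP
filtering. Every removal appends one ledger row; the manifest serializes
config, seed, versions and ledger with a checksum, and reruns with the same
seed and config are identical.

## Problem sizes

Tests and the acceptance script run simulations at 450–5000 loci and
60–450 samples — sizes at which every targeted effect (F<sub>ST</sub> 0.01
recovery to ±0.004, karyotype recovery ≥ 99%, kinship ±0.02, ancestry
±0.03) is measurable with comfortable Monte-Carlo margins while the whole
suite stays fast on a single core.

## Known limitations

* Inversion calls are "putative": recombination-suppressed haplotype blocks
  of other origins produce the same signature; breakpoints are resolved
  only to the outermost contributing SNPs.
* The admixture EM lacks the quasi-Newton acceleration of dedicated tools;
  at desk scale this costs seconds, not correctness.
* KING Φ is biased for hybrid pairs and, on small panels, for pairs sharing
  an inversion karyotype (see QC section).
* The sex scan's genotype-presence substrate is an analog of read-presence
  scans, not a replacement: depth-based evidence is out of scope.
* Bootstrap p-values for θ are resolution-limited at 1/n_boot.
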