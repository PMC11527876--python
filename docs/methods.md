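# Methods

This note documents the models, default parameters and design choices
behind `neosexscan`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Scaffold sex-linkage classification

Pooled male and female reads mapped to a female (ZW) assembly give each
scaffold three statistics: the male:female ratio of mean mapped depth, the
male:female ratio of horizontal coverage, and the proportion of the female
pool's single-copy kmers unmatched in the male pool. Ploidy fixes the depth
expectations — autosomes 1:1, Z 2:1 (males ZZ, females hemizygous Z), W ~0:1
plus a mismapping floor — and female-specificity drives the W kmer signal.

* Ratios use a pseudocount of 0.5 in numerator and denominator so W
  scaffolds with zero male depth stay finite. Ratios enter the PCA raw
  (not log-transformed) but z-standardized column-wise, which makes the
  classification invariant to affine rescaling of any single metric.
* Classification runs 1-D k-means (k = 3, 50 restarts, fixed seed) on PC1
  scores. Cluster→class anchoring is by rank of the median raw depth ratio
  (highest → Z, lowest → W), which preserves the affine invariance.
* Because k = 3 is imposed, a cohort genuinely lacking a class would have
  one of its real classes split in two. The pipeline therefore validates
  calls on the physical ratio scale: a called Z class with median raw depth
  ratio below 1.5, or a called W class above 0.5 (the midpoints between the
  ploidy expectations 0, 1 and 2), is treated as absent, its members
  relabelled autosomal with a warning. This separates the scale-free
  statistical step from the biologically anchored sanity check.
* Validation uses leave-one-out cross-validated LDA of the three metrics
  against the PCA-derived calls; LOOCV is deterministic, unlike k-fold.
  Classes with a single member cannot be held out and are excluded with a
  warning.
* Reference top hits come from PAF records filtered at mapQ ≥ 40 and ranked
  by descending mapQ, then descending block length, then ascending target
  name (a deterministic tiebreak). A sex-linked scaffold whose top target
  is an autosome is flagged neo-sex. Reference chromosome classes can be
  supplied as a two-column table; otherwise Z/W/mito are recognized by
  name, since assembly naming dialects vary.

## Gametolog bookkeeping

Genes inherit their parent scaffold's linkage call. Long, weakly
differentiated neo-sex scaffolds are the ones misclassified as autosomal,
so the reassignment rule is asymmetric and lineage-local: an orthogroup
slot pattern A+W with no Z promotes the autosomal copy to Z (a W copy
proves sex linkage, and W scaffolds — short, female-specific — are rarely
misassigned); A+Z with no W is left alone, the W copy treated as not
sequenced. The operation is idempotent.

Gap handling differs by statistic, matching how each is computed: pairwise
distances delete any aligned column where either sequence is gapped; the
codon statistics remove whole codon columns gapped in *any* focal-lineage
gametolog (outgroup-only gaps are kept). 'N' counts as a gap in both — a
conservative choice for distance estimation.

## Divergence statistics

**K80 distance (Dxy).** d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with P/Q the
observed transition/transversion proportions; no among-site rate
correction. Saturated pairs (non-positive log arguments) propagate as
explicit missing values, never as 0. ΔDxy = Dxy(W) − Dxy(Z) per orthogroup
is z-scored against the pooled distribution (sample SD) and flagged at
|z| > 1.96.

**NG86 dN/dS.** Nei–Gojobori (1986) counting with Jukes–Cantor correction.
Site counts disregard mutations to stop codons position-wise (S + N = 3 per
codon); differences are averaged over all shortest substitution pathways
with equal weight, excluding pathways through stop codons. Pathway-averaged
difference counts for all 61×61 sense-codon pairs are precomputed once.
This counting estimator replaces maximum-likelihood codon models: it is
dependency-free, exactly testable against enumeration, and sufficient for
the contrast-based questions (per-gene coastal−inland dN/dS differences,
with the most extreme ceil(1% · n) flagged; positive values mean faster
protein evolution in the coastal lineage).

**Bootstrap selection screen.** Codon columns are resampled with
replacement (default 1000 replicates, seeded per gene from the run seed);
the one-sided p-value for dN > dS is the fraction of defined replicates
with dN ≤ dS. This is a deliberately simple stand-in for branch-site
likelihood machinery; genes whose apparent acceleration stems from large
deletions are caught instead by the gap-span report, since deletions are a
known confounder of dN/dS-based selection tests.

**Exon forensics.** Gap spans are maximal runs of fully gapped ('---')
codons per sequence, with the span fraction taken over the aligned length;
'N' is missing data, not a deletion, and does not extend a span.
Cross-mapping of an exon against another assembly's scaffold uses local
Smith–Waterman alignment (match +2, mismatch −3, gap open −5, gap extend
−2, both strands, score threshold 50) via Biopython's `PairwiseAligner`.
Coordinates are 0-based half-open on the forward strand internally; only
human-readable reports use 1-based positions.

## Mixed models

Responses (Dxy; coastal−inland dN/dS) are modelled with crossed fixed
effects of gene function (N-mt vs not) and sex linkage (W vs Z) and a gene
random intercept. Estimation profiles the variance ratio λ = σ²_g/σ²_e out
of the REML criterion: at fixed λ the inverse correlation matrix is block
diagonal with a rank-one downdate per gene, so the GLS solution and the
criterion reduce to per-gene sums, and λ̂ is found by root-finding the
analytic REML score (machine precision; deterministic). On balanced
one-way designs this reproduces the closed-form ANOVA variance components.
Wald z-tests with a normal reference are reported per coefficient — a
reporting convention in the style of lme4 summaries. Reference levels are
fixed (non-N-mt, Z) and emitted in the report header so coefficient signs
are reproducible; the `linkage` coefficient is the W effect. Genes
contributing a single observation are retained (they inform σ²_e); with no
replication anywhere the intercept variance is inestimable and the fit
falls back to OLS with a warning. Per-class contrasts refit the model
within each linkage and function class, and the ratio of the W coefficient
between function classes summarizes how much stronger the W effect is in
N-mt genes.

## Synthetic data

The generators emulate the study conditions the pipeline assumes.

Scaffold cohort defaults: 200 autosomal + 60 Z + 40 W scaffolds;
`depth_mean = 90` (two pools of nine birds resequenced at ~10× each);
negative binomial counts with `depth_dispersion = 1.5` (variance =
dispersion × mean; 1 degenerates to Poisson) summed over ~1 kb windows, so
scaffold-level mean depth concentrates as it does when averaging along real
scaffolds. The absent sex receives a 2% mismapping depth floor, and its
horizontal coverage is drawn low (Beta mean 0.05) because mismapped reads
pile into repetitive tracts rather than spreading Poisson-like. W scaffolds
are shorter (log-normal median 50 kb vs 200 kb) as repeat content fragments
W assemblies.

Gene cohort defaults: 300 orthogroups × 300 codons; 10% N-mt (matching the
roughly one-in-ten share of N-mt genes among annotated neo-sex genes);
κ = 4 (passerine nuclear genes); all branch dN/dS = 0.2 (purifying).
Sequences start from a uniform draw over the 61 sense codons of the
standard nuclear code (these are nuclear genes; codon-frequency estimation
is out of scope) and evolve by a site-independent Gillespie process:
single-nucleotide codon changes only, rate κ for transitions × ω for
nonsynonymous changes, stops forbidden, rates normalized so one unit of
branch time is one expected substitution per nucleotide site at the root
composition. The fixed topology is
`(outgroup, ((A, (W, Z))_coastal, (A, (W, Z))_inland))` with branch lengths
(substitutions/site): outgroup 0.10, lineage stem ("split") 0.001,
autosomal 0.001, Z 0.0005, W 0.002. The inter-lineage split depth and the
Z/W onset are deliberately independent free parameters. `w_nmt_boost = 4`
multiplies W-branch lengths of N-mt genes, encoding accelerated neo-W
differentiation of mitochondrially functioning genes; deletions are applied
last from an explicit span list and recorded in the ground truth.

Every scaffold/gene draws from a seed-derived substream, so outputs are
byte-identical under a fixed seed and independent of iteration order.

**What the generator does not emulate:** read-level artefacts, assembly and
annotation errors, alignment uncertainty (homology is exact by
construction), indels other than specified deletions, recombination,
gene-tree discordance, and selection heterogeneity along genes. Passing
recovery tests therefore demonstrates correctness of the statistics under
the stated model, not robustness to real-data noise sources.

## Experiment sizes and numerical choices

The packaged experiments use: 10 cohorts × 300 scaffolds for classifier
recovery; 500 genes × 500 codons for neutral (ω = 1, κ = 1) calibration of
the NG86 estimator and the bootstrap screen (500 replicates per gene);
200 simulated fits for mixed-model coefficient coverage (3-SE intervals);
50 cohorts × 300 genes for interaction power under the default boost; and
the full 61×61 codon-pair grid plus 1000 random sequence pairs for oracle
agreement. K80/NG86 oracle comparisons are exact to 1e-12; REML matches
ANOVA components to better than 1e-10; undefined estimates (saturated
distances, dS = 0, p ≥ 3/4) propagate as missing values throughout.

## Known limitations

* The NG86 counting estimator is downward-biased at high divergence and
  ignores transition/transversion bias in pathway weighting (classic
  equal-weight convention); it is used for contrasts, not absolute rates.
* The bootstrap screen tests gene-wide dN > dS only; it cannot distinguish
  intensified positive selection from relaxed purifying selection, and
  lineage-specific episodic selection is out of scope.
* The scaffold classifier assumes the three-class mixture is visible along
  PC1; cohorts with heavy class imbalance or intermediate (partially
  differentiated) scaffolds will blur the k-means boundaries.
* Wald p-values with a normal reference are anti-conservative for very few
  groups; the packaged designs use hundreds of genes where this is
  immaterial.
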