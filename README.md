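# neosexscan

Tools for studying **neo-sex chromosome evolution from sex-pooled
resequencing data**, built around a two-lineage comparison of Z- and
W-linked gene copies (gametologs).

In birds and other ZW taxa, a former autosome recently fused to the sex
chromosomes ("neo-sex" chromosome) carries genes that are still intact, so
the early evolutionary dynamics of sex linkage can be observed directly.
Because the W chromosome is co-inherited with the mitochondrial genome,
nuclear genes with mitochondrial function (**N-mt genes**) on a neo-W are
prime candidates for mitonuclear co-evolution. `neosexscan` implements the
full analysis chain for this question:

1. **Scaffold sex-linkage (H1).** From pooled male/female mapping summaries
   it computes three per-scaffold metrics — male:female mean-depth ratio,
   male:female horizontal-coverage ratio, and the proportion of the female
   pool's single-copy kmers unmatched in the male pool — then classifies
   scaffolds as autosomal/Z/W by PCA + 1-D k-means along PC1, validates the
   calls with leave-one-out cross-validated LDA, and flags sex-linked
   scaffolds whose best reference hit (PAF, mapQ ≥ 40) is an autosome as
   neo-sex derived.
2. **Gametolog divergence (H2/H3).** Per orthogroup it applies the
   asymmetric autosome→Z reassignment rule, computes between-lineage
   divergence Dxy under the Kimura two-parameter model
   (d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)), per-gene ΔDxy = Dxy(W) − Dxy(Z) with
   |z| > 1.96 outlier flags, Nei–Gojobori (1986) dN/dS against an outgroup,
   coastal-minus-inland dN/dS contrasts with 1% outlier flags, a codon
   bootstrap screen for dN > dS, and exon-loss forensics (maximal gap-span
   detection plus Smith–Waterman cross-mapping of exons between assemblies).
3. **Inference.** Linear mixed models with gene as a random intercept
   (profiled REML, Wald z-tests) quantify the fixed effects of gene function
   and sex linkage — e.g. whether W linkage elevates between-lineage Dxy
   more in N-mt genes than in other genes.

A fully seeded synthetic-data module generates scaffold tables and codon
alignments (Gillespie simulation of a codon substitution process with
per-branch dN/dS) with ground-truth labels, so every stage is testable by
parameter recovery.

## Worked example

Run the whole pipeline on a synthetic cohort (300 scaffolds, 60 genes):

```bash
cat > sim.yaml <<EOF
seed: 7
outdir: run1
simulate:
  n_genes: 60
thresholds:
  n_boot: 200
EOF
neosexscan all --config sim.yaml
```

The JSON summary printed at the end includes (abridged):

```json
"h1": {
  "class_counts": {"A": 200, "W": 40, "Z": 60},
  "loocv_lda_accuracy": 1.0,
  "pc_variance_fractions": [0.8779, 0.1206, 0.0015],
  "n_neo_sex": 49,
  "neo_sex_total_length_bp": {"W": 934324, "Z": 7725030}
}
```

Read: the three inheritance classes separate cleanly along PC1 (88% of
metric variance), the LDA predicts every call correctly under leave-one-out
cross-validation, and 49 of the sex-linked scaffolds have their best
reference hit on an autosome — the neo-sex signature. The `h2h3` section
reports the Dxy/dN-dS tables, ΔDxy outliers, selection-screen p-values and
the mixed-model fits; under the default generator, W-linked N-mt genes are
more diverged between lineages than their Z-linked gametologs, and the
`function:linkage` interaction is significant.

Per-stage outputs land in `run1/` as TSV tables (`linkage_calls.tsv`,
`dxy.tsv`, `dnds.tsv`, `delta_dxy.tsv`, `selection_screen.tsv`,
`gap_spans.tsv`, …), each ending in a provenance comment (config hash,
seed, version).

## Layout

```
src/neosexscan/
  simdata.py     synthetic scaffold tables + codon alignments (with truth)
  sexlink.py     metrics, PCA/k-means classification, LDA, PAF rules
  gametolog.py   reassignment rule, function labels, gap handling
  divergence.py  K80, delta-Dxy, NG86 dN/dS, bootstrap screen, forensics
  stats.py       random-intercept REML mixed models
  pipeline.py    stage orchestration, TSV/JSON reports
  cli.py         `neosexscan simulate|h1|h2h3|all`
docs/methods.md  model and design notes
```
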