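# mztenh

Chromatin-based classification of early-embryo regulatory elements:
separating **H3K4me1-only enhancers** (hypermethylated, dependent on
maternal pluripotency-factor pioneering) from **H3K4me2-marked
enhancers** (hypomethylated, gamete-shared, pioneer-independent) in
blastula-stage zebrafish embryos, from CUT&RUN-style histone
modification coverage over ATAC-seq open-chromatin regions.

The package is aimed at computational biologists analysing chromatin
profiling of the maternal-to-zygotic transition, and at anyone who
needs a tested, reusable implementation of this class of
enrichment-threshold + discordance-detection pipeline.

## The method in brief

Each open-chromatin region *r* is quantified on three subintervals
(open interval plus two abutting 500-bp flanks) with
mononucleosome-sized fragments (140–250 bp, trimmed to tag-centered
73-bp windows, deduplicated), normalized as

    log2(RPK500 + 1),    RPK500 = count / (len/500) / (lib/10^6) = RPKM/2

A centered PCA of the pooled per-mark features feeds an RBF SVM
(γ = 1, C = 1) trained on annotation labels — promoters (regions
overlapping a CAGE-supported TSS, > 20 tags) versus distal regions
(≥ 2 kb from every TSS). Distal regions the SVM calls "promoter"
despite their distal location are the discordant, promoter-like class;
combined with pooled fold enrichment over IgG,

    fold(mark) = (RPK500_mark + 0.1) / (RPK500_IgG + 0.1)

the final calls are: **H3K4me2 enhancer** = SVM "promoter" ∧
H3K27ac ≥ 1.5 ∧ H3K4me2 ≥ 2 (plus a rescue for SVM-"enhancer" regions
with top-quartile H3K4me2 coverage); **H3K4me1 enhancer** = SVM
"enhancer" ∧ H3K4me1 ≥ 2 ∧ H3K4me2 < 1.25 ∧ H3K27ac ≥ 1.5; poised
(H3K27ac ≤ 1.5) and TSS-proximal potential enhancers are annotated
alongside. Putative enhancers with stable directional RNA-seq in their
100-bp flanks (≥ 1 RPKM, ≥ 2× strand-biased, in ≥ 2 stages, not
exon-contained) are removed as unannotated gene TSSs. Downstream
statistics — motif density and presence χ², methylation strata and
gamete sharing, CpG / C+G composition, nearest-gene rank-sum
comparisons, GO Fisher + BH — and the crispant qRT-PCR ΔCt analysis
(2^−ΔCt, control mean normalized to 1, rank-sum test) complete the
pipeline. `docs/methods.md` documents every rule, boundary convention
and default.

A first-class synthetic-data generator (`mztenh.simulate`) emulates
all inputs — negative-binomial CUT&RUN fragments over an IgG baseline,
spike-ins, methylation, stranded RNA flanks, expression tables,
Ct tables — with the planted class structure recorded as ground truth,
so the entire pipeline is testable without any external data.

## Worked example

Run the full pipeline on a default synthetic study (200 regions per
element class, 7 marks + IgG, 2 replicates, 1.5 M fragments/sample):

```bash
mztenh pipeline --seed 7
```

```json
{
  "recovery": {
    "H3K4me1-enhancer:sensitivity": 0.99,
    "H3K4me1-enhancer:precision": 1.0,
    "H3K4me2-enhancer:sensitivity": 0.9946236559139785,
    "H3K4me2-enhancer:precision": 1.0,
    "cryptic:removal_recall": 1.0
  },
  "final_call_counts": {
    "high-K4me23-promoter": 397,
    "unclassified": 210,
    "H3K4me1-enhancer": 198,
    "poised-enhancer": 193,
    "H3K4me2-enhancer": 185,
    "low-K4me23-promoter": 3
  },
  "svm": {
    "kernel": "radial-basis",
    "gamma": 1.0,
    "cost": 1.0,
    "n_pcs": 3,
    "training_accuracy": 0.8316666666666667
  }
}
```

Of the 200 planted H3K4me1 enhancers, 198 are recovered (99%
sensitivity) with no false positives; 185 of the 186 non-contaminant
H3K4me2 enhancers survive calling plus the transcription filter, and
all planted cryptic-TSS contaminants are removed. The SVM's training
accuracy is deliberately far below 1: the ~200 promoter-like H3K4me2
enhancers carry the training label "enhancer" (they are distal) but
sit inside the promoter point cloud, so the classifier "misclassifies"
them — that discordance is the signal the caller uses.

Analyse a crispant qRT-PCR Ct table (here a synthetic table planting a
1.7-fold knockdown across 10 embryos per group):

```bash
mztenh qpcr --ct ct_table.csv
```

```json
{
  "fold_decrease": 1.6852152254471517,
  "pvalue": 1.082508822446903e-05,
  "statistic": 100.0,
  "n_control": 10,
  "n_crispant": 10,
  "fold_method": "ratio-of-means"
}
```

The recovered fold decrease (1.69×) matches the planted effect within
per-embryo sampling error; the p-value is a two-sided Wilcoxon
rank-sum test between the normalized per-embryo expression values.

`mztenh simulate --outdir study/ --seed 7` writes a complete synthetic
study (BED regions and fragments, TSS/exon/expression tables,
methylation, Ct tables) to disk in plain-text formats.

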