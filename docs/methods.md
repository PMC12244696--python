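# Methods

## The problem

During the maternal-to-zygotic transition (MZT) in zebrafish, two
distinct sets of enhancers drive zygotic genome activation.
One class is marked by H3K4me1 (but not H3K4me2), is hypermethylated,
and depends on pioneering by the maternal pluripotency factors Nanog,
Pou5f3 and Sox19b (NPS). The other is marked by H3K4me2, is
hypomethylated — often in both gametes as well as the embryo — and
activates independently of NPS. `mztenh` implements the computational
pipeline that separates these two classes from CUT&RUN-style histone
modification coverage over ATAC-seq open-chromatin regions, plus the
downstream association statistics and the crispant qRT-PCR analysis
used to validate individual enhancers.

## The classification model

Every open-chromatin region is quantified by fragment counts on three
subintervals: the open interval itself and its two abutting 500-bp
flanks. Only mononucleosome-sized fragments (140–250 bp pair-spanned)
are used; each is trimmed to a tag-centered 73-bp window
([mid − 36, mid + 37), so all windows are exactly 73 bp) and exact
duplicates are removed per sample. Spans of exactly 73 bp are treated
as already-trimmed, which makes the filter idempotent. Counts are
normalized as log2(RPK500 + 1), where RPK500 = reads per 500 bp per
million filtered fragments = RPKM/2. The flank with the larger
all-mark raw coverage sum is labelled "downstream" (genomic-right on
ties).

A PCA (centered, not variance-scaled; loading signs fixed so each
vector's largest-magnitude entry is positive) summarizes the pooled
per-mark features. An RBF SVM with γ = 1 and C = 1, trained on the
standardized first three PC scores with promoter-taxonomy regions
labelled "promoter" and distal regions labelled "enhancer", provides a
chromatin-state reference label for every region. The taxonomy itself
comes from annotation: regions overlapping a selected promoter TSS
(the maximally expressed TSS per gene, requiring > 20 CAGE tags,
strict) are promoters; regions < 2 kb from any isoform TSS are
TSS-proximal; regions ≥ 2 kb away are distal. Distance is 0 for a
contained TSS, else min(|start − tss|, |tss − (end − 1)|) in 0-based
half-open coordinates.

Final element calls combine the SVM label with pooled dome-stage fold
enrichments over IgG, computed as (RPK500_mark + 0.1) /
(RPK500_IgG + 0.1) on the combined center + downstream interval:

* H3K4me2 enhancer: distal, SVM "promoter", H3K27ac ≥ 1.5,
  H3K4me2 ≥ 2 — the discordant, promoter-like chromatin is the
  defining signal;
* rescue: distal SVM-"enhancer" regions meeting the same enrichment
  thresholds whose pooled H3K4me2 coverage reaches the 75th percentile
  (linear-interpolation quantile) of the already-called class;
* H3K4me1 enhancer: distal, SVM "enhancer", H3K4me1 ≥ 2,
  H3K4me2 < 1.25, H3K27ac ≥ 1.5;
* poised enhancer: otherwise mark-bearing with H3K27ac ≤ 1.5. At
  exactly 1.5 an active call takes precedence (configurable);
* TSS-proximal potential enhancers: H3K4me3 < 1.25 with the same
  H3K4me2/H3K4me1 patterns;
* promoters are split by SVM concordance into high- and low-K4me2/3
  groups.

The two enhancer classes are mutually exclusive by construction
(H3K4me2 ≥ 2 versus < 1.25).

The enrichment interval (center + downstream) and the ratio
pseudocount 0.1 are configurable; they mirror the coverage-gate window
used for the initial heatmap groups and the conventional ratio-track
pseudocount.

## Transcription filter

Putative enhancers that behave like unannotated gene TSSs are removed:
a region is flagged if, in at least two developmental stages, one
strand's RNA-seq coverage in the 100-bp flank downstream of a putative
TSS direction is ≥ 1 RPKM and ≥ 2× the opposite flank (zero opposite
coverage qualifies; the ratio is +∞). Regions whose 100-bp flank lies
entirely within a single annotated exon are exempt — partial overlap
does not exempt, since that would excuse nearly everything near genes.
Flagged, non-exempt regions are dropped from both enhancer classes and
reported.

## Dynamics and association statistics

* Time-course H3K4-methylation PCA: each region contributes one row
  per stage (9 features: three marks × three subintervals), so group
  trajectories through PC space can be drawn.
* RNA activation trajectories: per gene, log2(x_t + 0.1) −
  log2(x_0 + 0.1); group mean with 95% CI = ± t(0.975, n−1) · sd/√n,
  sample (n−1) standard deviation. Maternal-zygotic genes are those
  with 2-cell expression > 0.5 RPKM (strict).
* Motif density: brute-force PWM log-odds scanning on both strands in
  a ±100 bp window around the open-interval center; the default
  threshold is 0.8 × the maximal achievable log-odds under a uniform
  background (the scanning tool threshold is otherwise unstated;
  recorded in output and configurable). Presence is compared between
  classes by Pearson chi-squared without continuity correction —
  default 2×2 presence/absence (1 d.o.f.); a 3-level {0, 1, ≥2 hits}
  variant (2 d.o.f.) is provided because both forms appear in the
  literature this follows.
* Methylation strata: < 20% low, 20–80% medium, > 80% high, with the
  boundaries inclusive to medium (the printed low/high bounds are
  strict). Gamete sharing: the fraction of embryo-hypomethylated
  regions also < 20% methylated in both egg and sperm.
* Distances and proximity: edge distance from enhancer to nearest
  gene-group TSS; two-sided Wilcoxon rank-sum (exact null for combined
  n ≤ 20 without ties, otherwise normal approximation with tie
  correction); proximity fractions at 100 kb / 1 Mb radii.
* GO enrichment: per-term two-sided Fisher's exact test on
  (annotated / not) × (near class A / near class B), Benjamini–
  Hochberg across terms.

## Crispant qRT-PCR

Technical replicates are averaged per embryo and primer; ΔCt =
Ct_target − Ct_reference; 2^−ΔCt is normalized so the control-embryo
average is exactly 1. The knockdown is the fold decrease
control-mean / crispant-mean (equivalently 1/crispant-mean) with a
two-sided rank-sum p. A mean-of-reciprocals variant is provided
because "average fold decrease" admits both readings; ratio-of-means
is the default.

## The synthetic-data generator

The generator emulates the full input suite — annotation, region
universe from two sources, fragment sets, spike-in counts, methylation,
stranded RNA flank reads, expression tables, motif counts, Ct tables —
with the statistical structure the analysis assumes planted as ground
truth. What it emulates, and what it does not:

* **Genome layout.** Genes and distal regions occupy a 6-kb slot grid
  on four 2.5-Mb chromosomes, so promoter-class regions overlap a
  CAGE-supported TSS and all other classes are ≥ 2 kb from every TSS
  by construction. Real genomes have clustered genes, repeats and
  scaffolds; those are exercised by constructed fixtures in the unit
  tests, not by the generator.
* **Coverage.** Per-region fragment counts are negative-binomial
  (var = μ + φμ², φ = 0.002 by default — deeply sequenced, mildly
  overdispersed libraries) with mean = baseline × planted fold.
  Fragment spans are a clipped normal (185 ± 30 bp within 100–400), so
  the mononucleosome gate removes a realistic tail. Each library is
  padded to the configured depth (1.5 M fragments/sample, two
  replicates) with background fragments outside region territory;
  region territory holds ~12% of an IgG library. Because library
  sizes are equal by construction, measured mark/IgG enrichment
  estimates the planted fold directly. Fragment midpoints are sampled
  without replacement within each subwindow: fragments model unique
  library molecules, and the finite window imposes a library-complexity
  ceiling that compresses the most extreme enrichments, as saturation
  does in real libraries.
* **Class profiles.** Six element classes with dome-stage fold
  enrichments over IgG for seven histone marks. The defining folds are
  strong (≥ 3): H3K4me1 enhancers carry H3K4me1 4.5× and H3K27ac 3.5×
  with background H3K4me2; H3K4me2 enhancers carry H3K4me2 5× and the
  promoter acetylation signature. Every region also draws a lognormal
  *activity* latent that scales the enrichment component of all its
  marks jointly: elements form a continuum of activity, not point
  masses. Active promoters, weak promoters and H3K4me2 enhancers sit
  on the same H3K4me2-high/acetylation-high ray of that continuum
  (weak promoters lower and broader), which is exactly the structure
  the discordance detection assumes: H3K4me2 enhancers land inside the
  promoter point cloud of the leading principal components and the SVM
  labels them "promoter". Promoter H3K4me3 is modelled as a modest
  enrichment (1.3×) so that H3K4 methylation degree and overall
  activity, not H3K4me3 alone, dominate the leading PCs — in the data
  this pipeline is built for, many marks share the promoter-activity
  variance and H3K4me3 does not separate the top components either.
* **Methylation.** Beta-distributed around class means (concentration
  80; infinite concentration gives exact means). 69% of H3K4me2
  enhancers are hypomethylated in both gametes; the rest are
  gamete-hypermethylated.
* **Transcribed contaminants.** 7% of H3K4me2 enhancers are flagged as
  cryptic gene TSSs and receive strong strand-biased flank coverage
  (mean 8 RPKM downstream vs 0.5 upstream) across four stages;
  everything else gets sparse ambient signal (mean 0.02 RPKM) so
  spurious reproducible directional calls are rare.
* **Ct tables.** Three technical replicates per embryo and primer;
  crispant ΔCt shifted by log2(fold) × (edited fraction / mean edited
  fraction), with the edited fraction Beta(8, 2)-distributed
  (mosaicism, mean 0.8). The normalization keeps the mean shift equal
  to log2(fold); with all noise scales at zero the recovered fold is
  exactly the planted fold.

Passing tests on this generator demonstrate that the pipeline recovers
structure it was designed to detect under realistic count noise; they
do not demonstrate robustness to mappability artifacts, copy-number
variation, antibody cross-reactivity, or annotation errors, none of
which the generator models.

## Numerical choices and determinism

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawn keys, so outputs are byte-identical
across runs; the package default is 20250710. PCA uses SVD with the
sign convention above; quantiles are linear-interpolation; the SVM's
`random_state` is pinned although the RBF solver is deterministic for
fixed inputs. Degenerate inputs are defined: enrichment of 0/0 is 1
(pseudocount), empty fragment sets give zero matrices, an empty
embryo-hypomethylated set yields an undefined (None) shared fraction,
and groups of n < 2 get means without confidence bounds.

## Problem sizes

The default study simulates 200 regions per class (1,200 regions),
seven marks + IgG at two replicates and 1.5 M fragments each —
about 12 M fragments — and runs end-to-end in well under a minute on
one CPU. Unit and property tests use 30–100 regions per class and
depths of 150–800 k to keep the suite fast; the acceptance checks run
the full default size.

## Known limitations

* The SVM discordance step depends on promoters outnumbering
  promoter-like enhancers locally in PC space; with gross class
  imbalance reversed (many more H3K4me2 enhancers than promoters) the
  rescue path alone cannot maintain sensitivity.
* Enrichment thresholds are calibrated for IgG-ratio fold changes with
  equal library sizes; strongly unequal library complexity between
  marks would bias ratios (the generator's unique-molecule model makes
  this explicit).
* The transcription filter's two-dataset confirmation logic is modeled
  as a single gating dataset with an optional intersection mode, since
  the combination rule in the original analysis is not fully specified.
* Spike-in scaling is provided for track export and cross-condition
  comparison only; classification uses within-stage mark/IgG ratios,
  which cancel the spike factor.
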