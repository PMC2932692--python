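# tilechip

Analysis of ChIP-chip tiling-array experiments: from per-probe two-channel
log2 ratios to z-score tracks, sliding-window peak calls, peak–gene
annotation, metagene profiles, and gene-set statistics — together with a
synthetic-data generator that implants known enrichment domains so every
stage can be validated against ground truth.

The package is aimed at the kind of experiment in which a chromatin factor
or histone mark (e.g. an H3K36 methyltransferase and its me2/me3 marks,
RNA polymerase II, or a mock-IP control) is profiled genome-wide on 50-bp
tiling probes, and the questions are: where are the binding domains, which
genes do they cover, how is binding distributed across chromosomes, and how
does it relate to gene expression classes.

## The model

**Normalization.** Per-probe enrichment is the log2 ratio of the IP channel
over the input channel, standardized per replicate to mean 0 and population
SD 1 (a *z-score track*), then averaged across replicates. A perturbed
condition can be *anchored*: an affine map `v ↦ a·v + b` is fitted so the
mean and SD over an anchor chromosome match a reference condition, and
applied genome-wide.

**Peak calling.** Windows of 500 bp stepped every 100 bp are scored by
their member-probe mean z̄. The background is Gaussian with SD σ₀
estimated from the negative probe values reflected about zero,
σ₀ = √(mean v² | v < 0), so a window of n probes has upper-tail p-value
P(N(0, σ₀/√n) ≥ z̄), computed in log space. Bonferroni correction
multiplies by the number of evaluated windows; windows with adjusted
p ≤ 10⁻²⁰ are merged (overlapping or bookended) into peaks whose summit is
the maximum-value probe midpoint. Peaks within 100 bp of a mock-IP
(no-antibody) peak are discarded.

**Annotation.** Peaks relate to genes with precedence gene-body >
upstream-1kb > downstream-1kb > intergenic (flanks strand-aware); summits
are classified by the hierarchy exon > intron > 3′ > 5′ > distal.
Per-chromosome counts are tested against a uniform-by-length null:
expected_c = N·L_c/ΣL, with an exact log-space binomial tail for the focal
chromosome and a chi-square across all chromosomes.

**Profiles and gene sets.** Genes are oriented 5′→3′ and probes pooled
into 50 × 50-bp bins around the TSS (−1 kb..+1.5 kb) and TES
(−1.5 kb..+1 kb), per expression quintile, with 1.96·SEM confidence bands;
intron–exon–intron triplets (all parts ≥ 300 bp) give exon-boundary
profiles with optional per-triplet intronic-baseline subtraction.
Gene-level scores (mean z over probes fully inside the transcript) feed
boxplot summaries, strict threshold classification (e.g. z > 1 on two
targets and z < 0 on a third), and hypergeometric set-overlap enrichment.

**Expression summarization.** Multi-probe expression arrays are quantile
normalized, summarized per gene by Tukey median polish under
`value ≈ gene + sample + probe`, averaged across samples, and z-scored
across genes.

## Worked example

Run the whole synthetic pipeline (6 × 1 Mb chromosomes, ~200 genes in six
expression classes, enrichment amplitude 5 on noise SD 1, 3 replicates per
target, X-like chromosome depleted of germline-class genes):

```sh
tilechip run --seed 0 --outdir out/
```

The run report (`out/report.json`) from that command contains, among other
counts:

```
callpeaks:  n_windows 60000, n_candidate_peaks 127, n_removed_by_control 0,
            n_peaks 127
annotate:   relation_counts {gene-body: 127}, n_bound_genes 127,
            focal_observed 6, focal_expected 21.17,
            focal_tail "depletion", focal_log10_p -4.42
genesets:   n_selected 20, evidence_percent 100
recovery:   recall 1.0, precision 1.0
```

Reading: all 127 peaks fall on implanted domains (precision 1.0) and every
implanted domain is found (recall 1.0); every peak overlaps a gene body;
only 6 peaks land on the X-like chromosome where 21.2 were expected under
the uniform-by-length null (binomial depletion p ≈ 10⁻⁴·⁴), reproducing
the autosomal concentration the generator implants; and the 20 genes with
high mes4/h3k36me3 (z > 1) but low pol2 (z < 0) are all germline-class
genes.

Individual stages are available as `tilechip
simulate|normalize|callpeaks|annotate|profile|genesets|expression`, and as
library functions (`tilechip.peakcalling.find_peaks`,
`tilechip.annotate.chromosome_distribution`, …).

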