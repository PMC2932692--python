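# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Coordinates and containers

All coordinates are 0-based, half-open; exporters convert where a format
requires otherwise (BED is native; bedGraph likewise). A probe's point
location, wherever one is needed (window membership, profile binning,
summits, densities), is its midpoint rounded down. Signal travels as probe
tables — DataFrames with `chrom, start, end, probe_id, value` sorted by
`(chrom, start)` — and readers validate coordinates against the declared
genome layout, rejecting out-of-bounds records rather than clamping.

## Normalization

Each replicate's log2 IP/input ratios are standardized to mean 0 and SD 1
over all probes genome-wide. The SD is the **population** SD (divide by
n): the choice makes the two-point case `[-1, 1]` exact and is the common
convention for whole-array standardization; `ddof=1` is available. No
per-chromosome stratification is applied. Replicates are standardized
first, then averaged (arithmetic mean per probe).

Anchored normalization estimates `a = sd_ref/sd_track` and
`b = mean_ref − a·mean_track` from anchor-chromosome probes only and
applies the map genome-wide. It exactly inverts any affine corruption of
the reference, which is the property the tests pin down. The intended use
is a depletion condition whose genome-wide signal is globally shifted, with
one chromosome expected to be unaffected.

Windowed median smoothing (default span 250 bp) replaces each probe's
value by the median over same-chromosome probes whose midpoints lie within
±span/2, closed at both ends; a lone probe maps to itself. Replicate and
cross-target concordance is the Pearson correlation matrix of smoothed
tracks over all probes.

## Peak calling

The caller assumes a Gaussian background. Its SD is estimated from the
negative values reflected about zero: σ₀ = √(mean v² over v < 0). The
rationale is that genuine enrichment is positive, so negative probes are
noise-only; reflecting them doubles the sample without assuming the
positive side is clean. This estimator is a documented reconstruction of
the sliding-window approach it follows; with a different background
estimator absolute peak counts on real data will differ, so genome-scale
counts are not expected to be bit-reproducible.

Windows (default 500 bp, step 100 bp) start at 0 on every chromosome and
run to the chromosome end, so a chromosome shorter than one window still
yields its truncated-coverage window. A probe belongs to a window iff its
midpoint is in `[start, start+window)`; windows with fewer than
`min_probes` (default 1 — the upstream tool's internal rule is not
recoverable, so it is exposed as a flag) are skipped. The upper-tail
p-value of the window mean under `Normal(0, σ₀/√n)` is computed with the
exact log-survival function; Bonferroni multiplies by the number of
**evaluated** windows genome-wide (not the theoretical grid). The cutoff
(default 10⁻²⁰, read inclusively: adjusted p ≤ cutoff passes) is applied
in log space, so tails far below float underflow remain ordered.

Significant windows that overlap or bookend (gap ≤ 0 under half-open
arithmetic) merge into maximal peaks; no sub-peak splitting is attempted.
The peak's summit is the midpoint of the maximum-value probe within the
merged interval, leftmost on ties; its adjusted p is the minimum over
merged windows and its mean z comes from the most significant window.
Control subtraction removes a peak iff its edge-to-edge gap to a
same-chromosome control peak is ≤ `max_gap` (default 100 bp, one step);
overlap counts as gap 0. The identity |input| = |removed| + |output| is
asserted in the pipeline report.

## Peak–gene annotation

Gene-level signal is the mean over probes **fully contained** in
`[tx_start, tx_end)`; genes shorter than a probe are missing, never zero.
Peak relations use the precedence gene-body > upstream-1kb >
downstream-1kb > intergenic, with flanks strand-aware; the precedence
resolves peaks that sit between two genes, a tie rule the source analysis
leaves unstated. The body-overlap genes (≥ 1 bp) form the "bound" set;
flank-only genes are reported separately. Summit features follow the
hierarchy exon > intron > 3′ > 5′ > distal, all tested as half-open
intervals containing the summit coordinate.

Chromosome distribution uses the uniform-by-length null
`expected_c = N·L_c/ΣL`. The focal-chromosome test is an exact binomial
tail computed in log space — lower tail when observed < expected
(depletion), upper tail otherwise; a chi-square over all chromosomes
(df = #chromosomes − 1) is reported alongside, because the test behind the
published depletion p-value is not named and the two can differ by many
orders of magnitude this far out in the tail. The WS170/ce4 chromosome
lengths ship as constants so length-expected counts can be reproduced
without downloads; any layout may be supplied. Densities are summits per
kb over a half-open region.

## Profiles

Genes are mirrored into transcription-relative coordinates, so minus-strand
genes contribute their probes reversed; without this, TSS/TES-asymmetric
signals would cancel. The TSS window default is −1000..+1500 and the TES
window −1500..+1000 (50 bins of 50 bp each). The alternative "methods"
convention (−1500..+1000 around the TSS) is available as a switch because
the two descriptions of the source analysis conflict; the default follows
the one consistent with the plotted profiles. Probes are assigned to the
**nearest bin center**; a midpoint exactly between two centers goes to the
left bin. Bin statistics pool probes across genes of a group (not
per-gene averages — a per-gene-weighted variant can be built on
`gene_mean_z` if needed); the confidence band is 1.96·SEM over pooled
probes, a normal approximation. Bins with no probes are NaN with count 0,
never silently zero.

Expression grouping takes genes longer than 2 kb, ranks by expression with
ties broken by gene id (a stable, reproducible rule), and splits into k
equal groups (±1) — group k−1 is the most expressed.

Exon-boundary profiles use intron–exon–intron triplets: every internal
exon whose length and both flanking intron lengths are ≥ 300 bp. Windows
are −300..+200 around exon starts and −200..+300 around exon ends
(10 bins each), in transcription orientation. With baseline subtraction,
each triplet's probe values are reduced by the mean over its two intronic
intervals first; triplets with no intronic probes are skipped and counted.

## Expression summarization

Quantile normalization equalizes column marginals to the cross-column mean
of order statistics, preserving within-column order and averaging ties;
it is idempotent. Gene summarization is Tukey median polish per gene
(probes × samples), starting with a row sweep, stopping at a maximum sweep
update < 10⁻⁶ or 10 iterations; the returned value per sample is
overall + sample effect, i.e. the probe effect is removed. On exactly
additive data the fit is exact with zero residual. Background correction
is deliberately omitted: the single-color input is assumed
vendor-background-handled, and no background parameters are available.
Values are log2 before normalization. Per-gene values are averaged across
samples and z-scored across genes (population SD).

## The synthetic-data generator

The generator emulates the *structure* the analysis assumes, not any real
genome: named chromosomes (default five autosome-like plus one X-like,
1 Mb each), non-overlapping genes with exon/intron structure, class labels
from one multinomial draw over a six-class mix (germline-specific,
germline-expressed, ubiquitous, embryo-expressed, soma-specific, silent),
50-bp probes tiled end to end, and per-target enrichment with Gaussian
probe noise on the log2 scale (matching the Gaussian background the peak
caller assumes; no heavier-tailed model is claimed by the analysis).

Enrichment shapes: `flat-body` (amplitude over fully contained probes),
`five-prime-skewed-body` (linear rise to a maximum 500 bp into the body,
then a gradual decline to 60% at the 3′ end), `tss-peak` and
`tss-and-tes-peak` (Gaussian bumps, σ = 250 bp, truncated at 3σ),
`anti-expressed` (negative body signal), and `promoter-dip` (body signal
with a depleted 300-bp promoter). Default targets: a 5′-skewed gene-body
factor ("mes4"), a flat gene-body mark ("h3k36me3"), a TSS+TES polymerase
("pol2"), and an all-zero mock IP ("noab").

Free parameters the emulated study does not quantify, fixed once here:
enrichment amplitude 5 and noise SD 1 (log2 units), 3 replicates, ~200
genes of which 70% exceed 2 kb, minimum gene gap 500 bp, germline-class
genes allowed on the X-like chromosome with probability 0.05, class
expression means (log2) silent 4 < soma 6 < germline-specific 7 <
germline-expressed/embryo 8 < ubiquitous 9, expression probe-offset and
noise SDs 0.25. Randomness is organized as named streams derived from the
master seed — one for the genome, one for expression, one per
(target, replicate) — so adding a target or replicate never perturbs the
others, and identical configurations reproduce outputs byte-for-byte.

What the generator does **not** emulate: sequence (no FASTA, no
hybridization thermodynamics), dye bias or spatial array artifacts,
copy-number or mappability structure, operons, overlapping or nested
genes, and probe-level GC effects. Passing recovery tests therefore shows
the pipeline is correct under its own model assumptions — Gaussian noise,
well-separated genes, step-like domains — not that it matches any
particular real-data peak count.

## Problem sizes and runtime choices

The default synthetic genome (6 Mb, 120k probes, 60k evaluated windows,
200 genes) runs the full pipeline in well under a minute on one CPU;
oracle-equivalence tests use instances of ≤ 10⁴ probes, and the
profile-oracle fixtures 200 genes, sizes at which the brute-force
references are exact and fast. These sizes are the package's own test
design; all operations scale linearly in probes and windows.

## Known limitations

- The background estimator is a reconstruction (see Peak calling); real
  datasets analyzed with the original tool will yield somewhat different
  peak inventories at the same nominal cutoff.
- Bonferroni over evaluated windows is conservative and ignores window
  overlap; no FDR alternative is offered by design.
- The binomial focal-chromosome test treats peaks as independent uniform
  placements; long enrichment domains violate independence, so the
  reported tails are sharper than a domain-aware null would give.
- Pooled-probe profile confidence bands treat probes as independent,
  ignoring within-gene correlation.
- Multi-variant genes are not merged; the caller supplies one transcript
  per gene.
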