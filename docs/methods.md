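# Methods

## The analysis model

The pipeline treats one experiment as a paired two-condition design:
within each age group, the injured (ipsi) and control (contra) hemisphere
are compared for RNA abundance and for three promoter histone marks
(H3K4me3, H3K9ac — activating; H3K27me3 — repressive) with matched input
chromatin. All genomic coordinates are 0-based half-open throughout; any
1-based dialect is converted at the I/O boundary. The transcription start
site (TSS) anchors everything: for a plus-strand gene it is `start`, for a
minus-strand gene `end − 1` (the last covered base).

## Differential expression

Counts are modeled as negative binomial with a common dispersion φ shared
across genes. The test is exact and conditional: for a gene with group
counts summing to T, the split of T between groups under the null is a
beta-binomial-type law with weights `n_a/φ` and `n_b/φ` that does not
depend on the unknown mean, so the two-sided p-value is the sum of all
conditional outcomes whose point probability does not exceed the observed
one. As φ → 0 the law converges to Binomial(T, n_a/(n_a+n_b)) — the
classic conditional Poisson test — and the implementation switches to that
limit exactly at φ = 0. Unequal library sizes are handled by rescaling
counts to the mean effective size before conditioning (rounding to
integers); this is an approximation, adequate when size factors are within
a few tens of percent of each other, as in the designs simulated here.

Dispersion is estimated by pooled method of moments: per gene and
replicated group, `(s² − m)/m²` from the within-group mean and unbiased
variance, averaged over genes and floored at zero after pooling. The mean
of the raw estimates is used rather than a median of floored ones because
with 2–3 replicates the sampling distribution of s² is strongly
right-skewed: the median sits well below the true dispersion and makes
the downstream test anti-conservative, visibly inflating the null DEG
rate.

Size factors are median-of-ratios (each sample's median ratio to the
per-gene geometric mean, over genes expressed everywhere). Raw library
sizes are deliberately not used: planted (or real) one-sided up-regulation
inflates one group's totals and makes every unchanged gene look
down-regulated — with 10% of genes up 4-fold, library-size normalization
alone pushed the false-discovery proportion above 0.1 in our recovery
benchmarks.

A gene is a DEG when the raw p-value < 0.01 and |log2 fold change| ≥ 1,
the fold change computed on size-factor-normalized group means with a
pseudocount of 0.5 added to both means (keeps zero-mean genes finite;
the value is a declared convention, and at moderate counts its effect is
negligible). No multiple-testing correction is applied by default;
Benjamini–Hochberg is available behind `adjust=True`.

## Locus clustering

Per chromosome, `AD = chromosome length / number of DEGs on it`; a single
left-to-right scan over DEG positions starts a new cluster whenever the
gap to the previous gene is ≥ AD (strictly smaller gaps join). Distance is
TSS-to-TSS by default — chosen because every other analysis in the package
is TSS-anchored; start-to-start and midpoint measures are available. The
rule's boundary is exact: a gap equal to AD splits.

## pDMG calling

Candidate peaks have fold enrichment strictly greater than 4 (a peak at
exactly 4.0 is excluded). The promoter window is symmetric,
`[tss − 5000, tss + 5001)`, clipped to the chromosome; a one-sided
upstream window is available since "near the TSS" is ambiguous in general.
Replicate peak sets are pooled before assignment. A gene is mark-positive
when ≥ 1 candidate peak overlaps its window by ≥ 1 bp (bookended
intervals do not overlap under half-open coordinates); one peak may
support several genes. pDMGs are the set differences: gained = positive in
ipsi only, lost = positive in contra only.

## rDMG calling

Peaks from all samples of one mark are merged by transitive ≥ 1 bp
overlap into disjoint merged peaks. Each merged peak's density per sample
is `reads / (library_size/10⁶) / width_kb`, the width being the merged
interval's, not the constituent peaks'. Library sizes default to each
sample's total read count. The input density (averaged over input
replicates of the same condition) is subtracted from each ChIP replicate's
density; non-positive enrichments are floored at ε = 10⁻³ and flagged
low-signal, so the logarithm stays defined without discarding peaks
asymmetrically between groups. The test is a two-sided equal-variance
Student t on the per-replicate natural-log enrichments (with two
replicates per side this is df = 2 — the group-averaged enrichment values
leave nothing to test). Significant peaks (p < 0.05) confer rDMG status
on every gene whose ±3 kb TSS window they overlap, with the direction of
the group difference.

## Profiles and set statistics

TSS metaprofiles bin read midpoints by signed offset within ±5 kb of each
TSS, negating offsets for minus-strand genes so positive is always
downstream; a read in the windows of several genes counts toward each
(single-assignment to the nearest TSS is optional). The peak-location
summary reports the percentage of peaks overlapping any ±2.5 kb TSS
window by ≥ 1 bp (a summit-inside mode is optional), both per sample then
averaged and pooled.

Set tests: hypergeometric overlap is the upper tail P(X ≥ k); the Fisher
2×2 p sums point probabilities ≤ the observed table's over fixed margins
(the conventional two-sided rule, stated because several conventions
exist); the KS comparison is the two-sample sup-norm statistic with the
asymptotic p. Gene-set enrichment applies the hypergeometric test per
category with optional BH adjustment. The universe for all association
tests is the expressed universe — genes with non-zero total RNA count —
configurable in the pipeline.

## The synthetic-data generator

The generator emulates the study design: two age groups × two hemispheres,
three marks + input with 2 ChIP replicates, RNA with 3 replicates. Genes
(default 500, lengths 1–5 kb) are packed uniformly without overlap on two
20 Mb chromosomes. RNA counts are NB(μ = 100, φ = 0.05); 10% of genes,
drawn preferentially (weight 5) from a designated inflammation set (10% of
genes), are planted up-regulated at log2 fold change 2 in ipsi (only
up-regulation by default, matching the asymmetry such injuries show;
down-regulation is a config option). Baseline promoter-mark occupancy is
mark-specific — H3K4me3 0.55, H3K9ac 0.35, H3K27me3 0.15 — mirroring the
usual TSS occupancy ranking. Mark gains/losses are planted on true DEGs in
configured proportions, in two modes: presence (peak exists only in the
gaining condition — the pDMG signal) or density (peak everywhere, read
rate ×4 in the gaining condition — the rDMG signal). One peak geometry per
(gene, mark) is reused across conditions and replicates, so replicates and
unchanged hemispheres differ only by Poisson read noise; per-peak reads
are Poisson with mean proportional to the peak's fold enrichment
(promoter peaks draw fold from U(4.5, 12)); background peaks are scattered
at 3/Mb with fold U(1, 8) so the >4 filter removes about half; input reads
are Poisson(10) per peak region. Mark changes are planted only at genes
whose TSS is ≥ 8 kb from every other TSS, so a planted presence/absence
event can neither be masked by nor bleed into a neighboring promoter
window — that makes exact recovery a well-defined contract.

What the generator does **not** emulate: fragment-length/shift structure,
mappability and copy-number artifacts, GC bias, peak-width heterogeneity,
gene-specific expression baselines, tagwise dispersion, or correlated
replicates. Passing recovery tests therefore demonstrates correctness of
the inference logic under the stated noise models, not performance on
real libraries, where dispersion varies by gene and input is structured.

Every output is a pure function of (config, seed): each stage derives its
generator from the seed and a fixed stage tag. Truth files are exported
separately and never read by inference code, whose interfaces accept only
annotation, peaks, reads and counts.

## Numerical and design choices

- Two-sided exact p-values sum point probabilities ≤ observed with a
  1 + 10⁻⁹ relative tolerance on the comparison, guarding against ties
  lost to floating-point rounding.
- Zero-variance t-test inputs: p = 1 when both sides are constant and
  equal, p = 0 when constant and different; scipy's NaN is mapped to 1.
- An all-zero gene tests at p = 1 (no evidence), not an error.
- The DEG rule is a strict conjunction; direction "up" means higher in
  the second (ipsi) group.
- Problem sizes in tests and the acceptance script (≤ 1,000 genes,
  ≤ 5,000 null peaks, two 20 Mb chromosomes) were chosen as the smallest
  at which the planted effects are comfortably identifiable under the
  stated noise models; all scale linearly if raised.

## Known limitations

- The exact conditional NB test with rescaled counts is approximate under
  strongly unequal library sizes; a quantile-matching adjustment would be
  the next refinement.
- Common dispersion only; genes with atypical variability are mis-weighted
  (the production-scale alternative is tagwise dispersion shrinkage).
- With two ChIP replicates per side the rDMG t-test has df = 2 and low
  power; the planted-recovery benchmarks use fold-4 density changes, which
  such a test detects reliably, but subtler shifts will be missed.
- pDMG presence/absence is undefined for promoters shared between close
  genes; the generator avoids planting there, real data cannot.
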