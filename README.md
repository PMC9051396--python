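# dmgcall

Integrative analysis of transcriptome change and promoter histone-mark
redistribution in a paired two-condition design — the kind of experiment
where the injured (ipsilateral) and control (contralateral) hemisphere of
the same brain are profiled by RNA-seq and by ChIP-seq of promoter histone
marks (H3K4me3, H3K27me3, H3K9ac) plus input chromatin, in two age groups.

`dmgcall` is for computational biologists who have gene annotation, called
peaks (narrowPeak), read positions and RNA count matrices in hand and want
to answer: which genes changed expression, do they cluster along the
genome, which promoters gained or lost a histone mark, and are the two
phenomena statistically associated?

## What it computes

- **DEGs** — for each gene, a two-sided exact conditional test under a
  common-dispersion negative binomial model, conditioning on the gene's
  total count (the group split is beta-binomial with weights $n_g/\phi$;
  the $\phi \to 0$ limit is the conditional binomial test). A gene is a DEG
  when $p < 0.01$ and the fold change of size-factor-normalized means is
  $\geq 2$.
- **Genomic-locus clustering** — per chromosome, the average distance
  $AD = L_{\text{chrom}} / n_{\text{DEG}}$ sets a gap threshold; adjacent
  DEGs with distance $< AD$ join one cluster.
- **pDMGs** (presence/absence) — peaks with fold enrichment $> 4$ are
  candidates; a gene is mark-positive when a candidate peak overlaps its
  $\pm 5$ kb TSS window; genes positive in exactly one hemisphere are
  pDMGs (gained / lost).
- **rDMGs** (quantitative) — peaks merged across samples wherever they
  overlap; density = reads per merged peak, normalized per million mapped
  reads and per kb; replicate densities minus the input density feed a
  two-sided equal-variance t-test on log enrichment ($p < 0.05$); genes
  with a significant peak within $\pm 3$ kb of the TSS are rDMGs.
- **TSS metaprofiles** and the percentage of peaks within $\pm 2.5$ kb of
  a TSS.
- **Set statistics** — hypergeometric Venn overlap $P(X \geq k)$, two-sided
  Fisher exact association of DEG status with dual-mark change, upset
  (exclusive-intersection) counts, KS profile comparison, and gene-set
  enrichment over user-supplied categories.
- **Synthetic experiments** — a seeded generator that plants known DEGs
  and promoter-mark gains/losses (concentrated on a designated
  inflammation gene set) so every stage can be scored against ground truth.

## Worked example

Run the whole pipeline on a synthetic experiment (500 genes, two age
groups, 10% planted up-regulated DEGs, planted promoter gains/losses):

```sh
dmgcall run --seed 9 --outdir out/
```

Among the report tables this writes, `pdmg_counts.tsv` holds the per-mark
presence/absence calls:

```
    mark age_group  gained  lost  shared
 H3K4me3       13m      24     8     266
H3K27me3       13m      12    27      84
  H3K9ac       13m      24    10     177
...
```

and `association.tsv` links expression to chromatin (counts are genes in
the expressed universe; `deg_dual` = upregulated DEGs whose promoters
changed both marks):

```
age_group  mark_a   mark_b  deg_dual deg_only dual_only neither  fisher_p      dual_gain_percent
13m        H3K4me3  H3K9ac  14       36       0         450      1.61e-15      20.0
```

Read: of the 52 DEGs called in the 13-month group (50 planted), 14 carry
changes of both activating marks at their promoter, an association far
beyond chance (Fisher $p = 1.6\times10^{-15}$), and 20% of upregulated
DEGs gained both H3K4me3 and H3K9ac — the signature the generator planted.

Every stage is also available separately (`dmgcall simulate | deg |
cluster | pdmg | rdmg | profile | stats`) and as library functions.

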