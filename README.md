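# cageprom

Alternative transcription start site (TSS) usage analysis for time-course
CAGE data.

Acute physiological stress (e.g. intense exercise) reshapes the
transcriptome of human skeletal muscle not only by switching genes on and
off but by shifting *which promoter* of a gene is used.  CAGE (cap analysis
of gene expression) reads mark transcription start positions at single-base
resolution, so a paired time-course design — the same subjects sampled
before and 1, 3 and 6 h after the stimulus — can resolve both gene-level
induction and within-gene redistribution of transcription starts.
`cageprom` implements that analysis as a reusable, fully tested Python
library, together with a synthetic study generator with recorded ground
truth, so every stage can be validated without any external download.

## What it computes

- **TSS clusters** — stranded CAGE 5′-tag positions chained by
  single-linkage (gap ≤ 20 bp), quantified as counts and TPM, with the
  robust filter (TPM ≥ 1 *and* count ≥ 11 in the same sample) and
  sharp/broad shape descriptors (count mass center, interquantile width).
- **Annotation** — each robust cluster is assigned a gene by strict
  priority: TSS (±50 bp) > 5′UTR > 3′UTR > CDS > non-coding exon > intron >
  intergenic, strand-matched; putative novel TSSs can be verified against
  RNA-seq splice-junction/coverage evidence; clusters that never reach 10%
  of their gene's top cluster are flagged *minor*.
- **Differential expression** — paired per-time-point test vs baseline:
  median-of-ratios size factors, per-subject log2 ratios (pseudo-count 1),
  one-sample t statistic, thresholds |FC| > 1.25 and BH-adjusted p < 0.01.
- **Differential TSS usage (DTU)** — per-sample cluster-count vectors
  x ~ DM(π, γ) (Dirichlet-multinomial with proportion vector π and
  precision γ); likelihood-ratio test of one shared π against one π per
  condition, γ profiled out by maximum likelihood, LRT ~ χ²(K−1),
  BH-adjusted p < 0.05.
- **Individual promoter regions** — replicate open-chromatin peaks merged
  per assay, ATAC ∩ DNase, intervals < 71 bp apart joined; a TSS cluster
  within 200 bp of a consensus interval defines an *Open* promoter
  (clusters sharing an interval share the promoter, giving bidirectional
  promoters naturally); remaining clusters chain into *Closed200* /
  *Closed2000* pseudo-promoters by whether open chromatin lies within
  2000 bp; TFBS density profiles over ±2000 bp around each anchor.
- **TFBS enrichment** — per-PWM log2-odds cutoff calibrated so background
  hit frequency ≤ 1 site / 2000 bp; both-strand scanning with greedy
  non-overlap reduction; enrichment of DE promoters vs never-DE background
  promoters as a site-rate ratio (binomial test) and a promoter-hit odds
  ratio (Fisher exact test), each with the 99%-CI-adjusted fold enrichment
  FE_adj; enriched = FE_adj > 1.5 at FDR < 0.05.
- **CRC clustering** — promoter time courses rank-transformed within each
  subject (highest of 4 time points → 4, lowest → 1) and partitioned by a
  Chinese-restaurant-process (Dirichlet-process mixture) Gibbs sampler with
  conjugate Normal–Inverse-Gamma components; the maximum-posterior
  partition over 100 processes × 100 cycles is returned.
- **Isoform mapping** — canonical TSS (most expressed at baseline), removed
  alternative promoters (> 200 bp beyond the canonical promoter region),
  and genes whose promoters link to transcripts with ≥ 2 distinct start
  codons (alternative protein isoforms).

## Worked example

```bash
python examples/05_tfbs_enrichment.py
```

```
foreground (DE) promoters: 84, background (never-DE): 209
matrix_id tf_name  sites_fg  sites_bg   fe_site  fe_adj_site     fdr_site  enriched
M_STRESS1    STF1        32         6 12.694446     4.197224 2.588019e-11      True
M_STRESS2    STF2         3        10  0.714063     0.145642 1.000000e+00     False
 M_HOUSE1    HKF1         2         8  0.595052     0.093263 1.000000e+00     False
   M_MYO1    MYF1         2         9  0.528935     0.084770 1.000000e+00     False
 M_HOUSE2    HKF2         1        13  0.183093     0.019947 1.000000e+00     False
   M_MYO2    MYF2         0        10  0.000000     0.002724 1.000000e+00     False
```

The generator plants the `M_STRESS1` consensus upstream of the canonical
TSS of differentially expressed genes.  After the full pipeline (clustering
→ annotation → promoter construction → promoter-level DE), its binding
sites occur 12.7× more often per bp in DE promoters than in never-DE
background promoters; the conservative 99%-CI-adjusted enrichment is still
4.2 > 1.5 at FDR ≈ 3·10⁻¹¹, so it is the only matrix flagged enriched —
exactly the planted truth.  The other examples (`examples/01…07`) walk
through each capability the same way: build or load a small input, run the
stage, print what it computed.

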