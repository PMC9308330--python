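# Methods

This note documents the models and procedures implemented in `cageprom`,
the defaults chosen where the design was open, and what the synthetic
validation does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open on both strands, matching
BED; GTF's 1-based inclusive coordinates are converted at the single read
site.  A minus-strand TSS position is `end − 1` of the 5′-most exon.  One
annotation GTF is consumed; when UTR features are absent they are derived
as exonic sequence outside the CDS span (5′ vs 3′ by strand).  The TRANSFAC
reader implements the minimal dialect shared by public matrix files:
blocks delimited by `//`, `ID`/`AC`/`NA` header tags, and rows beginning
with two digits holding exactly four counts.

## TSS clustering

CAGE 5′ tags are chained per (chromosome, strand) by single linkage:
consecutive tag positions at most `max_gap` (default 20) bp apart join one
cluster.  Decomposition of composite peaks is intentionally out of scope —
gap chaining is deterministic and exactly checkable against a transitive-
closure oracle, and every downstream rule consumes only the cluster
abstraction.  TPM uses the per-sample total of the input tag table as the
library size.  Shape descriptors use the 0.25/0.75 count quantiles; a
cluster is "sharp" when the interquantile width is ≤ 10 bp.  These labels
describe promoter architecture (focused vs dispersed initiation) and feed
no downstream logic, so the boundary is a configurable descriptor only.

## Annotation

Classes are tested in strict priority order against the cluster's count
mass center, strand-matched: within ±50 bp (inclusive) of an annotated
transcript TSS → TSS; else inside a 5′UTR → UTR5; else 3′UTR; else CDS;
else an exon of a non-coding transcript; else inside a transcript span →
intron; else intergenic.  The mass center is the anchor for all distance
tests, consistent with the promoter module.  Novel-TSS verification
(splice donor within 2000 bp downstream with ≥ 5 junction reads and > 0
coverage over ≥ 80% of the intervening bases) uses in-package defaults;
they are deliberately conservative and configurable.

The 10% rule reads "minor" as *below 10% of the gene's top cluster at
every time point* (major if it ever reaches 10%); the stricter ∀-reading
is available via `mode="major_if_always"`.  Intron/intergenic clusters are
exempt from the cutoff.

## Differential expression

The paired contrast is implemented directly: median-of-ratios size
factors, per-subject statistic d_i = log2((n_{i,t}+1)/(n_{i,base}+1)) on
normalized counts, one-sample t-test on {d_i}, fold change 2^mean(d), BH
correction across units within each time point, flags at |FC| > 1.25 and
adjusted p < 0.01.  This replaces a negative-binomial GLM fit with a fully
specified, oracle-testable statistic; its validity is asserted by
calibration (type-I error within [0.03, 0.07] at nominal 0.05 on 2000
synthetic null genes) and power (sensitivity ≥ 0.9 for planted |FC| ≥ 2)
rather than numeric identity to any particular GLM implementation.
A unit with zero counts throughout a comparison is reported untested; a
zero-variance nonzero-mean contrast receives the smallest positive double
and a `degenerate` flag.  The early 2-minute sample, when generated, is
excluded from every differential stage by design flag.

## Differential TSS usage

For a gene with K ≥ 2 robust clusters, per-sample count vectors are
modelled as Dirichlet-multinomial DM(π, γ):

    log P(x | π, γ) = log n!/(∏ x_k!) + log Γ(γ) − log Γ(n+γ)
                      + Σ_k [log Γ(x_k + γπ_k) − log Γ(γπ_k)]

The test compares one shared π (null) against one π per condition
(alternative), with a single γ per model estimated by profile maximum
likelihood over log γ ∈ [log 0.01, log 10⁴] (bounded scalar search,
tolerance 1e-4 on log γ).  Given γ, π is maximized by a multiplicative
fixed-point ascent π_k ∝ π_k Σ_i [ψ(x_ik+γπ_k) − ψ(γπ_k)], stopping when
the log-likelihood improves by < 1e-8 (max 500 iterations); the iteration
is monitored and stops on any decrease.  LRT = 2(ℓ₁ − ℓ₀) (clamped at 0)
is referred to χ²(K−1); BH across genes per time point; flag at adjusted
p < 0.05.  No precision moderation across genes is applied.  Correctness
anchors: the K = 2 pmf equals the closed-form beta-binomial to 1e-10; the
γ → ∞ limit approaches the multinomial; π recovery bias < 0.02; empirical
type-I error within [0.02, 0.08] on 500 null genes.

## Promoter regions

Within each assay replicate peaks are unioned; the two assay tracks are
intersected; consensus intervals separated by < 71 bp (less than half a
nucleosome's wrapped DNA) are joined — the 71 bp boundary is exclusive,
the 200 bp cluster-to-interval distance inclusive, and distances between
half-open intervals count touching as 0.  Clusters not assigned to an open
interval chain at ≤ 200 bp into pseudo-promoters; the group is Closed200
if any consensus interval lies within 2000 bp of its anchor, else
Closed2000.  The anchor is the mass center of the member with the highest
baseline mean TPM (ties: 5′-most on the member's strand).  A promoter is
bidirectional when it holds members on both strands; same-strand
multi-gene promoters are visible through the member table instead.
Promoter expression is the per-sample sum over members, tested for
differential expression exactly as genes are.

## TFBS enrichment

Weights are log2-odds with pseudocount 1: w(b,j) = log2((c(b,j) +
bg_b)/(N_j + 1)/bg_b), uniform background by default.  The per-matrix
cutoff is the smallest score whose both-strand background hit frequency is
≤ 1 per 2000 bp, calibrated on the background *promoter* set (the same
null the enrichment is scored against); if even the maximum attainable
score is too frequent the maximum is used with a warning.  Scanning
reports every window at or above the cutoff on both strands; windows
containing N score −∞; overlapping same-strand hits are reduced greedily
to the best-scoring non-overlapping set (ties leftmost) so that
low-complexity matrices cannot inflate site counts.

Enrichment of foreground vs background promoters is scored two ways:
FE_site = (sites_fg/bp_fg)/(sites_bg/bp_bg) with a one-sided binomial test
of the site allocation, and FE_seq = the odds ratio of the promoter-hit
2×2 table with a one-sided Fisher exact test.  The adjusted fold
enrichment is the lower bound of the two-sided 99% CI of the log ratio:
FE_adj = exp(ln FE − z₉₉·SE) with z₉₉ = 2.5758, SE from 1/(count+½) terms
(Haldane ½ corrections replace a zero or infinite point estimate).  A
matrix is enriched when either statistic shows FE_adj > 1.5 at its own
BH FDR < 0.05; per factor the matrix with the highest FE_adj (max of the
two statistics) is kept.  The background set is the promoters never
differentially expressed (adjusted p > 0.4 at every time point), capped at
5000.

## CRC clustering

Each promoter's T = 4 time-point values are replaced, within each subject,
by ranks 1..T (average ranks on ties), giving a promoters × (subjects·T)
matrix.  Components are independent Gaussians per dimension with a
conjugate Normal–Inverse-Gamma prior (μ₀ = rank-scale midpoint, κ₀ = 1,
a₀ = 2, b₀ = 1), so cluster marginal likelihoods are closed-form and a
collapsed Gibbs sampler reassigns each promoter proportionally to
size × posterior predictive (or α × prior predictive for a new cluster,
α = 1).  Each process initializes by a sequential CRP draw and runs
`n_cycles` sweeps; the partition with the highest log marginal posterior
(CRP prior × marginal likelihood) over every sampled state of every
process is returned.  Inverted profiles are not merged.  Production
defaults are 100 processes × 100 cycles; the tests and the acceptance
script use 5–10 processes × 30–50 cycles, which already recover planted
noiseless partitions exactly.

## Synthetic study generator

The generator emulates the study design at desk scale: 10 subjects × 4
time points (pre, 1 h, 3 h, 6 h; an optional 2-min point can be generated
but is never tested), ~200,000 tags per library, genes laid out one per
12 kb slot (so planted Closed2000 promoters cannot be contaminated by a
neighbour's peaks), 1–3 TSSs per gene spaced 2.2 kb apart, each with its
own transcript; a configurable subset of multi-TSS coding genes carries
distinct start codons per promoter, the rest share one.  Counts are
negative binomial (gamma-Poisson, dispersion 0.1 shared across clusters)
with mean library × gene abundance × TSS proportion × subject effect ×
fold change; the subject effect is a log-normal (σ = 0.4) gene-by-subject
factor constant over time, which is exactly the pairing signal the paired
test exploits.  DE genes (10%) multiply abundance by 2^±U(1,2) at every
post-stress time point; DTU genes (10%) reverse their TSS proportion
vector.  Tags spread geometrically (sharp) or uniformly over 30–80 bp
(broad) around each TSS.  Open TSSs get replicated ~800 bp peaks whose
center is shifted 150 bp upstream (strand-aware, ±50 bp replicate jitter);
Closed200 genes get peaks only in the 0.7–1.3 kb upstream band; Closed2000
genes get none.  ChIP-like sites mix a TSS-proximal Gaussian component
(mean −150 bp, sd 300 bp, weight 0.7) with uniform background.  The
consensus of one built-in PWM is written into the canonical promoter
window of DE genes at rate 0.8.

All outputs are byte-identically regenerable from (config, seed).  What
the generator does *not* emulate: mapping artifacts, sequence-composition
bias, rRNA/mitochondrial contamination, correlated peak noise, TSS
decomposition within composite peaks, and genes sharing regulatory space.
Passing recovery tests therefore demonstrates the correctness of the
implemented rules and the calibration of the statistics under the stated
model — not performance on real libraries.

## Problem sizes and numerical choices

The end-to-end validation runs 500 genes × 10 subjects × 4 time points;
calibration simulations use 2000 (DE) and 500 (DTU) null units, power 200
planted genes, motif recovery 200 + 500 promoters over 10–20 seeds, CRC
recovery 100 promoters over 5 seeds.  Degenerate inputs are defined
throughout: empty tag tables cluster to empty output, zero-count clusters
are a shape-metrics error, all-zero units are untested (never p-hacked to
0 or 1), infinite fold enrichments are reported as such with ½-corrected
CIs, and a single promoter clusters to a single cluster with finite
posterior.

## Known limitations

- The gap-based clustering does not split composite promoters; closely
  spaced alternative TSSs (< 20 bp) merge into one cluster.
- The DE statistic assumes approximately symmetric log-ratios; heavy
  zero-inflation at very low counts would distort its calibration.
- The DTU χ²(K−1) reference is asymptotic; with very few samples or very
  small totals the test becomes conservative/anticonservative — the
  calibration band is asserted only at the simulated design size.
- FE_adj is a conservative CI bound, not an unbiased effect estimate; it
  under-reports enrichment for sparse matrices by construction.
- The CRC sampler returns a MAP partition, not a consensus over the
  posterior; label-switching across processes is resolved by size-ordered
  relabelling only.
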