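# Methods

`meripqc` assesses the quality of MeRIP-seq / m6A-seq experiments from
aligned reads (BAM) and a transcriptome annotation (GTF).  An m6A-seq
experiment pairs an antibody-enriched IP library with a non-enriched
Input control; technically it behaves like a hybrid of ChIP-seq and
RNA-seq, so the package combines read-distribution diagnostics
(RNA-seq-style) with immunoprecipitation-efficiency metrics
(ChIP-seq-style signal extraction scaling adapted to the exome).

## Coordinate model

Genes are collapsed to **union-exon models**: the exons of all isoforms
of a gene are merged into disjoint intervals, which define an mRNA
coordinate system running 5'→3' (transcript position 0 is the rightmost
genomic exon base on the minus strand).  The union CDS footprint
segments the mRNA into 5'UTR / CDS / 3'UTR; noncoding genes are kept for
exon/intron accounting but excluded from sub-region percentages and the
metagene.  Union models avoid double-counting reads shared between
isoforms; no isoform quantification is attempted.  Internally all
coordinates are 0-based half-open; GTF input is 1-based closed.  A
strand of `.` is treated as `+`.

Each mRNA is tiled with fixed-width bins (default **200 nt**,
configurable), the unit of every count-based metric.  A trailing
remainder of at least a quarter bin is kept as a short final bin,
otherwise it is merged into the previous bin; genes shorter than one bin
form a single bin.

## Read counting

Primary, mapped alignments are assigned by the **midpoint of the aligned
genomic span** (for properly paired reads, the midpoint of the template
span, counted once per fragment).  The midpoint falls in exactly one of:
union exon (incrementing one bin and, for coding genes, one of
5'UTR/CDS/3'UTR), gene body outside exons (intron), or nongenic space.
This keeps all counters additive: bin counts per gene sum exactly to the
gene's exonic reads.  Duplicates are retained on purpose — the
coverage-class histogram is designed to reveal PCR artifacts.  No MAPQ
cut is applied by default (configurable); assignment is unstranded
because MeRIP library strandedness varies.

**Down-sampling** to a common depth makes samples comparable: at
counting time, exactly `down_to` reads are kept by seeded uniform
sampling without replacement; on an existing count vector, the finest
stored partition (all bins + intron + nongenic) is thinned with a
multivariate hypergeometric draw, and the UTR5/CDS/UTR3 triple is then
thinned to the retained coding-exon total.  Because the bin×sub-region
joint distribution is not stored, the sub-region thinning is marginally
(not jointly) consistent with uniform read removal; all thinned
invariants (non-negativity, additivity) hold exactly.

## Read-distribution statistics

* **Region table** — counts and percentages per sample: exon, intron and
  nongenic reads as a share of the total; 5'UTR/CDS/3'UTR reads as a
  share of their own sum (the mRNA sub-region convention).
* **Coverage-class histogram** — every exonic bin classified by read
  count into `[0]`, `[1,10]`, `(10,10^2]`, …, `(10^5, ∞)`; a fat upper
  tail at matched depth indicates coverage heterogeneity, typically PCR
  jackpots.
* **Metagene profile** — coding genes with ≥ 10 exonic reads contribute
  equally: per-nt coverage (piecewise constant over bins) is divided by
  its mRNA-wide mean, each region is rescaled to 100 grid points by
  linear interpolation, and the 25/50/75% quantiles across genes are
  reported per grid point (quantiles use linear interpolation between
  order statistics).  m6A appears as a peak at the CDS/3'UTR boundary.
  Genes lacking an annotated UTR are excluded (their regions cannot be
  rescaled).  Median region lengths are recorded for proportional axis
  display.

## ESES (exome signal extraction scaling)

For gene *g* and bin *i*, with IP and Input bin counts *y*ₜ,g,i and
*y*꜀,g,i, expression is normalized out by dividing by per-gene bin
means:

    ŷₜ,g,i = yₜ,g,i / ȳₜ,g      ŷ꜀,g,i = y꜀,g,i / ȳ꜀,g

Genes with fewer than 10 exonic reads in the IP **or** the merged Input
are excluded (the Input-side filter also guarantees a nonzero
denominator; the mean of ŷ over each retained gene's bins is exactly 1).
All ŷₜ are pooled and sorted ascending (ties broken by (gene id, bin
index) for determinism), ŷ꜀ is reordered by the same permutation, and
cumulative fraction curves are formed:

    p_j = Σ_{i≤j} ŷₜ,(i) / Σ ŷₜ      q_j = Σ_{i≤j} ŷ꜀,(i) / Σ ŷ꜀

The background cut is k = argmax_j |q_j − p_j| (the **largest** index on
ties, so an IP identical to its Input yields zero enriched fraction).
Reported metrics:

* **scale factor** = max_j |q_j − p_j|;
* **enriched region** = (N − k)/N, the fraction of bins past the cut;
* **signal reads** = 1 − p_k, the share of cumulated normalized IP
  signal in the enriched bins.

The enriched fraction is (N − k)/N, matching the definition of the
first k bins as background; the signal-read fraction is computed on the
normalized signal scale.

## C-test enrichment profile

The C-test is the exact conditional comparison of two Poisson means:
under H₀: λ_IP ≤ c·d·λ_Input (c the fold threshold, d the IP/Input
total-read ratio), conditional on T = x_IP + x_Input,
x_IP ~ Binomial(T, π₀) with π₀ = c·d/(1 + c·d), and the one-sided
p-value is the exact upper binomial tail (scipy's `binom.sf`).  Only
bins with more than 10 combined reads are tested.  The profile reports
the fraction of tested bins with p < α (default α = 0.05, one-sided)
over the fold grid (1, 1.5, 2, 2.5, 3, 3.5, 4); it is nonincreasing in
c by construction.  No multiplicity correction is applied — the profile
is a QC summary, not a peak list.

## Multi-sample comparison

Per-sample **size factors** s_j = y_j / exp(mean log y) (y_j the bin
total) remove depth differences; every normalized sample then sums to
the geometric mean of the raw totals.  Bins with zero counts in all
samples are dropped (they carry no information and destabilize
distances).  Samples are compared by:

* **hierarchical clustering** — complete linkage on Euclidean distances
  between normalized bin-count columns (linkage stated explicitly for
  reproducibility); exported as Newick and dendrogram;
* **PCA** — samples as observations, column-centered, not
  variance-scaled; explained-variance fractions sum to 1.  Identical
  samples give zero total variance and are flagged degenerate rather
  than crashing;
* **gene-specific heterogeneity** — per-gene mean and SD (ddof = 1) of
  bin counts per sample; enrichment signal and PCR artifacts raise the
  SD at a given mean, so IP curves sit above Input curves;
* **replicate consistency** — per-bin cross-replicate mean μ_i and SD
  s_i (divisor √(J−1)) of normalized counts within a replicate group.

Mean–SD relationships are summarized by a tri-cube-weighted local
*linear* regression (statsmodels lowess, span 0.75 — the classic
default, since no smoothing parameter is standard for this diagnostic),
evaluated on a 100-point grid over the observed range; a zero-width
range falls back to a constant fit.

## Quality verdicts

ESES metrics of each IP sample are compared against good-quality
reference ranges compiled from a survey of 61 published m6A-seq IP
samples: enriched region 12–25%, scale factor 0.08–0.30, signal reads
87–95%.  Intervals are closed (boundary values count as within); a
sample is flagged when any metric falls outside.  The ranges are
packaged constants and user-overridable — other modifications
(e.g. m1A) legitimately fall outside the m6A ranges.

## Synthetic data generator

The generator emits a toy transcriptome (GTF) and aligned reads
(sorted, indexed BAM) with full ground truth, emulating the m6A data
model:

* 50 genes by default on one chromosome, 1–3 exons each, UTR5/CDS/UTR3
  lengths uniform in 150–350 / 1800–3600 / 600–1400 nt (≈ 4 kb mRNAs,
  ~20 bins per gene at the default bin width);
* log-normal(σ = 1) gene abundances (expression heterogeneity);
* Input reads multinomial over bins ∝ abundance × bin length; 5% of
  reads intronic, 45% nongenic (matching the proportions observed in
  published IP/Input libraries);
* every gene carries stop-codon-proximal methylation — the typical m6A
  regime in which most expressed transcripts are methylated: the bin
  containing the stop codon is always methylated, and additional peaks
  (set per gene so the overall methylated-bin fraction matches
  `peak_fraction`, default 0.1) fall within ±2 bins of it with
  probability decaying away from the boundary.  IP reads multiply
  methylated-bin weights by `peak_fold` (default 8);
* artifact modes: `pcr_dup` (a ~1% seed subset of reads amplified with
  geometric copy numbers until duplicates make up 30% of the library —
  the jackpot pattern PCR produces), `three_prime_bias` (within-gene
  weights tilted by exp(1.5·relative position)), `swap` (IP/Input roles
  exchanged);
* reads are single-end, 50 nt, ungapped, MAPQ 60 — the simplest profile
  the midpoint counting rule needs; everything is deterministic per
  seed.

`simulate_counts` draws bin/region counts directly from the same
multinomial model without materializing reads; it is distributionally
identical to counting a simulated BAM and is used where only counts
matter.  The default fixture set (11 samples × 15k reads: clean
3×IP/3×Input, an Input-distributed outlier labelled IP, a swapped pair,
and PCR-duplication and 3'-bias twins of IP1) shares one transcriptome.

**What the generator does not emulate.**  Coverage is uniform within
bins; there are no splice-junction reads, sequencing errors, quality
scores, fragment-length variation, or annotation errors.  The toy
model compresses the dynamic range of real IP libraries: clean
synthetic samples land inside the published enriched-region range but
above/below the scale-factor and signal-read ranges, so passing tests
demonstrate the correctness of the computations and the direction of
every artifact contrast — not that the generator reproduces the
published metric distributions of real data.

## Test problem sizes

The enriched-fraction recovery experiment runs at 15 genes, depth 100k
and fold 8.  The background cut is identifiable only when the
background normalized level B/(B − n + fold·n) (B bins per gene, n
peaks) is separated from 1 by ≳ 3.5 per-bin Poisson standard
deviations; at a 5% planted fraction this requires ≥ 1 peak in every
gene and ≳ 100 background reads per bin, which fixes the gene count at
that depth.  The 50-gene default fixture set is deliberately more
heterogeneous and is used for exactness, contrast and end-to-end
checks, not for recovering small planted fractions.

## Known limitations

* Overlapping genes are resolved to the lexicographically smallest gene
  id — adequate for the synthetic transcriptome, crude for dense real
  annotations.
* rRNA is not treated specially; heavily rRNA-contaminated libraries
  will dominate the metrics.
* The metagene requires annotated UTRs; genes without them are skipped.
* The enriched-fraction estimator carries a small positive bias when
  per-bin coverage is low (the background noise tail crosses the Input
  level); down-sample comparisons to a common, adequate depth.
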