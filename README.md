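# meripqc

Quality assessment of **MeRIP-seq / m6A-seq** data.

MeRIP-seq (m6A-seq) profiles transcriptome-wide RNA N6-methyladenosine
by immunoprecipitating methylated RNA fragments (the IP library)
alongside a non-enriched Input control.  The technique is fragile —
antibody pull-down can fail, libraries can suffer PCR jackpots, 3' bias
or outright sample swaps — and generic read-level QC tools cannot see
these problems because they are only visible *relative to the
transcriptome and the matched control*.  `meripqc` takes coordinate-
sorted, indexed BAM files plus a GTF annotation and produces an HTML
quality report (with a JSON summary and TSV tables) for analysts
deciding whether an m6A-seq dataset is fit for peak calling and
downstream epitranscriptome analysis.

## What it computes

Reads are assigned by their aligned-span midpoint to union-exon gene
models tiled with fixed-width bins (default 200 nt).

**Read distribution** — reads per region (exon/intron/nongenic and
5'UTR/CDS/3'UTR), a coverage-class histogram of exonic bins (reveals
PCR artifacts at matched depth), and a quantile metagene profile of
mean-standardized coverage over length-normalized 5'UTR–CDS–3'UTR
coordinates (m6A shows a stop-codon peak).

**Immunoprecipitation efficiency (ESES, exome signal extraction
scaling)** — per gene g and bin i, IP and Input counts are normalized
by per-gene means, ŷ = y_{g,i}/ȳ_g, removing expression differences.
Pooling and sorting the IP signal ascending with the Input signal
reordered to match, the cumulative fraction curves
p_j = Σ_{i≤j} ŷ_t,(i)/Σŷ_t and q_j = Σ_{i≤j} ŷ_c,(i)/Σŷ_c define the
background cut k = argmax_j |q_j − p_j|, and the headline metrics

* scale factor = max_j |q_j − p_j|,
* enriched region = (N − k)/N,
* signal reads = 1 − p_k,

which are compared against good-quality reference ranges from a survey
of 61 published m6A-seq IP samples (enriched region 12–25%, scale
factor 0.08–0.30, signal reads 87–95%).

**C-test profile** — the exact conditional test of two Poisson means
(x_IP ~ Binomial(T, c·d/(1+c·d)) given T = x_IP + x_Input): the
fraction of well-covered bins significantly enriched at each fold
threshold c.

**Multi-sample comparison** — size-factor normalization
(s_j = y_j / geometric mean of totals), complete-linkage hierarchical
clustering and PCA of samples, per-gene mean–SD heterogeneity curves,
and cross-replicate consistency curves (μ_i, s_i per bin), each
summarized with a lowess fit.

A bundled simulator (`meripqc.simulate`) generates toy GTF + BAM
fixtures with planted stop-codon-proximal enrichment, expression
heterogeneity and artifact modes (PCR duplication, 3' bias, sample
swap), with full ground truth — so the whole suite is testable without
downloading data.

## Worked example

Simulate a small dataset and assess it:

```
$ meripqc simulate --out fix --seed 1 --depth 8000 --n-genes 20
$ meripqc eses --gtf fix/annotation.gtf \
    --ip fix/IP1.bam --ip fix/IP2.bam \
    --input fix/Input1.bam --input fix/Input2.bam
sample  enriched_region_pct     scale_factor    signal_read_pct verdict
IP1     15.27   0.3950  55.07   flagged
IP2     18.83   0.4056  59.63   flagged
$ meripqc run --gtf fix/annotation.gtf --ip fix/IP1.bam --ip fix/IP2.bam \
    --input fix/Input1.bam --input fix/Input2.bam --out report
```

Reading the numbers: about 15–19% of analyzed bins sit past the ESES
background cut (the planted ~10% of methylated bins plus low-coverage
smearing at this shallow depth), carrying ~55–60% of the cumulated
normalized IP signal; the largest IP/Input cumulative gap (scale
factor) is ~0.40.  The enriched region falls inside the published
good-quality range, while the toy generator's compressed dynamic range
puts scale factor and signal reads outside theirs, so the samples are
`flagged` — on real data these verdicts separate working IPs from
failed or swapped libraries.  `report/report.html` contains all
tables, figures and verdicts; `report/summary.json` holds every number
in machine-readable form.

The same analyses are available as library calls (`load_annotation`,
`count_sample`, `compute_eses`, `ctest_profile`, `normalize_matrix`,
…) operating on plain dataclasses and numpy arrays.

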