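"""Read-distribution statistics.

Three sample-level views of where reads land on the transcriptome:

* region statistics — counts and percentages over exon / intron /
  nongenic space, with the mRNA sub-regions (5'UTR, CDS, 3'UTR)
  expressed as percentages of the mRNA sub-region sum;
* a coverage-class histogram — the fraction of exonic bins covered by
  0, 1–10, 10–10^2, ... reads, which exposes coverage heterogeneity and
  PCR artifacts (best compared after down-sampling to a common depth);
* a quantile metagene profile — per-gene mean-standardized coverage
  over length-normalized 5'UTR/CDS/3'UTR coordinates, summarized by the
  25/50/75% quantiles across genes.  m6A enrichment appears as a peak
  near the CDS/3'UTR boundary (the stop codon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import GeneModel
from .counting import SampleCounts
from .errors import EmptySampleError, FilterError

__all__ = [
    "RegionStatsRow",
    "CoverageHistogramRow",
    "MetageneProfile",
    "COVERAGE_CLASSES",
    "region_stats",
    "coverage_histogram",
    "metagene",
]


@dataclass
class RegionStatsRow:
    sample_id: str
    total: int
    counts: dict[str, int]       # exon/intron/nongenic/utr5/cds/utr3
    percents: dict[str, float]   # same keys; see module docstring for denominators


def region_stats(counts: SampleCounts) -> RegionStatsRow:
    """Region counts with the two percentage conventions: exon/intron/
    nongenic over the total; UTR5/CDS/UTR3 over their own sum."""
    if counts.total_reads == 0:
        raise EmptySampleError(f"{counts.sample_id}: no reads counted")
    rc = counts.region_counts
    total = counts.total_reads
    sub_total = rc["utr5"] + rc["cds"] + rc["utr3"]
    pct = {}
    for r in ("exon", "intron", "nongenic"):
        pct[r] = 100.0 * rc[r] / total
    for r in ("utr5", "cds", "utr3"):
        pct[r] = 100.0 * rc[r] / sub_total if sub_total > 0 else float("nan")
    return RegionStatsRow(
        sample_id=counts.sample_id, total=total, counts=dict(rc), percents=pct
    )


COVERAGE_CLASSES = (
    "0",
    "1-10",
    "10^1-10^2",
    "10^2-10^3",
    "10^3-10^4",
    "10^4-10^5",
    ">10^5",
)


@dataclass
class CoverageHistogramRow:
    sample_id: str
    class_fractions: dict[str, float]
    n_bins: int


def coverage_histogram(counts: SampleCounts) -> CoverageHistogramRow:
    """Classify every exonic bin by its read count into decade classes
    [0], [1,10], (10,10^2], ..., (10^5, inf) and report bin fractions.

    Comparable across samples only at a common depth; down-sample first.
    """
    c = counts.bin_counts
    n = len(c)
    frac = {
        "0": np.count_nonzero(c == 0),
        "1-10": np.count_nonzero((c >= 1) & (c <= 10)),
        "10^1-10^2": np.count_nonzero((c > 10) & (c <= 100)),
        "10^2-10^3": np.count_nonzero((c > 100) & (c <= 1000)),
        "10^3-10^4": np.count_nonzero((c > 1000) & (c <= 10_000)),
        "10^4-10^5": np.count_nonzero((c > 10_000) & (c <= 100_000)),
        ">10^5": np.count_nonzero(c > 100_000),
    }
    return CoverageHistogramRow(
        sample_id=counts.sample_id,
        class_fractions={k: v / n for k, v in frac.items()},
        n_bins=n,
    )


@dataclass
class MetageneProfile:
    """Quantile metagene over a 300-point grid (100 per region,
    5'UTR -> CDS -> 3'UTR)."""

    sample_id: str
    positions: np.ndarray                     # 0..299
    quantile_curves: dict[int, np.ndarray]    # {25, 50, 75} -> 300-vector
    n_genes_used: int
    region_median_lengths: dict[str, float]   # for proportional axis display


def metagene(
    counts: SampleCounts,
    models: list[GeneModel],
    *,
    min_gene_reads: int = 10,
    grid_per_region: int = 100,
) -> MetageneProfile:
    """Quantile metagene profile of standardized coverage.

    Coding genes with >= ``min_gene_reads`` exonic reads (and all three
    regions annotated) contribute equally: per-nt coverage (piecewise
    constant over bins) is divided by its mean over the mRNA, each
    region is rescaled to ``grid_per_region`` points by linear
    interpolation, and the 25/50/75% quantiles across genes are taken at
    each grid point.
    """
    bin_index = counts.bin_index
    rows = []
    lengths = {"utr5": [], "cds": [], "utr3": []}
    for model in models:
        if not model.coding:
            continue
        spans = {
            "utr5": model.utr5_span,
            "cds": model.cds_span,
            "utr3": model.utr3_span,
        }
        if any(b - a < 1 for a, b in spans.values()):
            continue
        gene_bins = counts.gene_bin_counts(model.gene_id)
        if gene_bins.sum() < min_gene_reads:
            continue
        # piecewise-constant per-nt coverage from bin counts
        off, n = bin_index.gene_offsets[model.gene_id]
        cov = np.empty(model.mrna_length, dtype=float)
        for i in range(n):
            b = bin_index.bins[off + i]
            cov[b.tx_start : b.tx_end] = gene_bins[i] / len(b)
        cov = cov / cov.mean()
        parts = []
        for region in ("utr5", "cds", "utr3"):
            a, b = spans[region]
            vals = cov[a:b]
            lengths[region].append(b - a)
            x = np.linspace(0, len(vals) - 1, grid_per_region)
            parts.append(np.interp(x, np.arange(len(vals)), vals))
        rows.append(np.concatenate(parts))
    if not rows:
        raise FilterError(
            f"{counts.sample_id}: no coding gene passes the "
            f">={min_gene_reads}-read metagene filter"
        )
    mat = np.vstack(rows)
    curves = {
        q: np.percentile(mat, q, axis=0, method="linear") for q in (25, 50, 75)
    }
    return MetageneProfile(
        sample_id=counts.sample_id,
        positions=np.arange(3 * grid_per_region),
        quantile_curves=curves,
        n_genes_used=len(rows),
        region_median_lengths={k: float(np.median(v)) for k, v in lengths.items()},
    )
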