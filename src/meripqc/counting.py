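"""Read counting: BAM alignments -> region and bin counts.

Each primary mapped alignment is located by the *midpoint* of its
aligned genomic span and assigned to exactly one category: exon (with a
5'UTR/CDS/3'UTR sub-region for coding genes and an mRNA bin), intron, or
nongenic.  The midpoint rule gives every read a unique bin, keeping the
region accounting additive.

Down-sampling to a common depth — either at counting time (uniform read
sampling without replacement) or on an existing count vector
(multivariate-hypergeometric thinning) — makes samples of different
sequencing depth comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pysam
from intervaltree import IntervalTree

from .annotation import BinIndex, GeneModel
from .errors import (
    ContigMismatchError,
    DepthError,
    MissingIndexError,
    RoleError,
    ShapeError,
)

__all__ = [
    "SampleCounts",
    "GenomeIndex",
    "count_sample",
    "downsample_counts",
    "merge_inputs",
]

REGIONS = ("exon", "intron", "nongenic", "utr5", "cds", "utr3")


@dataclass
class SampleCounts:
    """Per-sample read counters over genomic regions and mRNA bins."""

    sample_id: str
    role: str  # "IP" or "Input"
    total_reads: int
    region_counts: dict[str, int]
    bin_counts: np.ndarray  # int64 vector over BinIndex bins
    bin_index: BinIndex

    def gene_bin_counts(self, gene_id: str) -> np.ndarray:
        return self.bin_counts[self.bin_index.gene_slice(gene_id)]

    def validate(self) -> None:
        rc = self.region_counts
        assert rc["exon"] + rc["intron"] + rc["nongenic"] == self.total_reads
        assert rc["utr5"] + rc["cds"] + rc["utr3"] <= rc["exon"]
        assert int(self.bin_counts.sum()) == rc["exon"]
        assert (self.bin_counts >= 0).all()


class GenomeIndex:
    """Interval lookup structures for assigning read midpoints to genes.

    Overlapping genes are resolved deterministically in favour of the
    lexicographically smallest gene_id.
    """

    def __init__(self, models: list[GeneModel]):
        self.models = {m.gene_id: m for m in models}
        self.chroms = {m.chrom for m in models}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._body_trees: dict[str, IntervalTree] = {}
        for m in models:
            et = self._exon_trees.setdefault(m.chrom, IntervalTree())
            for a, b in m.exons:
                et[a:b] = m.gene_id
            bt = self._body_trees.setdefault(m.chrom, IntervalTree())
            s, e = m.span
            bt[s:e] = m.gene_id

    def locate(self, chrom: str, pos: int) -> tuple[str, str | None]:
        """Return (region, gene_id) for a genomic point: region is
        'exon', 'intron' or 'nongenic'."""
        et = self._exon_trees.get(chrom)
        if et is not None:
            hits = et[pos]
            if hits:
                gene = min(h.data for h in hits)
                return "exon", gene
            hits = self._body_trees[chrom][pos]
            if hits:
                return "intron", min(h.data for h in hits)
        return "nongenic", None


def _midpoints_from_bam(bam_path, mapq: int) -> tuple[list[tuple[str, int]], int]:
    """Collect (chrom, midpoint) for usable alignments; returns the list
    and the count of alignments seen (including those later filtered by
    chromosome checks downstream)."""
    bam = pysam.AlignmentFile(str(bam_path), "rb")
    try:
        if not bam.has_index():
            raise MissingIndexError(f"{bam_path}: BAM index (.bai) not found")
        out = []
        for read in bam.fetch():
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq:
                continue
            if read.is_paired and read.is_proper_pair:
                # count fragments once, via the template span midpoint
                if read.is_read2:
                    continue
                tlen = abs(read.template_length)
                if tlen > 0:
                    start = min(read.reference_start, read.next_reference_start)
                    mid = start + tlen // 2
                else:
                    mid = (read.reference_start + read.reference_end) // 2
            else:
                mid = (read.reference_start + read.reference_end) // 2
            out.append((read.reference_name, mid))
    finally:
        bam.close()
    return out, len(out)


def count_sample(
    bam_source,
    models: list[GeneModel] | GenomeIndex,
    bin_index: BinIndex,
    *,
    role: str = "IP",
    sample_id: str | None = None,
    down_to: int | None = None,
    seed: int | None = None,
    mapq: int = 0,
) -> SampleCounts:
    """Count a coordinate-sorted, indexed BAM into region and bin counters.

    Uses primary mapped alignments only (optionally MAPQ-filtered); each
    read contributes once, at the midpoint of its aligned span.  With
    ``down_to``, exactly that many reads are retained by seeded uniform
    sampling without replacement before assignment.
    """
    gidx = models if isinstance(models, GenomeIndex) else GenomeIndex(models)
    midpoints, _ = _midpoints_from_bam(bam_source, mapq)

    known = [(c, p) for c, p in midpoints if c in gidx.chroms]
    n_unknown = len(midpoints) - len(known)
    if midpoints and n_unknown > 0.5 * len(midpoints):
        raise ContigMismatchError(
            f"{n_unknown}/{len(midpoints)} reads map to chromosomes absent "
            f"from the annotation"
        )

    if down_to is not None:
        if down_to > len(known):
            raise DepthError(
                f"requested down_to={down_to} exceeds available reads={len(known)}"
            )
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(known), size=down_to, replace=False)
        known = [known[i] for i in sorted(keep)]

    region = {r: 0 for r in REGIONS}
    bins = np.zeros(bin_index.n_bins, dtype=np.int64)
    for chrom, mid in known:
        reg, gene = gidx.locate(chrom, mid)
        region[reg] += 1
        if reg == "exon":
            model = gidx.models[gene]
            tx = model.genome_to_tx(mid)
            bins[bin_index.bin_of(gene, tx)] += 1
            sub = model.subregion_of(tx)
            if sub is not None:
                region[sub] += 1

    sid = sample_id if sample_id is not None else str(bam_source)
    counts = SampleCounts(
        sample_id=sid,
        role=role,
        total_reads=len(known),
        region_counts=region,
        bin_counts=bins,
        bin_index=bin_index,
    )
    counts.validate()
    return counts


def downsample_counts(
    counts: SampleCounts, down_to: int, seed: int | None = None
) -> SampleCounts:
    """Thin an existing count vector to ``down_to`` total reads.

    Equivalent in distribution to removing reads uniformly at random:
    the finest stored partition (every bin, plus intron and nongenic) is
    thinned with a multivariate hypergeometric draw; the UTR5/CDS/UTR3
    triple is then thinned to the retained coding-exon total.
    Deterministic for a fixed seed.
    """
    if down_to > counts.total_reads:
        raise DepthError(
            f"requested down_to={down_to} exceeds total_reads={counts.total_reads}"
        )
    rng = np.random.default_rng(seed)
    rc = counts.region_counts
    colors = np.concatenate(
        [counts.bin_counts, [rc["intron"], rc["nongenic"]]]
    ).astype(np.int64)
    thinned = rng.multivariate_hypergeometric(colors, down_to)
    new_bins = np.asarray(thinned[:-2], dtype=np.int64)
    new_region = {r: 0 for r in REGIONS}
    new_region["intron"] = int(thinned[-2])
    new_region["nongenic"] = int(thinned[-1])
    new_region["exon"] = int(new_bins.sum())

    sub_total = rc["utr5"] + rc["cds"] + rc["utr3"]
    if sub_total > 0:
        # retained reads in bins of coding genes bound the subregion total
        noncoding_exon = rc["exon"] - sub_total
        # thin the (utr5, cds, utr3, noncoding-exon) partition to the new
        # exon total so the subregion invariant is preserved
        sub = rng.multivariate_hypergeometric(
            np.array([rc["utr5"], rc["cds"], rc["utr3"], noncoding_exon]),
            new_region["exon"],
        )
        new_region["utr5"], new_region["cds"], new_region["utr3"] = map(int, sub[:3])

    out = replace(
        counts,
        total_reads=int(down_to),
        region_counts=new_region,
        bin_counts=new_bins,
    )
    out.validate()
    return out


def merge_inputs(inputs: list[SampleCounts]) -> SampleCounts:
    """Element-wise sum of Input-role samples into one unified Input."""
    if not inputs:
        raise RoleError("no Input samples to merge")
    if any(c.role != "Input" for c in inputs):
        raise RoleError("merge_inputs requires Input-role samples only")
    first = inputs[0]
    for c in inputs[1:]:
        same_index = c.bin_index is first.bin_index or (
            c.bin_index.n_bins == first.bin_index.n_bins
            and c.bin_index.gene_offsets == first.bin_index.gene_offsets
        )
        if not same_index or c.bin_counts.shape != first.bin_counts.shape:
            raise ShapeError("mismatched bin index across Input samples")
    region = {r: sum(c.region_counts[r] for c in inputs) for r in REGIONS}
    bins = np.sum([c.bin_counts for c in inputs], axis=0).astype(np.int64)
    out = SampleCounts(
        sample_id="merged_input",
        role="Input",
        total_reads=sum(c.total_reads for c in inputs),
        region_counts=region,
        bin_counts=bins,
        bin_index=first.bin_index,
    )
    out.validate()
    return out
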