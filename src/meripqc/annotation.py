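"""Transcript annotation handling.

Builds one union-exon gene model per gene from a GTF file, segments the
mRNA into 5'UTR / CDS / 3'UTR in transcript coordinates, and tiles every
mRNA with fixed-width bins that can be projected back to the genome.

MeRIP-seq QC works on the exome: the annotation separates signal
(transcribed regions) from noise (introns, intergenic space), and the
bins defined here are the unit of every downstream count-based metric.

Coordinates are 0-based half-open internally; GTF input is read as
1-based closed.  Transcript position 0 is the 5' end of the mRNA, which
on the minus strand is the rightmost genomic exon base.
"""

from __future__ import annotations

import gzip
import io
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyAnnotationError, GTFParseError, MeripQCError

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Bin",
    "BinIndex",
    "load_annotation",
    "build_bins",
    "project_to_genome",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Union-exon model of one gene.

    ``exons`` are disjoint, sorted genomic intervals (the union over all
    isoforms).  The mRNA coordinate system runs 5'->3' over the
    concatenated exons; ``utr5_span``/``cds_span``/``utr3_span`` partition
    ``[0, mrna_length)`` when the gene is coding.  Noncoding genes keep
    ``cds_span`` equal to the whole mRNA and are flagged ``coding=False``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    mrna_length: int = field(init=False)
    utr5_span: tuple[int, int] = (0, 0)
    cds_span: tuple[int, int] = (0, 0)
    utr3_span: tuple[int, int] = (0, 0)
    coding: bool = False
    # cumulative exonic length before each exon, for coordinate mapping
    _cumlen: np.ndarray = field(init=False, repr=False)
    _starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        exons = sorted(self.exons)
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c < b:
                raise ValueError(f"{self.gene_id}: overlapping exons after union")
        self.exons = exons
        lengths = [b - a for a, b in exons]
        self.mrna_length = int(sum(lengths))
        self._cumlen = np.concatenate([[0], np.cumsum(lengths)])
        self._starts = np.array([a for a, _ in exons])
        if self.strand not in ("+", "-"):
            self.strand = "+"

    # -- coordinate mapping -------------------------------------------------

    def genome_to_tx(self, pos: int) -> int | None:
        """Transcript coordinate of a genomic position, or None if intronic
        or outside the gene."""
        i = bisect_right(self._starts, pos) - 1
        if i < 0:
            return None
        a, b = self.exons[i]
        if not (a <= pos < b):
            return None
        plus_tx = int(self._cumlen[i]) + (pos - a)
        if self.strand == "-":
            return self.mrna_length - 1 - plus_tx
        return plus_tx

    @property
    def span(self) -> tuple[int, int]:
        """Genomic gene-body span (first exon start to last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    def subregion_of(self, tx_pos: int) -> str | None:
        """'utr5' | 'cds' | 'utr3' for a transcript position of a coding
        gene; None for noncoding genes."""
        if not self.coding:
            return None
        if tx_pos < self.cds_span[0]:
            return "utr5"
        if tx_pos < self.cds_span[1]:
            return "cds"
        return "utr3"


def project_to_genome(
    model: GeneModel, tx_interval: tuple[int, int]
) -> list[GenomicInterval]:
    """Map a transcript-coordinate interval through the exon chain.

    Returns genomic intervals in ascending genomic order; their lengths
    sum to the input length.  Strand-aware: transcript position 0 is the
    5' end (rightmost exon base on the minus strand).
    """
    tx_start, tx_end = tx_interval
    L = model.mrna_length
    if not (0 <= tx_start < tx_end <= L):
        raise MeripQCError(
            f"{model.gene_id}: transcript interval [{tx_start},{tx_end}) "
            f"outside [0,{L})"
        )
    if model.strand == "-":
        ps, pe = L - tx_end, L - tx_start
    else:
        ps, pe = tx_start, tx_end
    out = []
    for (a, b), off in zip(model.exons, model._cumlen[:-1]):
        lo = max(ps, int(off))
        hi = min(pe, int(off) + (b - a))
        if lo < hi:
            out.append(
                GenomicInterval(model.chrom, a + lo - int(off), a + hi - int(off),
                                model.strand)
            )
    return out


# ---------------------------------------------------------------------------
# GTF parsing


_ATTR_RE = re.compile(r'(\w+)\s+"?([^";]+)"?\s*;?')


def _parse_attributes(field9: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _ATTR_RE.finditer(field9)}


def _open_maybe_gzip(source):
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw)), True
    return io.TextIOWrapper(raw), True


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def load_annotation(gtf_source) -> list[GeneModel]:
    """Parse a GTF (path or text stream, gzip tolerated) into union-exon
    gene models, one per gene_id, sorted by gene_id.

    Exon features define the mRNA; CDS features (optional) define the
    union CDS footprint, which is projected into transcript coordinates
    to segment the mRNA into 5'UTR / CDS / 3'UTR.  Genes with no CDS are
    retained as noncoding.
    """
    handle, close = _open_maybe_gzip(gtf_source)
    exons: dict[str, list[tuple[int, int]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene -> (chrom, strand)
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GTFParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            feature = fields[2]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                end = int(fields[4])
            except ValueError:
                raise GTFParseError(lineno, f"non-numeric coordinates {fields[3]!r}/{fields[4]!r}")
            if not (0 <= start < end):
                raise GTFParseError(lineno, f"invalid coordinates {fields[3]}-{fields[4]}")
            attrs = _parse_attributes(fields[8])
            gene = attrs.get("gene_id")
            if gene is None:
                raise GTFParseError(lineno, "missing gene_id attribute")
            chrom, strand = fields[0], fields[6]
            prev = meta.setdefault(gene, (chrom, strand))
            if prev[0] != chrom:
                raise GTFParseError(lineno, f"gene {gene} spans multiple chromosomes")
            (exons if feature == "exon" else cdss).setdefault(gene, []).append((start, end))
    finally:
        if close:
            handle.close()

    if not exons:
        raise EmptyAnnotationError("annotation contains no exon records")

    models = []
    for gene in sorted(exons):
        chrom, strand = meta[gene]
        union = _merge_intervals(exons[gene])
        model = GeneModel(gene_id=gene, chrom=chrom, strand=strand, exons=union)
        L = model.mrna_length
        cds_union = _merge_intervals(cdss.get(gene, []))
        tx_positions = []
        for a, b in cds_union:
            # clip CDS to the exonic footprint, then map endpoint bases
            for e0, e1 in union:
                lo, hi = max(a, e0), min(b, e1)
                if lo < hi:
                    tx_positions.append(model.genome_to_tx(lo))
                    tx_positions.append(model.genome_to_tx(hi - 1))
        if tx_positions:
            cds_lo = min(tx_positions)
            cds_hi = max(tx_positions) + 1
            model.utr5_span = (0, cds_lo)
            model.cds_span = (cds_lo, cds_hi)
            model.utr3_span = (cds_hi, L)
            model.coding = True
        else:
            model.utr5_span = (0, 0)
            model.cds_span = (0, L)
            model.utr3_span = (L, L)
            model.coding = False
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# Bin tiling


@dataclass(frozen=True)
class Bin:
    """One mRNA bin: transcript-coordinate slice of a gene plus its
    genomic projection."""

    gene_id: str
    tx_start: int
    tx_end: int
    genomic: tuple[GenomicInterval, ...]

    def __len__(self) -> int:
        return self.tx_end - self.tx_start


@dataclass
class BinIndex:
    """Ordered fixed-width bins tiling every gene's mRNA.

    Bins are grouped by gene (genes in sorted gene_id order) and are
    contiguous, disjoint and exactly cover [0, mrna_length) within each
    gene.
    """

    bins: list[Bin]
    bin_width: int
    gene_offsets: dict[str, tuple[int, int]]  # gene_id -> (first index, n bins)
    _edges: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_bins_per_gene(self) -> dict[str, int]:
        return {g: n for g, (_, n) in self.gene_offsets.items()}

    def gene_slice(self, gene_id: str) -> slice:
        off, n = self.gene_offsets[gene_id]
        return slice(off, off + n)

    def bin_of(self, gene_id: str, tx_pos: int) -> int:
        """Global index of the bin containing a transcript position."""
        off, n = self.gene_offsets[gene_id]
        edges = self._edges[gene_id]
        i = int(np.searchsorted(edges, tx_pos, side="right")) - 1
        if not (0 <= i < n):
            raise MeripQCError(f"{gene_id}: transcript position {tx_pos} out of range")
        return off + i


def build_bins(models: Sequence[GeneModel], bin_width: int = 200) -> BinIndex:
    """Tile every gene 5'->3' with bins of ``bin_width`` nt.

    A final partial bin of length >= bin_width/4 is kept; a shorter
    remainder is merged into the previous bin.  Genes shorter than one
    bin form a single bin.
    """
    if bin_width < 10:
        raise MeripQCError(f"bin_width must be >= 10, got {bin_width}")
    models = sorted(models, key=lambda m: m.gene_id)
    if not models:
        raise EmptyAnnotationError("no gene models to bin")
    bins: list[Bin] = []
    offsets: dict[str, tuple[int, int]] = {}
    edges_map: dict[str, np.ndarray] = {}
    for model in models:
        L = model.mrna_length
        if L <= bin_width:
            edges = [0, L]
        else:
            edges = list(range(0, L, bin_width))
            rem = L - edges[-1]
            if rem == 0:
                edges = edges + [L]
            elif rem >= bin_width / 4:
                edges = edges + [L]
            else:
                edges[-1] = L  # merge remainder into previous bin
        first = len(bins)
        for a, b in zip(edges[:-1], edges[1:]):
            bins.append(
                Bin(model.gene_id, a, b, tuple(project_to_genome(model, (a, b))))
            )
        offsets[model.gene_id] = (first, len(edges) - 1)
        edges_map[model.gene_id] = np.asarray(edges[:-1])
    return BinIndex(bins=bins, bin_width=bin_width, gene_offsets=offsets, _edges=edges_map)
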