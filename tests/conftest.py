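"""Shared fixtures: the default synthetic dataset, counted samples, and
small hand-built annotations."""

import io

import numpy as np
import pytest

from meripqc.annotation import build_bins, load_annotation
from meripqc.counting import GenomeIndex, SampleCounts, count_sample, merge_inputs
from meripqc.simulate import make_default_fixtures


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Default synthetic fixture set: clean 3xIP/3xInput plus artifact
    samples, all on one shared toy transcriptome."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_default_fixtures(out, seed=0)


@pytest.fixture(scope="session")
def models(fixture_set):
    return load_annotation(fixture_set.gtf_path)


@pytest.fixture(scope="session")
def bin_index(models):
    return build_bins(models, 200)


@pytest.fixture(scope="session")
def genome_index(models):
    return GenomeIndex(models)


@pytest.fixture(scope="session")
def counted(fixture_set, genome_index, bin_index):
    """SampleCounts for every fixture sample, by sample_id."""
    out = {}
    for s in fixture_set.all_samples:
        out[s.sample_id] = count_sample(
            s.bam_path, genome_index, bin_index, role=s.role, sample_id=s.sample_id
        )
    return out


@pytest.fixture(scope="session")
def merged_input(counted):
    return merge_inputs([counted[f"Input{i}"] for i in (1, 2, 3)])


def make_annotation(gtf_text):
    return load_annotation(io.StringIO(gtf_text))


def toy_counts(bin_counts, bin_index, *, role="IP", sample_id="toy",
               intron=0, nongenic=0, subregions=None):
    """Hand-build a SampleCounts over an existing BinIndex."""
    bin_counts = np.asarray(bin_counts, dtype=np.int64)
    exon = int(bin_counts.sum())
    sub = subregions or {"utr5": 0, "cds": 0, "utr3": 0}
    region = {
        "exon": exon,
        "intron": intron,
        "nongenic": nongenic,
        "utr5": sub["utr5"],
        "cds": sub["cds"],
        "utr3": sub["utr3"],
    }
    return SampleCounts(
        sample_id=sample_id,
        role=role,
        total_reads=exon + intron + nongenic,
        region_counts=region,
        bin_counts=bin_counts,
        bin_index=bin_index,
    )


def single_gene_gtf(length=600, chrom="chr1", strand="+", cds=None, gene="g1"):
    """GTF text for one single-exon gene starting at genomic 1000."""
    start, end = 1001, 1000 + length  # 1-based closed
    lines = [
        f'{chrom}\tt\texon\t{start}\t{end}\t.\t{strand}\t.\tgene_id "{gene}"; transcript_id "{gene}.t";'
    ]
    if cds is not None:
        a, b = cds  # transcript coordinates, half-open
        if strand == "+":
            lines.append(
                f'{chrom}\tt\tCDS\t{start + a}\t{start + b - 1}\t.\t+\t0\tgene_id "{gene}"; transcript_id "{gene}.t";'
            )
        else:
            lines.append(
                f'{chrom}\tt\tCDS\t{end - b + 1}\t{end - a}\t.\t-\t0\tgene_id "{gene}"; transcript_id "{gene}.t";'
            )
    return "\n".join(lines) + "\n"
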