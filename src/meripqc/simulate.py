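"""Synthetic MeRIP-seq fixture generator.

Emits a toy transcriptome (GTF) and aligned reads (coordinate-sorted,
indexed BAM) with known ground truth, so every QC metric can be tested
without external data.  The data model mirrors a typical m6A-seq
experiment:

* gene abundances are log-normal (expression heterogeneity);
* Input reads fall on mRNA bins in proportion to abundance and bin
  length, plus background intronic and nongenic reads;
* IP reads additionally carry a fold-enrichment multiplier on a planted
  subset of "methylated" bins placed near the CDS/3'UTR boundary (the
  stop-codon-proximal pattern characteristic of m6A);
* artifact modes emulate common failure cases: ``pcr_dup`` (a read
  subset duplicated), ``three_prime_bias`` (within-gene sampling tilted
  toward 3' ends) and ``swap`` (IP/Input roles exchanged).

Reads are single-end, fixed-length, ungapped, MAPQ 60 — the simplest
profile the midpoint counting rules need.  Everything is deterministic
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation import BinIndex, GeneModel, build_bins, project_to_genome
from .counting import REGIONS, SampleCounts
from .errors import SimulationSpecError

__all__ = [
    "SimulationSpec",
    "Transcriptome",
    "SimulatedSample",
    "SimulatedDataset",
    "make_transcriptome",
    "simulate_counts",
    "simulate_reads",
    "simulate_dataset",
    "make_default_fixtures",
]

ARTIFACT_MODES = ("none", "pcr_dup", "three_prime_bias", "swap")


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic experiment."""

    n_genes: int = 50
    utr5_range: tuple[int, int] = (150, 350)
    cds_range: tuple[int, int] = (1800, 3600)
    utr3_range: tuple[int, int] = (600, 1400)
    max_exons: int = 3
    intron_range: tuple[int, int] = (200, 800)
    intergenic_range: tuple[int, int] = (500, 2000)
    expression_sigma: float = 1.0       # log-normal sd of gene abundance
    peak_fraction: float = 0.1          # fraction of mRNA bins methylated
    peak_fold: float = 8.0              # IP enrichment on methylated bins
    peak_window_bins: int = 2           # placement within +-2 bins of stop codon
    depth: int = 100_000                # reads per sample
    frac_intronic: float = 0.05
    frac_nongenic: float = 0.45
    bin_width: int = 200
    read_length: int = 50
    artifact_mode: str = "none"
    dup_fraction: float = 0.3           # pcr_dup: share of reads that are copies
    dup_seed_fraction: float = 0.01     # pcr_dup: share of reads amplified
    bias_strength: float = 1.5          # three_prime_bias: exponential tilt
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.peak_fraction <= 1):
            raise SimulationSpecError("peak_fraction must be in [0,1]")
        if self.peak_fold < 1:
            raise SimulationSpecError("peak_fold must be >= 1")
        if self.depth < 1:
            raise SimulationSpecError("depth must be >= 1")
        if self.cds_range[0] < 3:
            raise SimulationSpecError("CDS must be at least one codon")
        if self.frac_intronic + self.frac_nongenic >= 1:
            raise SimulationSpecError("background fractions must sum to < 1")
        if self.artifact_mode not in ARTIFACT_MODES:
            raise SimulationSpecError(f"unknown artifact_mode {self.artifact_mode!r}")
        if not (0 <= self.dup_fraction < 1):
            raise SimulationSpecError("dup_fraction must be in [0,1)")


@dataclass
class Transcriptome:
    """Toy transcriptome plus planted methylation truth."""

    models: list[GeneModel]
    bin_index: BinIndex
    abundance: dict[str, float]            # gene -> relative abundance
    methylated: dict[int, float]           # global bin index -> fold
    chrom_lengths: dict[str, int]
    gaps: list[tuple[str, int, int]]       # intergenic intervals
    gtf_text: str

    @property
    def planted_fraction(self) -> float:
        """Realized fraction of mRNA bins carrying methylation."""
        return len(self.methylated) / self.bin_index.n_bins

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append(
                dict(
                    gene_id=m.gene_id,
                    chrom=m.chrom,
                    strand=m.strand,
                    mrna_length=m.mrna_length,
                    utr5_len=m.utr5_span[1] - m.utr5_span[0],
                    cds_len=m.cds_span[1] - m.cds_span[0],
                    utr3_len=m.utr3_span[1] - m.utr3_span[0],
                    n_bins=self.bin_index.gene_offsets[m.gene_id][1],
                    abundance=self.abundance[m.gene_id],
                )
            )
        return pd.DataFrame(rows)

    def bin_table(self) -> pd.DataFrame:
        rows = []
        for idx, b in enumerate(self.bin_index.bins):
            rows.append(
                dict(
                    global_bin=idx,
                    gene_id=b.gene_id,
                    tx_start=b.tx_start,
                    tx_end=b.tx_end,
                    methylated=idx in self.methylated,
                    fold=self.methylated.get(idx, 1.0),
                )
            )
        return pd.DataFrame(rows)


def make_transcriptome(spec: SimulationSpec, rng: np.random.Generator) -> Transcriptome:
    """Build the toy transcriptome and plant methylated bins."""
    spec.validate()
    models: list[GeneModel] = []
    gtf_lines: list[str] = []
    gaps: list[tuple[str, int, int]] = []
    chrom = "chr1"
    cursor = int(rng.integers(*spec.intergenic_range)) + spec.read_length
    gap_start = spec.read_length
    width = len(str(spec.n_genes))
    for gi in range(spec.n_genes):
        gene_id = f"gene{gi + 1:0{width}d}"
        u5 = int(rng.integers(*spec.utr5_range))
        cds = 3 * (int(rng.integers(*spec.cds_range)) // 3)
        u3 = int(rng.integers(*spec.utr3_range))
        L = u5 + cds + u3
        n_exons = int(rng.integers(1, spec.max_exons + 1))
        # split the mRNA into n_exons segments, each >= 50 nt
        while True:
            cuts = np.sort(rng.integers(50, L - 50, size=n_exons - 1)) if n_exons > 1 else np.array([], dtype=int)
            seg_lens = np.diff(np.concatenate([[0], cuts, [L]]))
            if (seg_lens >= 50).all():
                break
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        gaps.append((chrom, gap_start, cursor))
        pos = cursor
        for j, sl in enumerate(seg_lens):
            exons.append((pos, pos + int(sl)))
            pos += int(sl)
            if j < len(seg_lens) - 1:
                pos += int(rng.integers(*spec.intron_range))
        model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)
        model.utr5_span = (0, u5)
        model.cds_span = (u5, u5 + cds)
        model.utr3_span = (u5 + cds, L)
        model.coding = True
        models.append(model)
        tid = f"{gene_id}.t1"
        attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
        for a, b in exons:
            gtf_lines.append(
                f"{chrom}\tsim\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t{attrs}"
            )
        for iv in project_to_genome(model, model.cds_span):
            gtf_lines.append(
                f"{chrom}\tsim\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t0\t{attrs}"
            )
        gap_start = pos
        cursor = pos + int(rng.integers(*spec.intergenic_range))
    gaps.append((chrom, gap_start, cursor))
    chrom_lengths = {chrom: cursor + spec.read_length}

    bin_index = build_bins(models, spec.bin_width)

    # log-normal expression
    abund = np.exp(rng.normal(0.0, spec.expression_sigma, size=spec.n_genes))
    abundance = {m.gene_id: float(a) for m, a in zip(models, abund)}

    # Plant methylated bins.  Every gene carries stop-codon-proximal
    # methylation — the regime typical of m6A, where most expressed
    # transcripts have at least one peak: the bin containing the stop
    # codon is always methylated, and any further peaks sit within
    # +-peak_window_bins of it with probability decaying away from the
    # boundary.  Per-gene peak numbers are set so the overall fraction
    # of methylated bins matches peak_fraction.
    methylated: dict[int, float] = {}
    if spec.peak_fraction > 0:
        w = spec.peak_window_bins
        side_weights = {d: w + 1 - abs(d) for d in range(-w, w + 1) if d != 0}
        for m in models:
            off, n = bin_index.gene_offsets[m.gene_id]
            stop_bin = bin_index.bin_of(m.gene_id, max(m.cds_span[1] - 1, 0)) - off
            window = [
                stop_bin + d
                for d in sorted(side_weights)
                if 0 <= stop_bin + d < n
            ]
            n_g = max(1, int(round(spec.peak_fraction * n)))
            n_g = min(n_g, 1 + len(window))
            methylated[off + stop_bin] = float(spec.peak_fold)
            if n_g > 1:
                probs = np.array(
                    [side_weights[b - stop_bin] for b in window], dtype=float
                )
                extra = rng.choice(
                    len(window), size=n_g - 1, replace=False, p=probs / probs.sum()
                )
                for e in extra:
                    methylated[off + window[e]] = float(spec.peak_fold)

    return Transcriptome(
        models=models,
        bin_index=bin_index,
        abundance=abundance,
        methylated=methylated,
        chrom_lengths=chrom_lengths,
        gaps=[g for g in gaps if g[2] - g[1] > 4 * spec.read_length],
        gtf_text="\n".join(gtf_lines) + "\n",
    )


# ---------------------------------------------------------------------------
# category weights and count-level simulation


def exonic_bin_weights(
    tr: Transcriptome, spec: SimulationSpec, role: str, artifact: str = "none"
) -> np.ndarray:
    """Unnormalized sampling weight of every mRNA bin for one sample."""
    bi = tr.bin_index
    w = np.zeros(bi.n_bins)
    for m in tr.models:
        off, n = bi.gene_offsets[m.gene_id]
        a = tr.abundance[m.gene_id]
        for i in range(n):
            b = bi.bins[off + i]
            w[off + i] = a * len(b) / m.mrna_length
            if artifact == "three_prime_bias":
                rel = 0.5 * (b.tx_start + b.tx_end) / m.mrna_length
                w[off + i] *= np.exp(spec.bias_strength * rel)
    if role == "IP":
        for idx, fold in tr.methylated.items():
            w[idx] *= fold
    return w


def _category_weights(
    tr: Transcriptome, spec: SimulationSpec, role: str, artifact: str
) -> tuple[np.ndarray, list[tuple[str, object]]]:
    """Full multinomial weight vector over (bins, gene introns, gaps)."""
    bins_w = exonic_bin_weights(tr, spec, role, artifact)
    cats: list[tuple[str, object]] = [("bin", i) for i in range(len(bins_w))]
    weights = [bins_w / bins_w.sum() * (1 - spec.frac_intronic - spec.frac_nongenic)]

    intron_genes = []
    intron_w = []
    for m in tr.models:
        introns = [
            (b0, a1) for (_, b0), (a1, _) in zip(m.exons[:-1], m.exons[1:])
        ]
        if introns:
            intron_genes.append((m, introns))
            intron_w.append(tr.abundance[m.gene_id])
    if intron_genes:
        iw = np.array(intron_w)
        weights.append(iw / iw.sum() * spec.frac_intronic)
        cats.extend(("intron", mi) for mi in intron_genes)

    gw = np.array([hi - lo for _, lo, hi in tr.gaps], dtype=float)
    weights.append(gw / gw.sum() * spec.frac_nongenic)
    cats.extend(("gap", g) for g in tr.gaps)

    return np.concatenate(weights), cats


def _dup_allocation(
    n_base: int, n_dup: int, spec: SimulationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """PCR-jackpot model: a small seed subset of reads is amplified with
    geometric copy numbers.  Returns (seed read indices into the base
    reads, copies per seed) with copies summing to n_dup."""
    n_seeds = max(1, int(round(spec.dup_seed_fraction * n_base)))
    seeds = rng.choice(n_base, size=n_seeds, replace=False)
    weights = rng.geometric(0.1, size=n_seeds).astype(float)
    copies = rng.multinomial(n_dup, weights / weights.sum())
    return seeds, copies


def _draw_category_counts(
    tr, spec, role, artifact, depth, rng
) -> tuple[np.ndarray, list]:
    w, cats = _category_weights(tr, spec, role, artifact)
    w = w / w.sum()
    if artifact == "pcr_dup":
        n_dup = int(round(spec.dup_fraction * depth))
        base = rng.multinomial(depth - n_dup, w)
        # each duplicated read stays in its category: pick seed reads
        # (categories proportional to base counts), amplify geometrically
        seeds, copies = _dup_allocation(int(base.sum()), n_dup, spec, rng)
        edges = np.cumsum(base)
        seed_cats = np.searchsorted(edges, seeds, side="right")
        counts = base.copy()
        np.add.at(counts, seed_cats, copies)
    else:
        counts = rng.multinomial(depth, w)
    return counts, cats


def simulate_counts(
    tr: Transcriptome,
    spec: SimulationSpec,
    role: str,
    rng: np.random.Generator,
    *,
    sample_id: str = "sim",
    artifact: str | None = None,
    depth: int | None = None,
) -> SampleCounts:
    """Draw a SampleCounts directly from the generative model (no BAM).

    Distributionally identical to counting a simulated BAM with the
    midpoint rule; used where only counts are needed.
    """
    artifact = spec.artifact_mode if artifact is None else artifact
    depth = spec.depth if depth is None else depth
    counts, cats = _draw_category_counts(tr, spec, role, artifact, depth, rng)
    bi = tr.bin_index
    bin_counts = np.zeros(bi.n_bins, dtype=np.int64)
    region = {r: 0 for r in REGIONS}
    models = {m.gene_id: m for m in tr.models}
    for c, (kind, payload) in zip(counts, cats):
        if c == 0:
            continue
        if kind == "bin":
            bin_counts[payload] += c
            b = bi.bins[payload]
            m = models[b.gene_id]
            # split the bin's reads over sub-regions by tx-span overlap
            spans = {"utr5": m.utr5_span, "cds": m.cds_span, "utr3": m.utr3_span}
            ov = np.array(
                [
                    max(0, min(b.tx_end, s[1]) - max(b.tx_start, s[0]))
                    for s in spans.values()
                ],
                dtype=float,
            )
            split = rng.multinomial(c, ov / ov.sum())
            for r, v in zip(spans, split):
                region[r] += int(v)
        elif kind == "intron":
            region["intron"] += int(c)
        else:
            region["nongenic"] += int(c)
    region["exon"] = int(bin_counts.sum())
    out = SampleCounts(
        sample_id=sample_id,
        role=role,
        total_reads=int(counts.sum()),
        region_counts=region,
        bin_counts=bin_counts,
        bin_index=bi,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# read-level simulation and BAM output


def simulate_reads(
    tr: Transcriptome,
    spec: SimulationSpec,
    role: str,
    rng: np.random.Generator,
    *,
    sample_id: str = "sim",
    artifact: str | None = None,
    depth: int | None = None,
) -> pd.DataFrame:
    """Generate individual reads with truth labels.

    Returns a DataFrame with one row per read: chrom, start (0-based),
    region, gene_id, global_bin, subregion, is_duplicate.  The read
    midpoint (start + read_length//2) determines all truth labels,
    matching the counting module's assignment rule.
    """
    artifact = spec.artifact_mode if artifact is None else artifact
    depth = spec.depth if depth is None else depth
    rl = spec.read_length
    half = rl // 2
    models = {m.gene_id: m for m in tr.models}
    bi = tr.bin_index

    if artifact == "pcr_dup":
        n_dup = int(round(spec.dup_fraction * depth))
        base = simulate_reads(
            tr, spec, role, rng, sample_id=sample_id, artifact="none",
            depth=depth - n_dup,
        )
        seeds, copies = _dup_allocation(len(base), n_dup, spec, rng)
        picks = np.repeat(seeds, copies)
        dups = base.iloc[picks].copy()
        dups["is_duplicate"] = True
        out = pd.concat([base, dups], ignore_index=True)
        return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    counts, cats = _draw_category_counts(tr, spec, role, artifact, depth, rng)
    rows = []
    for c, (kind, payload) in zip(counts, cats):
        if c == 0:
            continue
        if kind == "bin":
            b = bi.bins[payload]
            m = models[b.gene_id]
            tx_mids = rng.integers(b.tx_start, b.tx_end, size=c)
            for u in tx_mids:
                gmid = project_to_genome(m, (int(u), int(u) + 1))[0].start
                rows.append(
                    (m.chrom, gmid - half, "exon", m.gene_id, payload,
                     m.subregion_of(int(u)))
                )
        elif kind == "intron":
            m, introns = payload
            ilens = np.array([b - a for a, b in introns], dtype=float)
            which = rng.choice(len(introns), size=c, p=ilens / ilens.sum())
            for wi in which:
                a, b = introns[wi]
                gmid = int(rng.integers(a, b))
                rows.append((m.chrom, gmid - half, "intron", m.gene_id, -1, None))
        else:
            chrom, lo, hi = payload
            mids = rng.integers(lo + rl, hi - rl, size=c)
            for gmid in mids:
                rows.append((chrom, int(gmid) - half, "nongenic", None, -1, None))
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "region", "gene_id", "global_bin", "subregion"],
    )
    df["is_duplicate"] = False
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bam(
    reads: pd.DataFrame,
    chrom_lengths: dict[str, int],
    path,
    read_length: int = 50,
) -> pd.DataFrame:
    """Write reads as a coordinate-sorted, indexed BAM; returns the
    reads table with assigned read names."""
    path = Path(path)
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    reads = reads.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    names = [f"r{i:07d}" for i in range(len(reads))]
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, chrom, start in zip(names, reads["chrom"], reads["start"]):
            a = pysam.AlignedSegment()
            a.query_name = name
            a.reference_id = tid[chrom]
            a.reference_start = int(start)
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            a.flag = 0
            bam.write(a)
    pysam.index(str(path))
    out = reads.copy()
    out.insert(0, "read_name", names)
    return out


@dataclass
class SimulatedSample:
    sample_id: str
    role: str
    bam_path: Path
    truth_reads: pd.DataFrame


@dataclass
class SimulatedDataset:
    gtf_path: Path
    samples: list[SimulatedSample]
    transcriptome: Transcriptome
    spec: SimulationSpec

    @property
    def ip_bams(self) -> list[Path]:
        return [s.bam_path for s in self.samples if s.role == "IP"]

    @property
    def input_bams(self) -> list[Path]:
        return [s.bam_path for s in self.samples if s.role == "Input"]


def simulate_dataset(
    spec: SimulationSpec,
    out_dir,
    n_ip: int = 1,
    n_input: int = 1,
) -> SimulatedDataset:
    """Emit a GTF plus ``n_ip`` IP and ``n_input`` Input BAMs (with
    truth TSVs) under ``out_dir``; deterministic per spec.seed."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(spec.seed)
    tr = make_transcriptome(spec, np.random.default_rng(ss.spawn(1)[0]))
    gtf_path = out_dir / "annotation.gtf"
    gtf_path.write_text(tr.gtf_text)
    samples = []
    child_seeds = ss.spawn(n_ip + n_input + 1)[1:]
    roles = [("IP", i + 1) for i in range(n_ip)] + [
        ("Input", i + 1) for i in range(n_input)
    ]
    swap = spec.artifact_mode == "swap"
    for seed, (role, num) in zip(child_seeds, roles):
        sid = f"{role}{num}"
        gen_role = {"IP": "Input", "Input": "IP"}[role] if swap else role
        reads = simulate_reads(
            tr, spec, gen_role, np.random.default_rng(seed),
            sample_id=sid,
            artifact="none" if swap else spec.artifact_mode,
        )
        bam_path = out_dir / f"{sid}.bam"
        truth = write_bam(reads, tr.chrom_lengths, bam_path, spec.read_length)
        truth.insert(1, "sample_id", sid)
        samples.append(SimulatedSample(sid, role, bam_path, truth))
    tr.gene_table().to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    tr.bin_table().to_csv(out_dir / "truth_bins.tsv", sep="\t", index=False)
    pd.concat([s.truth_reads for s in samples], ignore_index=True).to_csv(
        out_dir / "truth_reads.tsv", sep="\t", index=False
    )
    return SimulatedDataset(gtf_path=gtf_path, samples=samples, transcriptome=tr, spec=spec)


@dataclass
class FixtureSet:
    """The canonical test fixture set: a clean 3xIP / 3xInput design
    plus artifact samples sharing the same transcriptome."""

    gtf_path: Path
    transcriptome: Transcriptome
    spec: SimulationSpec
    clean: dict[str, SimulatedSample]          # IP1..3, Input1..3
    outlier_ip: SimulatedSample                # Input-distributed, labelled IP
    swapped: dict[str, SimulatedSample]        # swap_IP, swap_Input
    dup_ip: SimulatedSample                    # pcr_dup twin of IP1
    bias_ip: SimulatedSample                   # three_prime_bias twin of IP1

    @property
    def all_samples(self) -> list[SimulatedSample]:
        return (
            list(self.clean.values())
            + [self.outlier_ip]
            + list(self.swapped.values())
            + [self.dup_ip, self.bias_ip]
        )


def make_default_fixtures(
    out_dir, seed: int = 0, depth: int = 15_000, n_genes: int = 50
) -> FixtureSet:
    """Write the default fixture set (~11 samples, <= 200k reads total).

    The artifact twins of IP1 reuse IP1's read seed, so each twin
    differs from IP1 only through its artifact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(n_genes=n_genes, depth=depth, seed=seed)
    spec.validate()
    ss = np.random.SeedSequence(seed)
    tr_seed, *read_seeds = ss.spawn(12)
    tr = make_transcriptome(spec, np.random.default_rng(tr_seed))
    gtf_path = out_dir / "annotation.gtf"
    gtf_path.write_text(tr.gtf_text)

    def emit(sid, role, gen_role, artifact, seed_):
        reads = simulate_reads(
            tr, spec, gen_role, np.random.default_rng(seed_),
            sample_id=sid, artifact=artifact,
        )
        truth = write_bam(reads, tr.chrom_lengths, out_dir / f"{sid}.bam",
                          spec.read_length)
        truth.insert(1, "sample_id", sid)
        return SimulatedSample(sid, role, out_dir / f"{sid}.bam", truth)

    clean = {}
    for i in range(3):
        clean[f"IP{i + 1}"] = emit(f"IP{i + 1}", "IP", "IP", "none", read_seeds[i])
    for i in range(3):
        clean[f"Input{i + 1}"] = emit(
            f"Input{i + 1}", "Input", "Input", "none", read_seeds[3 + i]
        )
    outlier = emit("outlier_IP", "IP", "Input", "none", read_seeds[6])
    swapped = {
        "swap_IP": emit("swap_IP", "IP", "Input", "none", read_seeds[7]),
        "swap_Input": emit("swap_Input", "Input", "IP", "none", read_seeds[8]),
    }
    dup = emit("dup_IP", "IP", "IP", "pcr_dup", read_seeds[0])
    bias = emit("bias_IP", "IP", "IP", "three_prime_bias", read_seeds[0])

    tr.gene_table().to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    tr.bin_table().to_csv(out_dir / "truth_bins.tsv", sep="\t", index=False)
    all_samples = list(clean.values()) + [outlier] + list(swapped.values()) + [dup, bias]
    pd.concat([s.truth_reads for s in all_samples], ignore_index=True).to_csv(
        out_dir / "truth_reads.tsv", sep="\t", index=False
    )
    return FixtureSet(
        gtf_path=gtf_path,
        transcriptome=tr,
        spec=spec,
        clean=clean,
        outlier_ip=outlier,
        swapped=swapped,
        dup_ip=dup,
        bias_ip=bias,
    )
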