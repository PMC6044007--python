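"""Pipeline orchestration, quality verdicts and the HTML report.

Runs annotation -> counting -> distribution -> enrichment -> multisample
on a set of IP and Input BAMs, compares each IP sample's ESES metrics
against the packaged good-quality reference ranges, and writes a
self-contained HTML report plus a machine-readable JSON summary.
"""

from __future__ import annotations

import base64
import html
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .annotation import build_bins, load_annotation
from .counting import GenomeIndex, SampleCounts, count_sample, merge_inputs
from .distribution import (
    COVERAGE_CLASSES,
    coverage_histogram,
    metagene,
    region_stats,
)
from .enrichment import (
    DEFAULT_FOLD_GRID,
    compute_eses,
    ctest_profile,
    normalize_gene_bins,
)
from .errors import MeripQCError
from .multisample import (
    cluster_samples,
    gene_mean_sd,
    normalize_matrix,
    pca_samples,
    replicate_consistency,
)
from . import plotting

__all__ = [
    "GOOD_QUALITY_RANGES",
    "QCVerdict",
    "QCReport",
    "PipelineConfig",
    "assess",
    "run_pipeline",
]

# Good-quality reference ranges compiled from a survey of 61 published
# m6A-seq IP samples (with matched Inputs) from high-impact studies;
# poor-quality regimes were characterized by sample swapping.  Other
# modifications (e.g. m1A) legitimately fall outside these m6A ranges.
GOOD_QUALITY_RANGES: dict[str, tuple[float, float]] = {
    "enriched_region_pct": (12.0, 25.0),
    "scale_factor": (0.08, 0.30),
    "signal_read_pct": (87.0, 95.0),
}


@dataclass
class QCVerdict:
    sample_id: str
    metrics: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    status: dict[str, str]      # metric -> within | below | above
    overall: str                # within | flagged

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "metrics": self.metrics,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "status": self.status,
            "overall": self.overall,
        }


def assess(
    sample_id: str,
    eses_result,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> QCVerdict:
    """Compare one IP sample's ESES metrics against reference ranges.

    Intervals are closed: a boundary value counts as within range.
    """
    ranges = dict(GOOD_QUALITY_RANGES if ranges is None else ranges)
    metrics = {
        "enriched_region_pct": 100.0 * eses_result.enriched_fraction,
        "scale_factor": eses_result.scale_factor,
        "signal_read_pct": 100.0 * eses_result.signal_read_fraction,
    }
    status = {}
    for key, value in metrics.items():
        lo, hi = ranges[key]
        status[key] = "below" if value < lo else ("above" if value > hi else "within")
    overall = "within" if all(s == "within" for s in status.values()) else "flagged"
    return QCVerdict(
        sample_id=sample_id, metrics=metrics, ranges=ranges, status=status,
        overall=overall,
    )


@dataclass
class PipelineConfig:
    ip_bams: list
    input_bams: list
    gtf: object
    out_dir: object
    bin_width: int = 200
    downsample: int | None = None
    seed: int = 0
    alpha: float = 0.05
    fold_grid: tuple[float, ...] = DEFAULT_FOLD_GRID
    mapq: int = 0
    min_gene_reads: int = 10
    min_bin_reads: int = 10
    make_plots: bool = True
    strict: bool = True
    sample_ids: dict | None = None  # path -> sample_id override


@dataclass
class QCReport:
    config: PipelineConfig
    summary: dict
    html_path: Path
    json_path: Path
    skipped: dict[str, str] = field(default_factory=dict)


def _sample_id(cfg, path, default):
    if cfg.sample_ids:
        for k, v in cfg.sample_ids.items():
            if str(k) == str(path):
                return v
    return default


def run_pipeline(config: PipelineConfig) -> QCReport:
    """Execute the full QC assessment and write HTML + JSON outputs.

    Deterministic for a fixed config and seed.  With ``strict`` unset,
    a failing non-fatal section is skipped (with its reason recorded)
    instead of aborting the run.
    """
    cfg = config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig_dir = out_dir / "figures"
    tbl_dir = out_dir / "tables"
    tbl_dir.mkdir(exist_ok=True)
    skipped: dict[str, str] = {}
    summary: dict = {
        "meta": {
            "version": __version__,
            "ip_bams": [str(p) for p in cfg.ip_bams],
            "input_bams": [str(p) for p in cfg.input_bams],
            "gtf": str(cfg.gtf),
            "parameters": {
                "bin_width": cfg.bin_width,
                "downsample": cfg.downsample,
                "seed": cfg.seed,
                "alpha": cfg.alpha,
                "fold_grid": list(cfg.fold_grid),
                "mapq": cfg.mapq,
                "min_gene_reads": cfg.min_gene_reads,
                "min_bin_reads": cfg.min_bin_reads,
                "read_location_rule": "midpoint",
                "gene_model": "union-exon",
                "linkage": "complete",
                "lowess_span": 0.75,
            },
        }
    }
    figures: dict[str, Path] = {}

    models = load_annotation(cfg.gtf)
    bin_index = build_bins(models, cfg.bin_width)
    gidx = GenomeIndex(models)
    summary["annotation"] = {
        "n_genes": len(models),
        "n_coding": sum(m.coding for m in models),
        "n_bins": bin_index.n_bins,
    }

    # -- counting -----------------------------------------------------------
    counts: list[SampleCounts] = []
    for role, paths in (("IP", cfg.ip_bams), ("Input", cfg.input_bams)):
        for i, path in enumerate(paths):
            sid = _sample_id(cfg, path, Path(str(path)).stem)
            counts.append(
                count_sample(
                    path, gidx, bin_index, role=role, sample_id=sid,
                    down_to=cfg.downsample, seed=cfg.seed, mapq=cfg.mapq,
                )
            )
    ip_counts = [c for c in counts if c.role == "IP"]
    input_counts = [c for c in counts if c.role == "Input"]
    merged_input = merge_inputs(input_counts)

    # -- read-distribution statistics --------------------------------------
    stats_rows = [region_stats(c) for c in counts]
    summary["region_stats"] = {
        r.sample_id: {
            "total": r.total,
            "counts": r.counts,
            "percents": {k: round(v, 4) for k, v in r.percents.items()},
        }
        for r in stats_rows
    }
    _write_region_table(stats_rows, tbl_dir / "region_stats.tsv")

    if cfg.downsample is None and len({c.total_reads for c in counts}) > 1:
        warnings.warn(
            "samples have unequal depths; coverage-histogram comparisons "
            "are best made after down-sampling to a common depth",
            stacklevel=2,
        )
    hist_rows = [coverage_histogram(c) for c in counts]
    summary["coverage_histogram"] = {
        h.sample_id: {k: round(v, 6) for k, v in h.class_fractions.items()}
        for h in hist_rows
    }
    _write_histogram_table(hist_rows, tbl_dir / "coverage_histogram.tsv")

    metagenes = {}
    for c in counts:
        try:
            metagenes[c.sample_id] = metagene(
                c, models, min_gene_reads=cfg.min_gene_reads
            )
        except MeripQCError as e:
            _skip(skipped, f"metagene:{c.sample_id}", e, cfg.strict)
    summary["metagene"] = {
        sid: {
            "n_genes_used": m.n_genes_used,
            "region_median_lengths": m.region_median_lengths,
            "quantile_curves": {
                str(q): np.round(curve, 6).tolist()
                for q, curve in m.quantile_curves.items()
            },
        }
        for sid, m in metagenes.items()
    }

    # -- enrichment (per IP vs merged Input) -------------------------------
    eses_results = {}
    ctest_results = {}
    verdicts = {}
    for c in ip_counts:
        try:
            norm = normalize_gene_bins(
                c, merged_input, bin_index, min_gene_reads=cfg.min_gene_reads
            )
            eses_results[c.sample_id] = compute_eses(norm)
            verdicts[c.sample_id] = assess(c.sample_id, eses_results[c.sample_id])
        except MeripQCError as e:
            _skip(skipped, f"eses:{c.sample_id}", e, cfg.strict)
        try:
            ctest_results[c.sample_id] = ctest_profile(
                c, merged_input, fold_grid=cfg.fold_grid, alpha=cfg.alpha,
                min_bin_reads=cfg.min_bin_reads,
            )
        except MeripQCError as e:
            _skip(skipped, f"ctest:{c.sample_id}", e, cfg.strict)
    summary["eses"] = {
        sid: {
            "n_bins": r.N,
            "k": r.k,
            "scale_factor": round(r.scale_factor, 6),
            "enriched_region_pct": round(100 * r.enriched_fraction, 4),
            "signal_read_pct": round(100 * r.signal_read_fraction, 4),
        }
        for sid, r in eses_results.items()
    }
    summary["ctest"] = {
        sid: {
            "fold_grid": list(p.fold_grid),
            "proportion_significant": np.round(p.proportions, 6).tolist(),
            "alpha": p.alpha,
            "n_bins_tested": p.n_bins_tested,
        }
        for sid, p in ctest_results.items()
    }
    summary["verdicts"] = {sid: v.as_dict() for sid, v in verdicts.items()}
    _write_eses_table(eses_results, verdicts, tbl_dir / "eses_metrics.tsv")

    # -- multisample -------------------------------------------------------
    norm_matrix = dend = pca = None
    if len(counts) >= 2:
        try:
            norm_matrix = normalize_matrix(counts)
            summary["normalization"] = {
                "size_factors": {
                    sid: round(float(s), 6)
                    for sid, s in zip(norm_matrix.sample_ids, norm_matrix.size_factors)
                },
                "raw_totals": {
                    sid: int(t)
                    for sid, t in zip(norm_matrix.sample_ids, norm_matrix.raw_totals)
                },
            }
            dend = cluster_samples(norm_matrix)
            (out_dir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
            pca = pca_samples(norm_matrix)
            summary["pca"] = {
                "explained_variance_ratio": np.round(
                    pca.explained_variance_ratio, 6
                ).tolist(),
                "scores": {
                    sid: np.round(pca.scores[i], 6).tolist()
                    for i, sid in enumerate(pca.sample_ids)
                },
                "degenerate": pca.degenerate,
            }
        except MeripQCError as e:
            _skip(skipped, "multisample", e, cfg.strict)

    mean_sd_curves = {}
    for c in counts:
        try:
            mean_sd_curves[c.sample_id] = gene_mean_sd(c, bin_index)
        except MeripQCError as e:
            _skip(skipped, f"mean_sd:{c.sample_id}", e, cfg.strict)
    summary["gene_mean_sd"] = {
        sid: {
            "n_genes": len(c.gene_ids),
            "grid": np.round(c.grid, 6).tolist(),
            "fitted": np.round(c.fitted, 6).tolist(),
        }
        for sid, c in mean_sd_curves.items()
    }

    consistency = {}
    if norm_matrix is not None:
        for role, group in (("IP", ip_counts), ("Input", input_counts)):
            if len(group) >= 2:
                try:
                    consistency[role] = replicate_consistency(
                        norm_matrix, [c.sample_id for c in group]
                    )
                except MeripQCError as e:
                    _skip(skipped, f"consistency:{role}", e, cfg.strict)
    summary["consistency"] = {
        role: {
            "samples": c.sample_ids,
            "grid": np.round(c.grid, 6).tolist(),
            "fitted": np.round(c.fitted, 6).tolist(),
        }
        for role, c in consistency.items()
    }

    summary["skipped_sections"] = dict(skipped)

    # -- figures -----------------------------------------------------------
    if cfg.make_plots:
        for sid, m in metagenes.items():
            figures[f"metagene {sid}"] = plotting.plot_metagene(
                m, fig_dir / f"metagene_{sid}.png"
            )
        for sid, r in eses_results.items():
            figures[f"ESES {sid}"] = plotting.plot_eses_curves(
                r, sid, fig_dir / f"eses_{sid}.png"
            )
        if ctest_results:
            figures["C-test profiles"] = plotting.plot_ctest_profiles(
                ctest_results, fig_dir / "ctest.png"
            )
        if hist_rows:
            figures["coverage histogram"] = plotting.plot_coverage_histogram(
                hist_rows, fig_dir / "coverage_histogram.png"
            )
        if dend is not None:
            figures["dendrogram"] = plotting.plot_dendrogram(
                dend, fig_dir / "dendrogram.png"
            )
        if pca is not None and not pca.degenerate:
            figures["PCA"] = plotting.plot_pca(pca, fig_dir / "pca.png")
        if mean_sd_curves:
            figures["gene mean-SD"] = plotting.plot_mean_sd(
                mean_sd_curves, fig_dir / "mean_sd.png"
            )
        if consistency:
            figures["replicate consistency"] = plotting.plot_consistency(
                consistency, fig_dir / "consistency.png"
            )

    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    html_path = out_dir / "report.html"
    html_path.write_text(_render_html(summary, figures))
    return QCReport(
        config=cfg, summary=summary, html_path=html_path, json_path=json_path,
        skipped=skipped,
    )


def _skip(skipped: dict, section: str, err: Exception, strict: bool) -> None:
    if strict:
        raise MeripQCError(f"section {section!r} failed: {err}") from err
    skipped[section] = str(err)


# ---------------------------------------------------------------------------
# TSV tables


def _write_region_table(rows, path):
    cols = ["exon", "intron", "nongenic", "utr5", "cds", "utr3"]
    with open(path, "w") as fh:
        fh.write("sample_id\ttotal\t" + "\t".join(f"{c}\t{c}_pct" for c in cols) + "\n")
        for r in rows:
            cells = [r.sample_id, str(r.total)]
            for c in cols:
                cells += [str(r.counts[c]), f"{r.percents[c]:.2f}"]
            fh.write("\t".join(cells) + "\n")


def _write_histogram_table(rows, path):
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(COVERAGE_CLASSES) + "\n")
        for r in rows:
            fh.write(
                r.sample_id
                + "\t"
                + "\t".join(f"{100 * r.class_fractions[c]:.2f}" for c in COVERAGE_CLASSES)
                + "\n"
            )


def _write_eses_table(eses_results, verdicts, path):
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tenriched_region_pct\tscale_factor\tsignal_read_pct\toverall\n"
        )
        for sid, r in eses_results.items():
            v = verdicts.get(sid)
            fh.write(
                f"{sid}\t{100 * r.enriched_fraction:.2f}\t{r.scale_factor:.4f}\t"
                f"{100 * r.signal_read_fraction:.2f}\t"
                f"{v.overall if v else 'NA'}\n"
            )


# ---------------------------------------------------------------------------
# HTML rendering (stdlib templates; figures embedded as base64 PNG)


def _table(headers, rows) -> str:
    head = "".join(f"<th>{html.escape(str(h))}</th>" for h in headers)
    body = "".join(
        "<tr>" + "".join(f"<td>{html.escape(str(c))}</td>" for c in row) + "</tr>"
        for row in rows
    )
    return f"<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>"


def _render_html(summary: dict, figures: dict[str, Path]) -> str:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>MeRIP-seq QC report</title>",
        "<style>body{font-family:sans-serif;margin:2em;max-width:1000px}"
        "table{border-collapse:collapse;margin:1em 0}"
        "td,th{border:1px solid #999;padding:3px 8px;font-size:13px}"
        "h2{border-bottom:1px solid #ccc}.flagged{color:#b00}"
        ".within{color:#070}</style></head><body>",
        "<h1>MeRIP-seq quality assessment report</h1>",
    ]
    meta = summary["meta"]
    parts.append(f"<p>meripqc version {html.escape(meta['version'])}</p>")
    parts.append("<h2>Run parameters</h2>")
    parts.append(
        _table(
            ["parameter", "value"],
            sorted((k, v) for k, v in meta["parameters"].items()),
        )
    )

    parts.append("<h2>Reads aligned to genomic regions</h2>")
    rows = []
    for sid, r in summary["region_stats"].items():
        p, c = r["percents"], r["counts"]
        rows.append(
            [
                sid,
                r["total"],
                f"{c['exon']} ({p['exon']:.2f}%)",
                f"{c['intron']} ({p['intron']:.2f}%)",
                f"{c['nongenic']} ({p['nongenic']:.2f}%)",
                f"{c['utr5']} ({p['utr5']:.2f}%)",
                f"{c['cds']} ({p['cds']:.2f}%)",
                f"{c['utr3']} ({p['utr3']:.2f}%)",
            ]
        )
    parts.append(
        _table(
            ["Sample", "Total", "Exon", "Intron", "Non-genic", "5'UTR", "CDS", "3'UTR"],
            rows,
        )
    )

    parts.append("<h2>Exonic bins by read coverage</h2>")
    rows = [
        [sid] + [f"{100 * h[c]:.2f}%" for c in COVERAGE_CLASSES]
        for sid, h in summary["coverage_histogram"].items()
    ]
    parts.append(_table(["Sample"] + list(COVERAGE_CLASSES), rows))

    parts.append("<h2>Immunoprecipitation efficiency (ESES)</h2>")
    rows = []
    for sid, r in summary["eses"].items():
        v = summary["verdicts"].get(sid, {})
        rows.append(
            [
                sid,
                f"{r['enriched_region_pct']:.2f}%",
                f"{r['scale_factor']:.4f}",
                f"{r['signal_read_pct']:.2f}%",
                v.get("overall", "NA"),
            ]
        )
    parts.append(
        _table(
            ["Sample", "Enriched region", "Scale factor", "Signal reads", "Verdict"],
            rows,
        )
    )
    rng = GOOD_QUALITY_RANGES
    parts.append(
        "<p>Good-quality reference ranges: enriched region "
        f"{rng['enriched_region_pct'][0]:g}&ndash;{rng['enriched_region_pct'][1]:g}%, "
        f"scale factor {rng['scale_factor'][0]:g}&ndash;{rng['scale_factor'][1]:g}, "
        f"signal reads {rng['signal_read_pct'][0]:g}&ndash;{rng['signal_read_pct'][1]:g}% "
        "(survey of 61 published m6A-seq IP samples).</p>"
    )

    if summary.get("skipped_sections"):
        parts.append("<h2>Skipped sections</h2>")
        parts.append(
            _table(
                ["section", "reason"],
                sorted(summary["skipped_sections"].items()),
            )
        )

    for title, path in figures.items():
        data = base64.b64encode(Path(path).read_bytes()).decode()
        parts.append(f"<h2>{html.escape(title)}</h2>")
        parts.append(f"<img src='data:image/png;base64,{data}' style='max-width:100%'>")

    parts.append("</body></html>")
    return "".join(parts)
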