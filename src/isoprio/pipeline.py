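"""End-to-end per-gene workflow: parse, normalize, categorize, sweep, filter,
rank, and write tables, figures and reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as iso_io
from .categories import category_partition
from .expression import (
    FilterConfig,
    NflrMatrix,
    apply_filters,
    compute_nflr,
    rank_transcripts,
    summarize_nflr,
    sweep_detection_counts,
)
from .model import Dataset, SourceDialect
from .report import TranscriptReport, build_reports
from .viz import (
    plot_category_counts,
    plot_category_expression,
    plot_ranked_transcripts,
    plot_threshold_curve,
    render_gene_report,
    summarize_categories,
)

logger = logging.getLogger("isoprio")


class PipelineError(RuntimeError):
    """A pipeline-level failure with a user-facing message."""


@dataclass
class RunConfig:
    """Everything one invocation needs: inputs, thresholds, outputs."""

    classification: Path
    gene_list: Path
    outdir: Path
    dialect: SourceDialect = SourceDialect.SQANTI3
    counts: Optional[Path] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    figure_format: str = "svg"
    make_report: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.figure_format not in ("svg", "png"):
            raise ValueError("figure_format must be 'svg' or 'png'")


def _configure_logging(outdir: Path, level: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("isoprio")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    # replace any handlers from a previous in-process run
    for h in list(root.handlers):
        root.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        root.addHandler(handler)


def load_dataset(config: RunConfig) -> tuple[Dataset, set[str]]:
    genes = iso_io.read_gene_list(config.gene_list)
    if config.dialect is SourceDialect.TALON:
        dataset = iso_io.read_talon_abundance(config.classification, gene_list=genes)
    else:
        dataset = iso_io.read_sqanti_classification(
            config.classification, counts_path=config.counts, gene_list=genes
        )
    return dataset, genes


def subset_gene(nflr: NflrMatrix, gene: str) -> NflrMatrix:
    """Restrict an NFLR matrix to one gene's transcripts (for per-gene sweeps
    and figures)."""
    rows = nflr.gene_rows()[gene]
    ids = [nflr.transcript_ids[i] for i in rows]
    return NflrMatrix(
        transcript_ids=ids,
        sample_ids=list(nflr.sample_ids),
        nflr=nflr.nflr[rows, :],
        gene_of={t: gene for t in ids},
        zero_total_flags={gene: nflr.zero_total_flags[gene]},
    )


def analyse(dataset: Dataset, filters: FilterConfig) -> list[TranscriptReport]:
    """Run the analytical core (no file output): NFLR normalization,
    categorization, filtering and ranking, joined into transcript reports."""
    nflr = compute_nflr(dataset.flr)
    summary = summarize_nflr(nflr)
    categories = category_partition(dataset)
    verdicts = apply_filters(nflr, summary, filters)
    ranks = rank_transcripts(summary, nflr.gene_of)
    return build_reports(dataset, nflr, summary, categories, verdicts, ranks)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Raises :class:`PipelineError` when no candidate gene is present in the
    input.  Per gene, writes the transcript table, four or more figures and
    (optionally) a self-contained HTML report; a cross-gene master table
    collects every transcript report.
    """
    _configure_logging(config.outdir, config.log_level)
    dataset, genes = load_dataset(config)
    present = set(dataset.flr.gene_of.values())
    if genes and not (genes & present):
        raise PipelineError(
            "no candidate gene found in the input; missing: " + ", ".join(sorted(genes))
        )
    missing = genes - present
    if missing:
        logger.warning("candidate gene(s) absent from input: %s", ", ".join(sorted(missing)))

    nflr = compute_nflr(dataset.flr)
    summary = summarize_nflr(nflr)
    categories = category_partition(dataset)
    verdicts = apply_filters(nflr, summary, config.filters)
    ranks = rank_transcripts(summary, nflr.gene_of)
    reports = build_reports(dataset, nflr, summary, categories, verdicts, ranks)

    iso_io.write_transcript_table(reports, config.outdir / "transcript_reports.tsv")

    ext = config.figure_format
    for gene in dataset.flr.genes():
        gene_dir = config.outdir / gene
        gene_dir.mkdir(parents=True, exist_ok=True)
        gene_reports = [r for r in reports if r.gene_id == gene]
        gene_nflr = subset_gene(nflr, gene)
        curve = sweep_detection_counts(gene_nflr, config.filters.sweep_grid)
        summaries = summarize_categories(gene_reports, dataset.flr)

        iso_io.write_transcript_table(gene_reports, gene_dir / "transcripts.tsv")
        figures = [
            ("Transcript detection vs expression threshold", gene_dir / f"threshold_curve.{ext}"),
            ("Detection per sample", gene_dir / f"threshold_curve_per_sample.{ext}"),
            ("Transcripts detected per category (pre-filter)", gene_dir / f"category_counts_prefilter.{ext}"),
            ("Transcripts retained per category (post-filter)", gene_dir / f"category_counts_postfilter.{ext}"),
            ("Expression by category", gene_dir / f"category_expression.{ext}"),
            ("Ranked transcripts", gene_dir / f"ranked_transcripts.{ext}"),
        ]
        plot_threshold_curve(curve, figures[0][1], per_sample=False)
        plot_threshold_curve(curve, figures[1][1], per_sample=True)
        plot_category_counts(summaries, figures[2][1], post_filter=False)
        plot_category_counts(summaries, figures[3][1], post_filter=True)
        plot_category_expression(gene_reports, figures[4][1])
        plot_ranked_transcripts(gene_reports, figures[5][1])
        if config.make_report:
            render_gene_report(
                gene, gene_reports, summaries, curve, gene_dir / "report.html",
                figure_files=figures,
            )

        n_pass = sum(r.verdict.passed for r in gene_reports)
        logger.info(
            "gene %s: %d transcripts, %d pass filters", gene, len(gene_reports), n_pass
        )
    return config.outdir


def run_sweep(config: RunConfig) -> Path:
    """Sweep-only mode: per-gene detection curves and figures, no filtering.

    A decision aid for choosing thresholds before a filtered run.
    """
    _configure_logging(config.outdir, config.log_level)
    dataset, genes = load_dataset(config)
    present = set(dataset.flr.gene_of.values())
    if genes and not (genes & present):
        raise PipelineError(
            "no candidate gene found in the input; missing: " + ", ".join(sorted(genes))
        )
    nflr = compute_nflr(dataset.flr)
    ext = config.figure_format
    for gene in dataset.flr.genes():
        gene_dir = config.outdir / gene
        gene_dir.mkdir(parents=True, exist_ok=True)
        curve = sweep_detection_counts(subset_gene(nflr, gene), config.filters.sweep_grid)
        plot_threshold_curve(curve, gene_dir / f"threshold_curve.{ext}", per_sample=False)
        plot_threshold_curve(
            curve, gene_dir / f"threshold_curve_per_sample.{ext}", per_sample=True
        )
        np.savetxt(
            gene_dir / "threshold_curve.tsv",
            np.column_stack([curve.thresholds, curve.mean_count, curve.sd_count]),
            delimiter="\t",
            header="threshold\tmean_detected\tsd_detected",
            comments="",
            fmt="%.4f",
        )
    return config.outdir
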