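"""Per-gene summaries and figures.

Four figure types mirror how a targeted isoform study is read:

* threshold sweep — detected-transcript count as the NFLR threshold varies
  (mean +/- SD band, or one line per sample), with an inset magnifying the
  low-threshold region where detection collapses;
* category counts — transcripts detected per category before filtering
  (mean across samples, SD error bars) and retained after filtering;
* category expression — boxplot of per-transcript-per-sample NFLR by category;
* ranked transcripts — bars of mean NFLR ordered by rank, colored by category.

SVG output is deterministic: a fixed hash salt and no embedded timestamps,
so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import base64
import io as _io
import logging
from dataclasses import dataclass
from html import escape
from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .categories import CATEGORY_ORDER, IsoformCategory
from .expression import ThresholdCurve
from .model import FlrMatrix
from .report import TranscriptReport

logger = logging.getLogger("isoprio")

matplotlib.rcParams["svg.hashsalt"] = "isoprio"

#: Fixed palette so categories are comparable across genes and runs.
CATEGORY_PALETTE: dict[IsoformCategory, str] = {
    IsoformCategory.CODING_KNOWN_COMPLETE_MATCH: "#1b9e77",
    IsoformCategory.CODING_KNOWN_ALT_ENDS: "#66c2a5",
    IsoformCategory.CODING_NOVEL: "#d95f02",
    IsoformCategory.NMD_KNOWN: "#7570b3",
    IsoformCategory.NMD_NOVEL: "#beaed4",
    IsoformCategory.NON_CODING_KNOWN: "#e7298a",
    IsoformCategory.NON_CODING_NOVEL: "#fbb4ae",
}

INSET_REGION = (0.0, 2.0)  # NFLR units magnified by the sweep-plot inset


@dataclass(frozen=True)
class CategorySummary:
    """Detection and retention statistics for one isoform category."""

    category: IsoformCategory
    mean_detected: float
    sd_detected: float
    n_transcripts_post_filter: int


def summarize_categories(
    reports: Sequence[TranscriptReport], flr: FlrMatrix
) -> list[CategorySummary]:
    """Per category: mean/SD across samples of the number of transcripts with
    at least one full-length read, and the count retained by the filter.

    Only categories with at least one reported transcript appear, in display
    order.  Detection is independent of the filter verdict.
    """
    row_of = {t: i for i, t in enumerate(flr.transcript_ids)}
    out = []
    for cat in CATEGORY_ORDER:
        members = [r for r in reports if r.category is cat]
        if not members:
            continue
        rows = np.array([row_of[r.isoform_id] for r in members], dtype=int)
        detected = (flr.counts[rows, :] > 0).sum(axis=0)  # per sample
        sd = float(detected.std(ddof=1)) if flr.n_samples > 1 else 0.0
        out.append(
            CategorySummary(
                category=cat,
                mean_detected=float(detected.mean()),
                sd_detected=sd,
                n_transcripts_post_filter=sum(r.verdict.passed for r in members),
            )
        )
    return out


def _save(fig: plt.Figure, out: str | Path) -> None:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    metadata = {"Date": None} if out.suffix.lower() == ".svg" else None
    fig.savefig(out, metadata=metadata)
    plt.close(fig)


def _draw_threshold_curve(ax: plt.Axes, curve: ThresholdCurve, per_sample: bool) -> None:
    t = curve.thresholds
    if per_sample:
        for j, sid in enumerate(curve.sample_ids):
            ax.plot(t, curve.counts_per_sample[:, j], lw=1.0, label=sid)
    else:
        ax.plot(t, curve.mean_count, color="#2166ac", lw=1.5)
        ax.fill_between(
            t,
            curve.mean_count - curve.sd_count,
            curve.mean_count + curve.sd_count,
            color="#2166ac",
            alpha=0.25,
            linewidth=0,
        )


def plot_threshold_curve(
    curve: ThresholdCurve, out: str | Path, per_sample: bool = False
) -> None:
    """Detected transcripts vs NFLR threshold, with a low-threshold inset.

    ``per_sample=False`` draws the cross-sample mean with a +/- SD band;
    ``per_sample=True`` draws one line per sample with a legend.
    """
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    _draw_threshold_curve(ax, curve, per_sample)
    ax.set_xlabel("NFLR threshold (% of gene expression)")
    ax.set_ylabel("transcripts detected")
    if per_sample:
        ax.legend(fontsize=6, ncol=2, frameon=False)
    lo, hi = INSET_REGION
    mask = (curve.thresholds >= lo) & (curve.thresholds <= hi)
    if mask.sum() >= 2:
        ax.axvspan(lo, hi, color="red", alpha=0.08)
        inset = ax.inset_axes([0.55, 0.55, 0.42, 0.4])
        sub = ThresholdCurve(
            thresholds=curve.thresholds[mask],
            sample_ids=curve.sample_ids,
            counts_per_sample=curve.counts_per_sample[mask, :],
            mean_count=curve.mean_count[mask],
            sd_count=curve.sd_count[mask],
        )
        _draw_threshold_curve(inset, sub, per_sample)
        inset.tick_params(labelsize=6)
    fig.tight_layout()
    _save(fig, out)


def plot_category_counts(
    summaries: Sequence[CategorySummary], out: str | Path, post_filter: bool = False
) -> None:
    """Bar chart of transcripts per category: detected (mean across samples,
    SD error bars) pre-filter, or the retained count post-filter."""
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    if summaries:
        labels = [s.category.label for s in summaries]
        colors = [CATEGORY_PALETTE[s.category] for s in summaries]
        if post_filter:
            heights = [s.n_transcripts_post_filter for s in summaries]
            ax.bar(labels, heights, color=colors)
            ax.set_ylabel("transcripts retained after filtering")
        else:
            heights = [s.mean_detected for s in summaries]
            errs = [s.sd_detected for s in summaries]
            ax.bar(labels, heights, yerr=errs, color=colors, capsize=3)
            ax.set_ylabel("transcripts detected (mean ± SD across samples)")
        ax.tick_params(axis="x", rotation=30)
        plt.setp(ax.get_xticklabels(), ha="right")
    fig.tight_layout()
    _save(fig, out)


def plot_category_expression(
    reports: Sequence[TranscriptReport],
    out: str | Path,
    post_filter_only: bool = False,
) -> None:
    """Boxplot of NFLR values grouped by category; one data point per
    transcript per sample.  All identified transcripts are shown unless
    ``post_filter_only`` restricts to those passing the filter."""
    rows = [r for r in reports if (r.verdict.passed or not post_filter_only)]
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    cats = [c for c in CATEGORY_ORDER if any(r.category is c for r in rows)]
    if cats:
        data = [
            [x for r in rows if r.category is c for x in r.nflr_per_sample] for c in cats
        ]
        sns.boxplot(
            data=data,
            palette=[CATEGORY_PALETTE[c] for c in cats],
            width=0.6,
            fliersize=2,
            ax=ax,
        )
        ax.set_xticks(range(len(cats)), [c.label for c in cats])
        ax.tick_params(axis="x", rotation=30)
        plt.setp(ax.get_xticklabels(), ha="right")
        ax.set_ylabel("NFLR (% of gene expression)")
    fig.tight_layout()
    _save(fig, out)


def plot_ranked_transcripts(reports: Sequence[TranscriptReport], out: str | Path) -> None:
    """Bar chart of one gene's transcripts ordered by rank: bar height is the
    mean NFLR, error bars the SD across samples, color the category."""
    ordered = sorted(reports, key=lambda r: r.rank)
    fig, ax = plt.subplots(figsize=(max(6.5, 0.25 * len(ordered)), 4.5))
    if ordered:
        xs = np.arange(len(ordered))
        ax.bar(
            xs,
            [r.mean_nflr for r in ordered],
            yerr=[r.sd_nflr for r in ordered],
            color=[CATEGORY_PALETTE[r.category] for r in ordered],
            capsize=2,
        )
        ax.set_xticks(xs, [r.isoform_id for r in ordered], rotation=90, fontsize=5)
        ax.set_ylabel("mean NFLR (% of gene expression)")
        ax.set_xlabel("transcripts (ranked by mean NFLR)")
        handles = [
            plt.Rectangle((0, 0), 1, 1, color=CATEGORY_PALETTE[c])
            for c in CATEGORY_ORDER
            if any(r.category is c for r in ordered)
        ]
        labels = [c.label for c in CATEGORY_ORDER if any(r.category is c for r in ordered)]
        ax.legend(handles, labels, fontsize=6, frameon=False)
    fig.tight_layout()
    _save(fig, out)


# ---------------------------------------------------------------------------
# HTML report
# ---------------------------------------------------------------------------


def _fig_to_data_uri(render, fmt: str = "svg") -> str:
    """Render a figure via ``render(path_or_buffer)`` into a data URI."""
    buf = _io.BytesIO()
    render(buf)
    payload = base64.b64encode(buf.getvalue()).decode("ascii")
    mime = "image/svg+xml" if fmt == "svg" else "image/png"
    return f"data:{mime};base64,{payload}"


_REPORT_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{gene_id} — transcript prioritization report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 70em; }}
h1 {{ font-size: 1.4em; }} h2 {{ font-size: 1.1em; margin-top: 2em; }}
table {{ border-collapse: collapse; font-size: 0.85em; }}
th, td {{ border: 1px solid #ccc; padding: 0.3em 0.6em; text-align: right; }}
th {{ background: #f0f0f0; }} td:first-child, td:nth-child(2) {{ text-align: left; }}
img {{ max-width: 100%; }}
.fail {{ color: #b2182b; }} .pass {{ color: #1b7837; }}
</style>
</head>
<body>
<h1>Gene {gene_id}: transcript prioritization report</h1>
<p>{n_transcripts} transcripts across {n_samples} samples;
{n_pass} passed the reproducibility filter.</p>
{figures}
<h2>Ranked transcripts</h2>
<table>
<tr><th>rank</th><th>isoform</th><th>category</th><th>mean NFLR</th>
<th>SD NFLR</th><th>filter</th><th>fail reasons</th></tr>
{table_rows}
</table>
</body>
</html>
"""


def render_gene_report(
    gene_id: str,
    reports: Sequence[TranscriptReport],
    summaries: Sequence[CategorySummary],
    curve: ThresholdCurve,
    out: str | Path,
    figure_files: Optional[Sequence[tuple[str, Path]]] = None,
) -> None:
    """Write a single self-contained HTML report for one gene: all figures
    embedded as data URIs (no external resources) plus the ranked table.

    ``figure_files`` — (title, path) pairs of already-rendered SVG/PNG files
    to embed instead of re-rendering the standard figure set.
    """
    gene_reports = [r for r in reports if r.gene_id == gene_id]
    sections = []

    def embed_file(title: str, path: Path) -> None:
        path = Path(path)
        payload = base64.b64encode(path.read_bytes()).decode("ascii")
        mime = "image/svg+xml" if path.suffix.lower() == ".svg" else "image/png"
        sections.append(
            f"<h2>{escape(title)}</h2>\n"
            f"<img src=\"data:{mime};base64,{payload}\" alt=\"{escape(title)}\">"
        )

    def add_figure(title: str, plot_fn) -> None:
        uri = _fig_to_data_uri(plot_fn)
        sections.append(f"<h2>{escape(title)}</h2>\n<img src=\"{uri}\" alt=\"{escape(title)}\">")

    if figure_files is not None:
        for title, path in figure_files:
            embed_file(title, path)
        return _finish_report(gene_id, gene_reports, sections, out)

    add_figure(
        "Transcript detection vs expression threshold",
        lambda buf: _plot_to_buffer(buf, lambda p: plot_threshold_curve(curve, p, per_sample=False)),
    )
    add_figure(
        "Detection per sample",
        lambda buf: _plot_to_buffer(buf, lambda p: plot_threshold_curve(curve, p, per_sample=True)),
    )
    add_figure(
        "Transcripts detected per category (pre-filter)",
        lambda buf: _plot_to_buffer(buf, lambda p: plot_category_counts(summaries, p, post_filter=False)),
    )
    add_figure(
        "Transcripts retained per category (post-filter)",
        lambda buf: _plot_to_buffer(buf, lambda p: plot_category_counts(summaries, p, post_filter=True)),
    )
    add_figure(
        "Expression by category",
        lambda buf: _plot_to_buffer(buf, lambda p: plot_category_expression(gene_reports, p)),
    )
    add_figure(
        "Ranked transcripts",
        lambda buf: _plot_to_buffer(buf, lambda p: plot_ranked_transcripts(gene_reports, p)),
    )
    _finish_report(gene_id, gene_reports, sections, out)


def _finish_report(
    gene_id: str,
    gene_reports: Sequence[TranscriptReport],
    sections: list[str],
    out: str | Path,
) -> None:
    rows = []
    for r in sorted(gene_reports, key=lambda r: r.rank):
        verdict = (
            '<span class="pass">pass</span>'
            if r.verdict.passed
            else '<span class="fail">fail</span>'
        )
        rows.append(
            "<tr><td>{rank}</td><td>{iso}</td><td>{cat}</td><td>{mean:.4f}</td>"
            "<td>{sd:.4f}</td><td>{verdict}</td><td>{reasons}</td></tr>".format(
                rank=r.rank,
                iso=escape(r.isoform_id),
                cat=escape(r.category.label),
                mean=r.mean_nflr,
                sd=r.sd_nflr,
                verdict=verdict,
                reasons=escape(";".join(sorted(r.verdict.fail_reasons))),
            )
        )

    html = _REPORT_TEMPLATE.format(
        gene_id=escape(gene_id),
        n_transcripts=len(gene_reports),
        n_samples=len(gene_reports[0].sample_ids) if gene_reports else 0,
        n_pass=sum(r.verdict.passed for r in gene_reports),
        figures="\n".join(sections),
        table_rows="\n".join(rows),
    )
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(html, encoding="utf-8")


def _plot_to_buffer(buf: _io.BytesIO, plot_fn) -> None:
    """Run a path-based plot function, capturing the SVG bytes in a buffer."""
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".svg") as tmp:
        plot_fn(tmp.name)
        buf.write(Path(tmp.name).read_bytes())
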