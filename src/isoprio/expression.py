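"""Per-gene expression normalization, threshold sweeps, filtering and ranking.

The central quantity is the normalized full-length-read value
``NFLR_Ti = 100 * FLR_Ti / sum_{T' in gene(T)} FLR_T'i`` — the share (in
percent) of a gene's full-length reads in sample *i* that belong to
transcript *T*.  Normalizing within genes removes between-sample differences
in overall gene expression, so the statistic measures transcript *usage*.
The per-transcript mean across samples, ``NFLR_T``, is the quantity that is
thresholded, swept and ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .model import FlrMatrix

logger = logging.getLogger("isoprio")


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class NflrMatrix:
    """Per-sample normalized expression (percent of gene total), plus flags
    for (gene, sample) cells where the gene had zero reads in that sample.

    Invariant: within a gene and an unflagged sample the NFLR values sum to
    100; in a flagged sample they are all exactly 0.
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    nflr: np.ndarray
    gene_of: dict[str, str]
    zero_total_flags: dict[str, np.ndarray]  # gene -> bool per sample

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_rows(self) -> dict[str, np.ndarray]:
        rows: dict[str, list[int]] = {}
        for i, t in enumerate(self.transcript_ids):
            rows.setdefault(self.gene_of[t], []).append(i)
        return {g: np.array(ix, dtype=int) for g, ix in rows.items()}


@dataclass
class NflrSummary:
    """Per-transcript NFLR statistics across samples.

    ``mean_nflr`` averages over *all* samples, counting samples where the
    gene itself was silent as 0 — a sample without the gene is evidence
    against the transcript's reproducibility, not missing data.  ``sd_nflr``
    is the sample standard deviation (ddof=1; 0 when there is one sample).
    """

    transcript_ids: list[str]
    mean_nflr: np.ndarray
    sd_nflr: np.ndarray
    n_samples_expressed: np.ndarray

    def as_dict(self) -> dict[str, tuple[float, float, int]]:
        return {
            t: (float(self.mean_nflr[i]), float(self.sd_nflr[i]), int(self.n_samples_expressed[i]))
            for i, t in enumerate(self.transcript_ids)
        }


def default_sweep_grid() -> np.ndarray:
    """Dense from 0 to 10 NFLR (step 0.1) where detection collapses fastest,
    then coarse up to 100 (step 1)."""
    return np.unique(np.concatenate([np.arange(0.0, 10.0 + 1e-9, 0.1), np.arange(10.0, 100.0 + 1e-9, 1.0)])).round(10)


@dataclass
class FilterConfig:
    """Thresholds for the reproducibility filter.

    per_sample_threshold : minimum NFLR a transcript must reach in a sample
        for that sample to count toward reproducibility (NFLR units, >= 0).
    min_sample_fraction : fraction of all samples that must reach the
        per-sample threshold; 1.0 reproduces the strict expressed-in-every-
        sample filter of the upstream tools.
    mean_threshold : minimum mean NFLR across all samples.
    sweep_grid : strictly increasing thresholds for detection-curve sweeps.

    All comparisons are inclusive (>=).
    """

    per_sample_threshold: float = 0.3
    min_sample_fraction: float = 0.5
    mean_threshold: float = 0.3
    sweep_grid: np.ndarray = field(default_factory=default_sweep_grid)

    def __post_init__(self) -> None:
        if self.per_sample_threshold < 0 or self.mean_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.min_sample_fraction <= 1.0:
            raise ValueError("min_sample_fraction must lie in [0, 1]")
        self.sweep_grid = np.asarray(self.sweep_grid, dtype=float)
        if self.sweep_grid.size == 0:
            raise ValueError("sweep_grid must be non-empty")
        if (np.diff(self.sweep_grid) <= 0).any() or self.sweep_grid[0] < 0:
            raise ValueError("sweep_grid must be strictly increasing and start >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        """Load thresholds from a YAML file.  Recognized keys:
        per_sample_threshold, min_sample_fraction, mean_threshold, and
        sweep_min/sweep_max/sweep_step for a uniform grid."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("per_sample_threshold", "min_sample_fraction", "mean_threshold"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if any(k in raw for k in ("sweep_min", "sweep_max", "sweep_step")):
            lo = float(raw.get("sweep_min", 0.0))
            hi = float(raw.get("sweep_max", 100.0))
            step = float(raw.get("sweep_step", 0.1))
            kwargs["sweep_grid"] = np.arange(lo, hi + step / 2, step)
        unknown = set(raw) - {
            "per_sample_threshold",
            "min_sample_fraction",
            "mean_threshold",
            "sweep_min",
            "sweep_max",
            "sweep_step",
        }
        if unknown:
            logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        return cls(**kwargs)


FAIL_BELOW_MEAN = "below_mean_threshold"
FAIL_INSUFFICIENT_SAMPLES = "insufficient_samples"


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the reproducibility filter for one transcript."""

    passed: bool
    fail_reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.passed != (len(self.fail_reasons) == 0):
            raise ValueError("passed must be equivalent to an empty fail_reasons set")


@dataclass
class ThresholdCurve:
    """Detected-transcript counts as a function of the NFLR threshold.

    ``counts_per_sample[k, s]`` is the number of transcripts detected in
    sample *s* at threshold ``thresholds[k]``; detection at threshold 0 means
    NFLR > 0 (never-observed transcripts are not detected), and detection at
    t > 0 means NFLR >= t.  Counts are non-increasing in the threshold.
    """

    thresholds: np.ndarray
    sample_ids: list[str]
    counts_per_sample: np.ndarray
    mean_count: np.ndarray
    sd_count: np.ndarray


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_nflr(flr: FlrMatrix) -> NflrMatrix:
    """Normalize FLR counts to percent-of-gene expression per sample.

    For each gene g and sample s the counts of g's transcripts are divided by
    their sum and scaled to 100.  A (gene, sample) cell with zero total reads
    yields NFLR 0 for all of the gene's transcripts and is flagged.
    """
    nflr = np.zeros(flr.counts.shape, dtype=float)
    flags: dict[str, np.ndarray] = {}
    for gene, rows in flr.gene_rows().items():
        block = flr.counts[rows, :].astype(float)
        totals = block.sum(axis=0)
        zero = totals == 0
        if zero.any():
            logger.info(
                "gene %s has zero FLR in %d/%d sample(s)", gene, int(zero.sum()), flr.n_samples
            )
        safe = np.where(zero, 1.0, totals)
        nflr[rows, :] = 100.0 * block / safe
        nflr[np.ix_(rows, np.flatnonzero(zero))] = 0.0
        flags[gene] = zero
    return NflrMatrix(
        transcript_ids=list(flr.transcript_ids),
        sample_ids=list(flr.sample_ids),
        nflr=nflr,
        gene_of=dict(flr.gene_of),
        zero_total_flags=flags,
    )


def summarize_nflr(nflr: NflrMatrix) -> NflrSummary:
    """Mean/SD of NFLR across all samples, and the number of samples in which
    each transcript was observed at all.

    Flagged zero-total samples enter the mean as 0.  SD uses ddof=1 and is 0
    for a single sample.  A transcript is "expressed" in a sample iff its
    NFLR is positive there, which coincides with FLR > 0.
    """
    x = nflr.nflr
    n = x.shape[1]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1) if n > 1 else np.zeros(x.shape[0])
    expressed = (x > 0).sum(axis=1)
    return NflrSummary(
        transcript_ids=list(nflr.transcript_ids),
        mean_nflr=mean,
        sd_nflr=sd,
        n_samples_expressed=expressed.astype(int),
    )


def sweep_detection_counts(nflr: NflrMatrix, grid: Sequence[float]) -> ThresholdCurve:
    """Count detected transcripts per sample at every threshold of the grid.

    Detection is NFLR >= t for t > 0 and NFLR > 0 at t = 0.  The resulting
    per-sample curves are non-increasing; the mean and SD across samples are
    what the summary sweep figure draws.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sweep grid must be non-empty")
    if (np.diff(grid) <= 0).any():
        raise ValueError("sweep grid must be strictly increasing")
    x = nflr.nflr
    counts = np.empty((grid.size, x.shape[1]), dtype=int)
    for k, t in enumerate(grid):
        detected = (x > 0) if t == 0 else (x >= t)
        counts[k, :] = detected.sum(axis=0)
    mean = counts.mean(axis=1)
    sd = counts.std(axis=1, ddof=1) if x.shape[1] > 1 else np.zeros(grid.size)
    return ThresholdCurve(
        thresholds=grid,
        sample_ids=list(nflr.sample_ids),
        counts_per_sample=counts,
        mean_count=mean,
        sd_count=sd,
    )


def apply_filters(
    nflr: NflrMatrix, summary: NflrSummary, config: FilterConfig
) -> dict[str, FilterVerdict]:
    """Apply the two-level reproducibility filter to every transcript.

    A transcript passes iff (a) its mean NFLR across all samples reaches
    ``mean_threshold`` and (b) the fraction of samples (out of the full
    sample count) in which its NFLR reaches ``per_sample_threshold`` is at
    least ``min_sample_fraction``.  Both comparisons are inclusive.
    """
    n = nflr.n_samples
    meets = nflr.nflr >= config.per_sample_threshold
    frac = meets.sum(axis=1) / n
    verdicts: dict[str, FilterVerdict] = {}
    for i, t in enumerate(nflr.transcript_ids):
        reasons = set()
        if summary.mean_nflr[i] < config.mean_threshold:
            reasons.add(FAIL_BELOW_MEAN)
        if frac[i] < config.min_sample_fraction:
            reasons.add(FAIL_INSUFFICIENT_SAMPLES)
        verdicts[t] = FilterVerdict(passed=not reasons, fail_reasons=frozenset(reasons))
    return verdicts


def rank_transcripts(
    summary: NflrSummary, gene_of: Mapping[str, str]
) -> dict[str, int]:
    """Rank transcripts within each gene by mean NFLR, descending.

    Ranks are 1-based and consecutive within a gene.  Ties are broken by
    ascending lexicographic isoform id so ranking is deterministic.
    """
    means = summary.as_dict()
    by_gene: dict[str, list[str]] = {}
    for t in summary.transcript_ids:
        by_gene.setdefault(gene_of[t], []).append(t)
    ranks: dict[str, int] = {}
    for gene, ts in by_gene.items():
        ordered = sorted(ts, key=lambda t: (-means[t][0], t))
        for r, t in enumerate(ordered, start=1):
            ranks[t] = r
    return ranks
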