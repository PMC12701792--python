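"""Per-transcript report records: the unit joining every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .categories import IsoformCategory
from .expression import FilterVerdict, NflrMatrix, NflrSummary
from .model import Dataset


@dataclass(frozen=True)
class TranscriptReport:
    """One transcript's category, expression statistics, rank and filter
    verdict — the row type of every output table."""

    isoform_id: str
    gene_id: str
    category: IsoformCategory
    sample_ids: tuple[str, ...]
    nflr_per_sample: tuple[float, ...]
    mean_nflr: float
    sd_nflr: float
    rank: int
    verdict: FilterVerdict

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if len(self.nflr_per_sample) != len(self.sample_ids):
            raise ValueError("nflr_per_sample length must match sample_ids")


def build_reports(
    dataset: Dataset,
    nflr: NflrMatrix,
    summary: NflrSummary,
    categories: Mapping[str, IsoformCategory],
    verdicts: Mapping[str, FilterVerdict],
    ranks: Mapping[str, int],
) -> list[TranscriptReport]:
    """Join the per-stage outputs into one report per transcript, ordered by
    gene (first appearance) then rank."""
    stats = summary.as_dict()
    index = {t: i for i, t in enumerate(nflr.transcript_ids)}
    reports = []
    for t in nflr.transcript_ids:
        mean, sd, _ = stats[t]
        reports.append(
            TranscriptReport(
                isoform_id=t,
                gene_id=nflr.gene_of[t],
                category=categories[t],
                sample_ids=tuple(nflr.sample_ids),
                nflr_per_sample=tuple(float(x) for x in nflr.nflr[index[t], :]),
                mean_nflr=mean,
                sd_nflr=sd,
                rank=ranks[t],
                verdict=verdicts[t],
            )
        )
    gene_order = {g: i for i, g in enumerate(dict.fromkeys(r.gene_id for r in reports))}
    reports.sort(key=lambda r: (gene_order[r.gene_id], r.rank))
    return reports
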