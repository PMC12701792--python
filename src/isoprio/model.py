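"""Core data model: transcript annotations and full-length-read count matrices.

The unit of analysis is a *characterized isoform*: a transcript model emitted
by an upstream long-read characterization tool (SQANTI3 or TALON) together
with its structural comparison against the reference annotation, an optional
coding/ORF call, an optional nonsense-mediated-decay (NMD) prediction, and a
full-length-read (FLR) count per sample.  All downstream computation is
gene-based, so every transcript carries its parent gene identifier.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("isoprio")


class StructuralCategory(enum.Enum):
    """SQANTI-style structural comparison of an isoform against the reference."""

    FULL_SPLICE_MATCH = "full_splice_match"
    INCOMPLETE_SPLICE_MATCH = "incomplete_splice_match"
    NOVEL_IN_CATALOG = "novel_in_catalog"
    NOVEL_NOT_IN_CATALOG = "novel_not_in_catalog"
    GENIC = "genic"
    ANTISENSE = "antisense"
    FUSION = "fusion"
    INTERGENIC = "intergenic"
    GENIC_INTRON = "genic_intron"
    OTHER = "other"


class Subcategory(enum.Enum):
    """Structural subcategory; only reference_match denotes a complete
    end-to-end match with a reference transcript."""

    REFERENCE_MATCH = "reference_match"
    ALTERNATIVE_3END = "alternative_3end"
    ALTERNATIVE_5END = "alternative_5end"
    ALTERNATIVE_3END5END = "alternative_3end5end"
    MONO_EXON = "mono_exon"
    OTHER = "other"
    NOT_APPLICABLE = "not_applicable"


class CodingStatus(enum.Enum):
    CODING = "coding"
    NON_CODING = "non_coding"
    UNKNOWN = "unknown"


def _canon(token: str) -> str:
    """Canonical spelling for enum matching: case-insensitive, with '-', '_'
    and ' ' treated as equivalent separators."""
    return token.strip().lower().replace("-", "_").replace(" ", "_")


_STRUCTURAL_LOOKUP = {c.value: c for c in StructuralCategory}
_SUBCATEGORY_LOOKUP = {c.value: c for c in Subcategory}
# spellings seen in the wild beyond the canonical underscore form
_SUBCATEGORY_LOOKUP.update(
    {
        "alternative_3end5end": Subcategory.ALTERNATIVE_3END5END,
        "alternative_5end3end": Subcategory.ALTERNATIVE_3END5END,
        "3prime_fragment": Subcategory.OTHER,
    }
)


def parse_structural_category(raw: str) -> StructuralCategory:
    """Map a free-text structural category cell onto the enum.

    Unrecognized values degrade to OTHER with a warning rather than failing:
    upstream tools add categories between versions.
    """
    key = _canon(raw)
    if key in _STRUCTURAL_LOOKUP:
        return _STRUCTURAL_LOOKUP[key]
    logger.warning("unrecognized structural category %r mapped to 'other'", raw)
    return StructuralCategory.OTHER


def parse_subcategory(raw: str) -> Subcategory:
    key = _canon(raw)
    if key in ("", "na", "nan", "none"):
        return Subcategory.NOT_APPLICABLE
    if key in _SUBCATEGORY_LOOKUP:
        return _SUBCATEGORY_LOOKUP[key]
    logger.warning("unrecognized subcategory %r mapped to 'other'", raw)
    return Subcategory.OTHER


def parse_coding_status(raw: str) -> CodingStatus:
    key = _canon(raw)
    if key == "coding":
        return CodingStatus.CODING
    if key in ("non_coding", "noncoding"):
        return CodingStatus.NON_CODING
    if key in ("", "na", "nan", "none", "unknown"):
        return CodingStatus.UNKNOWN
    logger.warning("unrecognized coding status %r mapped to 'unknown'", raw)
    return CodingStatus.UNKNOWN


def parse_nmd(raw: str) -> Optional[bool]:
    """Parse an NMD-prediction cell; blank/NA means 'not assessed' (None).

    SQANTI3 leaves the field blank for non-coding isoforms, so None is a
    routine value, not an error.
    """
    key = _canon(raw)
    if key in ("true", "t", "yes", "1"):
        return True
    if key in ("false", "f", "no", "0"):
        return False
    if key in ("", "na", "nan", "none", "unknown"):
        return None
    logger.warning("unrecognized NMD value %r mapped to unknown", raw)
    return None


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One characterized isoform: identifiers plus the structural, coding and
    NMD calls inherited from the upstream characterization tool.

    ``nmd_predicted`` is a tristate: True / False / None (not assessed).
    """

    isoform_id: str
    gene_id: str
    structural_category: StructuralCategory
    subcategory: Subcategory = Subcategory.NOT_APPLICABLE
    coding_status: CodingStatus = CodingStatus.UNKNOWN
    nmd_predicted: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.isoform_id:
            raise ValueError("isoform_id must be non-empty")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if (
            self.subcategory is Subcategory.REFERENCE_MATCH
            and self.structural_category is not StructuralCategory.FULL_SPLICE_MATCH
        ):
            raise ValueError(
                "subcategory reference_match requires a full_splice_match "
                f"structural category (isoform {self.isoform_id})"
            )


@dataclass
class FlrMatrix:
    """Non-negative integer full-length-read counts, transcripts x samples.

    Row order follows the source file; ``gene_of`` maps every transcript to
    its gene so that all normalization is performed within genes.
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.transcript_ids)} transcripts x {len(self.sample_ids)} samples"
            )
        if self.counts.size and (
            not np.issubdtype(self.counts.dtype, np.integer) or (self.counts < 0).any()
        ):
            raise ValueError("FLR counts must be non-negative integers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        missing = [t for t in self.transcript_ids if t not in self.gene_of]
        if missing:
            raise ValueError(f"transcripts without a gene mapping: {missing[:5]}")

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def genes(self) -> list[str]:
        """Gene ids in order of first appearance."""
        seen: dict[str, None] = {}
        for t in self.transcript_ids:
            seen.setdefault(self.gene_of[t], None)
        return list(seen)

    def gene_rows(self) -> dict[str, np.ndarray]:
        """Row indices of each gene's transcripts, in file order."""
        rows: dict[str, list[int]] = {}
        for i, t in enumerate(self.transcript_ids):
            rows.setdefault(self.gene_of[t], []).append(i)
        return {g: np.array(ix, dtype=int) for g, ix in rows.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.transcript_ids, columns=self.sample_ids
        )


class SourceDialect(enum.Enum):
    SQANTI3 = "sqanti3"
    TALON = "talon"


@dataclass
class Dataset:
    """A parsed characterization run: annotations plus the FLR count matrix.

    Annotation isoform ids and count-matrix transcript ids coincide as sets;
    ``annotations`` is keyed by isoform id for O(1) lookup.
    """

    annotations: dict[str, TranscriptAnnotation]
    flr: FlrMatrix
    source_dialect: SourceDialect = SourceDialect.SQANTI3

    def __post_init__(self) -> None:
        ann_ids = set(self.annotations)
        flr_ids = set(self.flr.transcript_ids)
        if ann_ids != flr_ids:
            raise ValueError(
                "annotation and count-matrix transcript ids differ: "
                f"{sorted(ann_ids ^ flr_ids)[:5]}"
            )

    @property
    def n_transcripts(self) -> int:
        return self.flr.n_transcripts

    def annotation_rows(self) -> Iterable[TranscriptAnnotation]:
        """Annotations in count-matrix (file) order."""
        return (self.annotations[t] for t in self.flr.transcript_ids)
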