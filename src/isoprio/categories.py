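"""Re-grouping of characterized isoforms into seven interpretable categories.

Structural categories, ORF calls and NMD predictions from the upstream
characterization tool are collapsed into a small set of labels that answer
the questions a geneticist actually asks of a candidate gene: is the isoform
known or novel, is it protein-coding, and if coding, is it a predicted NMD
target (and therefore unlikely to produce protein)?

The seven categories:

==============================  ==========================================
internal value                  display label
==============================  ==========================================
non_coding_novel                non-coding novel
non_coding_known                non-coding known
nmd_novel                       NMD novel
nmd_known                       NMD known
coding_novel                    coding novel
coding_known_complete_match     coding known (complete match)
coding_known_alt_ends           coding known (alternate 3'/5' end)
==============================  ==========================================

"Known" means the isoform fully matches a reference transcript model
(structural category full_splice_match); everything else — including
incomplete splice matches, which truncate the reference model — is "novel".
Within coding known isoforms, only the reference_match subcategory counts as
a complete match; alternative-end and mono-exonic full splice matches land in
the alternate-ends group.
"""

from __future__ import annotations

import enum
import logging
from typing import FrozenSet, Mapping

from .model import (
    CodingStatus,
    Dataset,
    SourceDialect,
    StructuralCategory,
    Subcategory,
    TranscriptAnnotation,
)

logger = logging.getLogger("isoprio")


class IsoformCategory(enum.Enum):
    NON_CODING_NOVEL = "non_coding_novel"
    NON_CODING_KNOWN = "non_coding_known"
    NMD_NOVEL = "nmd_novel"
    NMD_KNOWN = "nmd_known"
    CODING_NOVEL = "coding_novel"
    CODING_KNOWN_COMPLETE_MATCH = "coding_known_complete_match"
    CODING_KNOWN_ALT_ENDS = "coding_known_alt_ends"

    @property
    def label(self) -> str:
        """Display label used in tables and figure legends."""
        return _LABELS[self]

    @property
    def is_known(self) -> bool:
        return self in (
            IsoformCategory.NON_CODING_KNOWN,
            IsoformCategory.NMD_KNOWN,
            IsoformCategory.CODING_KNOWN_COMPLETE_MATCH,
            IsoformCategory.CODING_KNOWN_ALT_ENDS,
        )


_LABELS = {
    IsoformCategory.NON_CODING_NOVEL: "non-coding novel",
    IsoformCategory.NON_CODING_KNOWN: "non-coding known",
    IsoformCategory.NMD_NOVEL: "NMD novel",
    IsoformCategory.NMD_KNOWN: "NMD known",
    IsoformCategory.CODING_NOVEL: "coding novel",
    IsoformCategory.CODING_KNOWN_COMPLETE_MATCH: "coding known (complete match)",
    IsoformCategory.CODING_KNOWN_ALT_ENDS: "coding known (alternate 3'/5' end)",
}

#: Display order used consistently across tables and figures.
CATEGORY_ORDER: tuple[IsoformCategory, ...] = (
    IsoformCategory.CODING_KNOWN_COMPLETE_MATCH,
    IsoformCategory.CODING_KNOWN_ALT_ENDS,
    IsoformCategory.CODING_NOVEL,
    IsoformCategory.NMD_KNOWN,
    IsoformCategory.NMD_NOVEL,
    IsoformCategory.NON_CODING_KNOWN,
    IsoformCategory.NON_CODING_NOVEL,
)

#: Structural categories treated as "known" by default.  Incomplete splice
#: matches are deliberately excluded: an ISM does not fully reproduce any
#: reference transcript model.  Pass a different frozenset to
#: :func:`assign_category` to widen the definition.
DEFAULT_KNOWN_CATEGORIES: FrozenSet[StructuralCategory] = frozenset(
    {StructuralCategory.FULL_SPLICE_MATCH}
)


def assign_category(
    annotation: TranscriptAnnotation,
    known_categories: FrozenSet[StructuralCategory] = DEFAULT_KNOWN_CATEGORIES,
) -> IsoformCategory:
    """Assign one of the seven categories to an annotation.

    The mapping is total and deterministic.  Rules, in priority order:

    1. non-coding (or unassessed) ORF -> non-coding known/novel.  An
       unverified ORF is conservatively *not* promoted to coding.
    2. coding with a positive NMD prediction -> NMD known/novel.
    3. otherwise coding: known isoforms split on whether the subcategory is a
       reference_match (complete match) or any alternative end form; novel
       isoforms are coding novel.  An absent NMD call is treated as negative.
    """
    known = annotation.structural_category in known_categories
    if annotation.coding_status is not CodingStatus.CODING:
        return (
            IsoformCategory.NON_CODING_KNOWN if known else IsoformCategory.NON_CODING_NOVEL
        )
    if annotation.nmd_predicted is True:
        return IsoformCategory.NMD_KNOWN if known else IsoformCategory.NMD_NOVEL
    if not known:
        return IsoformCategory.CODING_NOVEL
    if annotation.subcategory is Subcategory.REFERENCE_MATCH:
        return IsoformCategory.CODING_KNOWN_COMPLETE_MATCH
    return IsoformCategory.CODING_KNOWN_ALT_ENDS


def category_partition(
    dataset: Dataset,
    known_categories: FrozenSet[StructuralCategory] = DEFAULT_KNOWN_CATEGORIES,
) -> dict[str, IsoformCategory]:
    """Categorize every isoform of a dataset.

    TALON abundance files carry no ORF or NMD predictions, so every TALON
    isoform necessarily falls into a non-coding (structure-only) category; a
    warning flags that the partition reflects structure only.
    """
    if dataset.source_dialect is SourceDialect.TALON:
        logger.warning(
            "TALON input provides no coding/NMD predictions: categories are "
            "structure-only (known vs novel within the non-coding groups)"
        )
    return {
        ann.isoform_id: assign_category(ann, known_categories)
        for ann in dataset.annotation_rows()
    }
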