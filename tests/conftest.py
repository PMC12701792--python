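import numpy as np
import pytest

from isoprio.model import (
    CodingStatus,
    Dataset,
    FlrMatrix,
    SourceDialect,
    StructuralCategory,
    Subcategory,
    TranscriptAnnotation,
)


@pytest.fixture
def worked_example_flr() -> FlrMatrix:
    """Five transcripts of one gene in one sample with counts 40/20/10/10/10
    (gene total 90), the canonical normalization example."""
    ids = ["A", "B", "C", "D", "E"]
    return FlrMatrix(
        transcript_ids=ids,
        sample_ids=["s1"],
        counts=np.array([[40], [20], [10], [10], [10]]),
        gene_of={t: "G1" for t in ids},
    )


def make_annotation(
    isoform_id="tx1",
    gene_id="G1",
    structural=StructuralCategory.FULL_SPLICE_MATCH,
    sub=Subcategory.REFERENCE_MATCH,
    coding=CodingStatus.CODING,
    nmd=False,
) -> TranscriptAnnotation:
    return TranscriptAnnotation(
        isoform_id=isoform_id,
        gene_id=gene_id,
        structural_category=structural,
        subcategory=sub,
        coding_status=coding,
        nmd_predicted=nmd,
    )


def make_dataset(counts, gene_of, sample_ids=None, annotations=None) -> Dataset:
    """Build a SQANTI3-source dataset from a count matrix; annotations default
    to coding FSM reference matches."""
    counts = np.asarray(counts)
    ids = sorted(gene_of)
    if sample_ids is None:
        sample_ids = [f"s{j+1}" for j in range(counts.shape[1])]
    flr = FlrMatrix(
        transcript_ids=ids, sample_ids=sample_ids, counts=counts, gene_of=dict(gene_of)
    )
    if annotations is None:
        annotations = {
            t: make_annotation(isoform_id=t, gene_id=gene_of[t]) for t in ids
        }
    return Dataset(annotations=annotations, flr=flr, source_dialect=SourceDialect.SQANTI3)
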