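"""Readers and writers for the supported tabular dialects.

Two upstream characterization dialects are supported, both tab-separated:

* SQANTI3 ``*_classification.txt`` — one row per isoform with structural
  category, subcategory, ORF ("coding") and NMD predictions.  Full-length
  read counts are either embedded (a single ``FL`` column, or one ``FL.<sample>``
  column per sample) or supplied as a companion counts table (isoform column
  plus one numeric column per sample); a companion table overrides embedded
  columns.
* TALON ``*_abundance.tsv`` — annotation columns followed by one integer
  count column per dataset.  TALON reports transcript novelty but no ORF or
  NMD predictions, so those fields read as unknown.

All files are UTF-8 with Unix newlines; floats in output tables are rendered
with 4 decimal places.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CodingStatus,
    Dataset,
    FlrMatrix,
    SourceDialect,
    StructuralCategory,
    Subcategory,
    TranscriptAnnotation,
    parse_coding_status,
    parse_nmd,
    parse_structural_category,
    parse_subcategory,
)
from .report import TranscriptReport

logger = logging.getLogger("isoprio")

FLOAT_FMT = "%.4f"


class FormatError(ValueError):
    """The file exists but does not conform to the expected dialect."""


class InputError(ValueError):
    """The inputs as a whole are unusable (missing counts, no genes, ...)."""


SQANTI_REQUIRED_COLUMNS = (
    "isoform",
    "associated_gene",
    "structural_category",
    "subcategory",
    "coding",
    "predicted_NMD",
)

#: TALON annotation columns recognized by name; count columns are everything
#: after the last of these that appears (TALON column sets vary by version).
TALON_ANNOTATION_COLUMNS = (
    "gene_ID",
    "transcript_ID",
    "annot_gene_id",
    "annot_transcript_id",
    "annot_gene_name",
    "annot_transcript_name",
    "n_exons",
    "length",
    "gene_novelty",
    "transcript_novelty",
    "ISM_subtype",
)

TALON_NOVELTY_MAP = {
    "known": StructuralCategory.FULL_SPLICE_MATCH,
    "ism": StructuralCategory.INCOMPLETE_SPLICE_MATCH,
    "nic": StructuralCategory.NOVEL_IN_CATALOG,
    "nnc": StructuralCategory.NOVEL_NOT_IN_CATALOG,
    "antisense": StructuralCategory.ANTISENSE,
    "intergenic": StructuralCategory.INTERGENIC,
    "genomic": StructuralCategory.GENIC,
}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # all cells read as strings; numeric validation is explicit so errors can
    # name the offending row
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file has no header row") from exc


def _to_counts(df: pd.DataFrame, path: str | Path) -> np.ndarray:
    """Validate and convert string count cells to a non-negative int matrix."""
    out = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric count {cell!r} in column {col!r}, data row {i + 1}"
                ) from None
            if value < 0 or value != int(value):
                raise FormatError(
                    f"{path}: count {cell!r} in column {col!r}, data row {i + 1} "
                    "is not a non-negative integer"
                )
            out[i, j] = int(value)
    return out


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text candidate gene list: one identifier per line,
    blank lines and ``#`` comments ignored, surrounding whitespace stripped."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read gene list {path}: {exc}") from exc
    genes = set()
    for line in text.splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            genes.add(token)
    return genes


def _filter_genes(df: pd.DataFrame, gene_col: str, gene_list: set[str]) -> pd.DataFrame:
    if not gene_list:
        return df
    present = set(df[gene_col])
    for gene in sorted(gene_list - present):
        logger.info("candidate gene %s has no transcripts in the input", gene)
    kept = df[df[gene_col].isin(gene_list)]
    logger.debug(
        "gene filter kept %d/%d transcripts for %d candidate gene(s)",
        len(kept),
        len(df),
        len(gene_list),
    )
    return kept


def read_sqanti_classification(
    classification_path: str | Path,
    counts_path: Optional[str | Path] = None,
    gene_list: Optional[set[str]] = None,
) -> Dataset:
    """Parse a SQANTI3 classification table (plus optional counts table) into
    a :class:`Dataset`, restricted to the candidate genes.

    An empty/None ``gene_list`` keeps every isoform.  Row order of the file
    is preserved.  Unrecognized category strings degrade to the ``other`` /
    ``unknown`` enum values with a warning.
    """
    gene_list = gene_list or set()
    df = _read_tsv(classification_path)
    for col in SQANTI_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{classification_path}: missing required column {col!r}")
    dup = df["isoform"][df["isoform"].duplicated()]
    if not dup.empty:
        raise FormatError(
            f"{classification_path}: duplicate isoform id(s): {sorted(set(dup))[:5]}"
        )
    df = _filter_genes(df, "associated_gene", gene_list)

    if counts_path is not None:
        counts_df = _read_tsv(counts_path)
        id_col = "isoform" if "isoform" in counts_df.columns else counts_df.columns[0]
        counts_df = counts_df.set_index(id_col)
        missing = [t for t in df["isoform"] if t not in counts_df.index]
        if missing:
            raise FormatError(
                f"{counts_path}: no counts for isoform(s) {missing[:5]}"
            )
        sample_ids = list(counts_df.columns)
        counts = _to_counts(counts_df.loc[list(df["isoform"])], counts_path)
    else:
        fl_cols = [c for c in df.columns if c.startswith("FL.")]
        if fl_cols:
            sample_ids = [c[len("FL.") :] for c in fl_cols]
            counts = _to_counts(df[fl_cols], classification_path)
        elif "FL" in df.columns:
            sample_ids = ["sample_1"]
            counts = _to_counts(df[["FL"]], classification_path)
        else:
            raise InputError(
                f"{classification_path}: no embedded FL count columns and no "
                "counts table supplied"
            )

    annotations: dict[str, TranscriptAnnotation] = {}
    gene_of: dict[str, str] = {}
    for row in df.itertuples(index=False):
        ann = TranscriptAnnotation(
            isoform_id=row.isoform,
            gene_id=row.associated_gene,
            structural_category=parse_structural_category(row.structural_category),
            subcategory=parse_subcategory(row.subcategory),
            coding_status=parse_coding_status(row.coding),
            nmd_predicted=parse_nmd(row.predicted_NMD),
        )
        annotations[ann.isoform_id] = ann
        gene_of[ann.isoform_id] = ann.gene_id

    flr = FlrMatrix(
        transcript_ids=list(df["isoform"]),
        sample_ids=sample_ids,
        counts=counts,
        gene_of=gene_of,
    )
    return Dataset(annotations=annotations, flr=flr, source_dialect=SourceDialect.SQANTI3)


def read_talon_abundance(
    path: str | Path, gene_list: Optional[set[str]] = None
) -> Dataset:
    """Parse a TALON abundance table into a :class:`Dataset`.

    Structural categories are derived from the transcript-novelty column;
    coding status and NMD prediction are unknown (TALON does not call them).
    """
    gene_list = gene_list or set()
    df = _read_tsv(path)
    if "transcript_novelty" not in df.columns:
        raise FormatError(f"{path}: missing required column 'transcript_novelty'")
    tx_col = next(
        (c for c in ("annot_transcript_id", "transcript_ID") if c in df.columns), None
    )
    if tx_col is None:
        raise FormatError(
            f"{path}: missing a transcript id column (annot_transcript_id or transcript_ID)"
        )
    gene_col = next(
        (c for c in ("annot_gene_name", "annot_gene_id", "gene_ID") if c in df.columns),
        None,
    )
    if gene_col is None:
        raise FormatError(
            f"{path}: missing a gene id column (annot_gene_name, annot_gene_id or gene_ID)"
        )
    annotated = [i for i, c in enumerate(df.columns) if c in TALON_ANNOTATION_COLUMNS]
    count_cols = list(df.columns[max(annotated) + 1 :])
    if not count_cols:
        raise InputError(f"{path}: no count columns after the annotation columns")

    dup = df[tx_col][df[tx_col].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate transcript id(s): {sorted(set(dup))[:5]}")
    df = _filter_genes(df, gene_col, gene_list)
    counts = _to_counts(df[count_cols], path)

    annotations: dict[str, TranscriptAnnotation] = {}
    gene_of: dict[str, str] = {}
    for _, row in df.iterrows():
        novelty = row["transcript_novelty"].strip().lower()
        category = TALON_NOVELTY_MAP.get(novelty, StructuralCategory.OTHER)
        if novelty not in TALON_NOVELTY_MAP:
            logger.warning("unrecognized transcript novelty %r mapped to 'other'", novelty)
        ann = TranscriptAnnotation(
            isoform_id=row[tx_col],
            gene_id=row[gene_col],
            structural_category=category,
            subcategory=Subcategory.NOT_APPLICABLE,
            coding_status=CodingStatus.UNKNOWN,
            nmd_predicted=None,
        )
        annotations[ann.isoform_id] = ann
        gene_of[ann.isoform_id] = ann.gene_id

    flr = FlrMatrix(
        transcript_ids=list(df[tx_col]),
        sample_ids=count_cols,
        counts=counts,
        gene_of=gene_of,
    )
    return Dataset(annotations=annotations, flr=flr, source_dialect=SourceDialect.TALON)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _serialize_nmd(value: Optional[bool]) -> str:
    return "NA" if value is None else ("TRUE" if value else "FALSE")


def _serialize_coding(value: CodingStatus) -> str:
    return "" if value is CodingStatus.UNKNOWN else value.value


def write_sqanti_classification(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the SQANTI3 classification dialect with embedded
    ``FL.<sample>`` count columns (round-trips through
    :func:`read_sqanti_classification`)."""
    flr = dataset.flr
    rows = []
    for i, ann in enumerate(dataset.annotation_rows()):
        row = {
            "isoform": ann.isoform_id,
            "associated_gene": ann.gene_id,
            "structural_category": ann.structural_category.value,
            "subcategory": ann.subcategory.value,
            "coding": _serialize_coding(ann.coding_status),
            "predicted_NMD": _serialize_nmd(ann.nmd_predicted),
        }
        for j, s in enumerate(flr.sample_ids):
            row[f"FL.{s}"] = int(flr.counts[i, j])
        rows.append(row)
    cols = list(SQANTI_REQUIRED_COLUMNS) + [f"FL.{s}" for s in flr.sample_ids]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


_TALON_NOVELTY_INVERSE = {
    StructuralCategory.FULL_SPLICE_MATCH: "Known",
    StructuralCategory.INCOMPLETE_SPLICE_MATCH: "ISM",
    StructuralCategory.NOVEL_IN_CATALOG: "NIC",
    StructuralCategory.NOVEL_NOT_IN_CATALOG: "NNC",
    StructuralCategory.ANTISENSE: "Antisense",
    StructuralCategory.INTERGENIC: "Intergenic",
    StructuralCategory.GENIC: "Genomic",
}


def write_talon_abundance(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in the TALON abundance dialect.

    Structural categories without a TALON novelty label serialize as
    ``Other``; coding/NMD information is not representable in this dialect.
    """
    flr = dataset.flr
    rows = []
    for i, ann in enumerate(dataset.annotation_rows()):
        row = {
            "gene_ID": ann.gene_id,
            "transcript_ID": ann.isoform_id,
            "annot_gene_id": ann.gene_id,
            "annot_transcript_id": ann.isoform_id,
            "annot_gene_name": ann.gene_id,
            "annot_transcript_name": ann.isoform_id,
            "gene_novelty": "Known",
            "transcript_novelty": _TALON_NOVELTY_INVERSE.get(
                ann.structural_category, "Other"
            ),
        }
        for j, s in enumerate(flr.sample_ids):
            row[s] = int(flr.counts[i, j])
        rows.append(row)
    cols = [
        "gene_ID",
        "transcript_ID",
        "annot_gene_id",
        "annot_transcript_id",
        "annot_gene_name",
        "annot_transcript_name",
        "gene_novelty",
        "transcript_novelty",
    ] + list(flr.sample_ids)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_counts_table(flr: FlrMatrix, path: str | Path) -> None:
    """Write a companion counts table: isoform column + one column per sample."""
    df = flr.to_frame()
    df.insert(0, "isoform", df.index)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def transcript_table(reports: Sequence[TranscriptReport]) -> pd.DataFrame:
    """Assemble the per-transcript report table as a DataFrame.

    Column order is stable: identifiers, category, per-sample NFLR, summary
    statistics, rank, filter verdict.
    """
    sample_ids = reports[0].sample_ids if reports else []
    nflr_cols = [f"NFLR.{s}" for s in sample_ids]
    rows = []
    for r in reports:
        row = {"isoform_id": r.isoform_id, "gene_id": r.gene_id, "category": r.category.label}
        for col, v in zip(nflr_cols, r.nflr_per_sample):
            row[col] = v
        row.update(
            mean_nflr=r.mean_nflr,
            sd_nflr=r.sd_nflr,
            rank=r.rank,
            filter_pass=r.verdict.passed,
            fail_reasons=";".join(sorted(r.verdict.fail_reasons)),
        )
        rows.append(row)
    cols = (
        ["isoform_id", "gene_id", "category"]
        + nflr_cols
        + ["mean_nflr", "sd_nflr", "rank", "filter_pass", "fail_reasons"]
    )
    return pd.DataFrame(rows, columns=cols)


def write_transcript_table(reports: Sequence[TranscriptReport], path: str | Path) -> None:
    """Write the per-transcript report table as TSV (floats at 4 d.p.),
    ordered by gene then rank."""
    ordered = sorted(reports, key=lambda r: (r.gene_id, r.rank))
    transcript_table(ordered).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n"
    )
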