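"""Synthetic characterization datasets with known ground truth.

The generator emulates the *output* of an upstream long-read characterization
run — a classification table with structural/coding/NMD calls and per-sample
full-length-read counts — not the sequencing itself.  Per gene it fixes a
dominant transcript with a chosen expected usage share, splits the remainder
randomly among the other isoforms, and then draws per-sample counts as a
multinomial over (optionally noise-perturbed, dropout-thinned) proportions at
a per-sample gene depth.  Both input dialects are written, together with the
gene list, a ground-truth table and a manifest, so every downstream stage can
be tested against known truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as iso_io
from .categories import CATEGORY_ORDER, IsoformCategory, assign_category
from .model import (
    CodingStatus,
    Dataset,
    FlrMatrix,
    SourceDialect,
    StructuralCategory,
    Subcategory,
    TranscriptAnnotation,
)

#: Novel structural categories an inverted annotation may use.  genic_intron
#: and fusion are excluded only to keep TALON round-trips lossless (TALON has
#: no novelty label for them).
_NOVEL_STRUCTURAL = (
    StructuralCategory.INCOMPLETE_SPLICE_MATCH,
    StructuralCategory.NOVEL_IN_CATALOG,
    StructuralCategory.NOVEL_NOT_IN_CATALOG,
    StructuralCategory.ANTISENSE,
    StructuralCategory.GENIC,
    StructuralCategory.INTERGENIC,
)

_NON_REFMATCH_SUBCATEGORIES = (
    Subcategory.ALTERNATIVE_3END,
    Subcategory.ALTERNATIVE_5END,
    Subcategory.ALTERNATIVE_3END5END,
    Subcategory.MONO_EXON,
    Subcategory.OTHER,
    Subcategory.NOT_APPLICABLE,
)


def default_category_mix() -> dict[IsoformCategory, float]:
    """A mix typical of a targeted long-read run on a coding gene: novel
    isoforms (coding and non-coding) outnumber known ones, with smaller NMD
    fractions."""
    return {
        IsoformCategory.CODING_KNOWN_COMPLETE_MATCH: 0.10,
        IsoformCategory.CODING_KNOWN_ALT_ENDS: 0.15,
        IsoformCategory.CODING_NOVEL: 0.25,
        IsoformCategory.NMD_KNOWN: 0.05,
        IsoformCategory.NMD_NOVEL: 0.10,
        IsoformCategory.NON_CODING_KNOWN: 0.10,
        IsoformCategory.NON_CODING_NOVEL: 0.25,
    }


@dataclass
class SimulationParams:
    """Knobs of the synthetic dataset.

    dominance : expected NFLR share (fraction of 1) of each gene's dominant
        transcript.  The default 0.5 mirrors the common observation that a
        gene's principal isoform carries only about half of its output.
    noise_dispersion : scalar controlling sample-to-sample Dirichlet noise on
        isoform proportions (0 = none; larger = noisier).
    dropout_rate : probability that a non-dominant transcript records zero
        reads in a sample.
    gene_depth_range : inclusive range of total FLR per gene per sample.
    """

    n_genes: int = 20
    transcripts_per_gene: tuple[int, int] = (2, 10)
    n_samples: int = 6
    category_mix: dict[IsoformCategory, float] = field(default_factory=default_category_mix)
    dominance: float = 0.5
    gene_depth_range: tuple[int, int] = (100, 1000)
    noise_dispersion: float = 0.05
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be >= 1")
        lo, hi = self.transcripts_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("transcripts_per_gene must be a valid range with min >= 1")
        if not 0 < self.dominance <= 1:
            raise ValueError("dominance must lie in (0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1 (got {total})")


@dataclass
class GroundTruth:
    """True per-transcript categories and expected usage proportions, plus
    each gene's dominant transcript."""

    transcripts: pd.DataFrame  # isoform_id, gene_id, category, expected_proportion, is_dominant
    dominant_of: dict[str, str]


def invert_category(
    category: IsoformCategory, rng: np.random.Generator
) -> dict[str, object]:
    """Draw annotation fields whose categorization equals ``category``.

    A right inverse of the category assignment: any returned field
    combination maps back to the requested category.
    """
    known = category.is_known
    if known:
        structural = StructuralCategory.FULL_SPLICE_MATCH
    else:
        structural = _NOVEL_STRUCTURAL[rng.integers(len(_NOVEL_STRUCTURAL))]

    if category is IsoformCategory.CODING_KNOWN_COMPLETE_MATCH:
        subcategory = Subcategory.REFERENCE_MATCH
    elif structural is StructuralCategory.FULL_SPLICE_MATCH and category in (
        IsoformCategory.NMD_KNOWN,
        IsoformCategory.NON_CODING_KNOWN,
    ):
        # any FSM subcategory is consistent, reference_match included
        pool = (Subcategory.REFERENCE_MATCH,) + _NON_REFMATCH_SUBCATEGORIES
        subcategory = pool[rng.integers(len(pool))]
    else:
        subcategory = _NON_REFMATCH_SUBCATEGORIES[
            rng.integers(len(_NON_REFMATCH_SUBCATEGORIES))
        ]

    if category in (IsoformCategory.NON_CODING_KNOWN, IsoformCategory.NON_CODING_NOVEL):
        coding, nmd = CodingStatus.NON_CODING, None
    elif category in (IsoformCategory.NMD_KNOWN, IsoformCategory.NMD_NOVEL):
        coding, nmd = CodingStatus.CODING, True
    else:
        coding, nmd = CodingStatus.CODING, False

    return {
        "structural_category": structural,
        "subcategory": subcategory,
        "coding_status": coding,
        "nmd_predicted": nmd,
    }


def _expected_proportions(n: int, dominance: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Expected usage proportions for one gene and the dominant index."""
    if n == 1:
        return np.array([1.0]), 0
    dom = int(rng.integers(n))
    rest = rng.dirichlet(np.ones(n - 1)) * (1.0 - dominance)
    props = np.empty(n)
    props[dom] = dominance
    props[[i for i in range(n) if i != dom]] = rest
    return props, dom


def _sample_counts(
    props: np.ndarray,
    dom: int,
    depth: int,
    noise_dispersion: float,
    dropout_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    p = props.copy()
    if noise_dispersion > 0:
        alpha = np.maximum(p / noise_dispersion, 1e-6)
        p = rng.dirichlet(alpha)
    if dropout_rate > 0 and p.size > 1:
        drop = rng.random(p.size) < dropout_rate
        drop[dom] = False
        p[drop] = 0.0
    total = p.sum()
    if total == 0:
        return np.zeros(p.size, dtype=np.int64)
    return rng.multinomial(depth, p / total).astype(np.int64)


def simulate_dataset(
    params: SimulationParams, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a dataset and write every fixture file under ``outdir``.

    Deterministic given ``params.seed``: repeated calls produce byte-identical
    files.  Returns the written paths and the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    categories = list(CATEGORY_ORDER)
    mix = np.array([params.category_mix.get(c, 0.0) for c in categories])
    sample_ids = [f"sample_{j + 1:02d}" for j in range(params.n_samples)]

    annotations: dict[str, TranscriptAnnotation] = {}
    gene_of: dict[str, str] = {}
    transcript_ids: list[str] = []
    count_rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    dominant_of: dict[str, str] = {}

    lo, hi = params.transcripts_per_gene
    dlo, dhi = params.gene_depth_range
    for g in range(params.n_genes):
        gene = f"GENE{g + 1:04d}"
        n_tx = int(rng.integers(lo, hi + 1))
        props, dom = _expected_proportions(n_tx, params.dominance, rng)
        depths = rng.integers(dlo, dhi + 1, size=params.n_samples)
        counts = np.stack(
            [
                _sample_counts(
                    props, dom, int(depths[j]), params.noise_dispersion,
                    params.dropout_rate, rng,
                )
                for j in range(params.n_samples)
            ],
            axis=1,
        )
        for i in range(n_tx):
            tx = f"{gene}.tx{i + 1:03d}"
            category = categories[rng.choice(len(categories), p=mix)]
            fields = invert_category(category, rng)
            ann = TranscriptAnnotation(isoform_id=tx, gene_id=gene, **fields)
            assert assign_category(ann) is category
            annotations[tx] = ann
            gene_of[tx] = gene
            transcript_ids.append(tx)
            count_rows.append(counts[i, :])
            truth_rows.append(
                {
                    "isoform_id": tx,
                    "gene_id": gene,
                    "category": category.value,
                    "expected_proportion": props[i],
                    "is_dominant": i == dom,
                }
            )
        dominant_of[gene] = f"{gene}.tx{dom + 1:03d}"

    flr = FlrMatrix(
        transcript_ids=transcript_ids,
        sample_ids=sample_ids,
        counts=np.stack(count_rows, axis=0) if count_rows else np.zeros((0, params.n_samples), dtype=np.int64),
        gene_of=gene_of,
    )
    dataset = Dataset(annotations=annotations, flr=flr, source_dialect=SourceDialect.SQANTI3)
    truth = GroundTruth(
        transcripts=pd.DataFrame(
            truth_rows,
            columns=["isoform_id", "gene_id", "category", "expected_proportion", "is_dominant"],
        ),
        dominant_of=dominant_of,
    )

    paths = {
        "classification": outdir / "classification.txt",
        "counts": outdir / "counts.tsv",
        "talon_abundance": outdir / "talon_abundance.tsv",
        "gene_list": outdir / "genes.txt",
        "ground_truth": outdir / "ground_truth.tsv",
        "manifest": outdir / "manifest.txt",
    }
    iso_io.write_sqanti_classification(dataset, paths["classification"])
    iso_io.write_counts_table(flr, paths["counts"])
    iso_io.write_talon_abundance(dataset, paths["talon_abundance"])
    paths["gene_list"].write_text(
        "".join(f"GENE{g + 1:04d}\n" for g in range(params.n_genes)), encoding="utf-8"
    )
    truth.transcripts.to_csv(
        paths["ground_truth"], sep="\t", index=False, float_format="%.10g",
        lineterminator="\n",
    )
    manifest = {
        "seed": params.seed,
        "n_genes": params.n_genes,
        "transcripts_per_gene": f"{lo}-{hi}",
        "n_samples": params.n_samples,
        "dominance": params.dominance,
        "gene_depth_range": f"{dlo}-{dhi}",
        "noise_dispersion": params.noise_dispersion,
        "dropout_rate": params.dropout_rate,
        "category_mix": ",".join(
            f"{c.value}={params.category_mix.get(c, 0.0):g}" for c in categories
        ),
    }
    paths["manifest"].write_text(
        "".join(f"{k}: {v}\n" for k, v in manifest.items()), encoding="utf-8"
    )
    return paths, truth
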