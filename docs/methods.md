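# Methods

## Problem and model

Long-read RNA sequencing characterizes transcripts as full-length reads
(FLRs) and routinely reports hundreds to thousands of transcript models per
gene, most of them novel. `isoprio` performs the downstream, gene-based
prioritization step: given a characterization table from SQANTI3 or TALON
and a list of candidate genes, it decides which transcript models are
reproducible, how much each contributes to its gene's output, and how to
summarize them for interpretation.

### Normalization (NFLR)

For transcript *T* of gene *g* in sample *i*:

    NFLR_Ti = 100 · FLR_Ti / Σ_{T' ∈ g} FLR_T'i

i.e. the percentage of the gene's full-length reads in that sample carried
by the transcript. Within a gene and sample, NFLR sums to 100 (to 1e-9);
if the gene has zero reads in a sample, all its NFLR values in that sample
are 0 and the (gene, sample) cell is flagged. The statistic is invariant
under scaling a sample's counts, so it measures transcript *usage*
independent of absolute gene expression. The per-transcript summary
NFLR_T is the arithmetic mean of NFLR_Ti over **all** samples; a flagged
zero-total sample contributes 0 rather than being dropped, because a sample
in which the gene is silent is evidence against reproducibility, not
missing data. The spread statistic is the sample standard deviation
(denominator S−1; defined as 0 for a single sample), treating samples as
replicates from a population.

### Category re-grouping

Each isoform's structural category, ORF call and NMD prediction collapse
into one of seven labels: non-coding novel, non-coding known, NMD novel,
NMD known, coding novel, coding known (complete match), coding known
(alternate 3'/5' end). Decision order:

1. not coding (including an unassessed ORF) → non-coding known/novel;
2. coding with a positive NMD prediction → NMD known/novel;
3. remaining coding isoforms: known ones split on subcategory
   (reference_match → complete match; anything else, including mono-exonic
   matches → alternate ends); novel ones → coding novel.

"Known" means full_splice_match only; incomplete splice matches truncate
the reference model and are treated as novel. This is configurable
(`known_categories` argument) for analyses that prefer ISM-as-known.
Treating an unknown ORF as non-coding is deliberately conservative: an
unverified ORF is not promoted. An absent NMD call counts as negative,
matching upstream tools that leave the field blank when not applicable.
TALON provides neither ORF nor NMD calls, so TALON input yields
structure-only categories (everything in the non-coding groups) and the
partition warns accordingly.

### Filtering and ranking

Two thresholds, both in NFLR units and both compared inclusively (≥):

* `mean_threshold` (default 0.3) — minimum mean NFLR across all samples;
* `per_sample_threshold` (default 0.3) with `min_sample_fraction`
  (default 0.5) — the fraction of *all* samples (not just those where the
  gene is expressed) in which the transcript must reach the per-sample
  threshold. Setting the fraction to 1 reproduces the strict
  expressed-in-every-sample filter of the upstream tools.

Inclusive comparisons make the degenerate all-zero configuration
well-defined (everything passes). Failures record which condition(s) were
violated. Ranking orders transcripts within each gene by mean NFLR
descending, 1-based, with ties broken by ascending lexicographic isoform id
so output is deterministic.

The threshold sweep counts detected transcripts per sample at each grid
point; detection at threshold 0 means NFLR > 0 (a never-observed transcript
is not "detected"), and NFLR ≥ t above that. The default grid runs 0–10 in
steps of 0.1 — the region where detection collapses and where the decision
is actually made — then 10–100 in steps of 1.

## Synthetic data generator

The generator emulates the *output* of a characterization run, not
sequencing: per gene it fixes a dominant transcript at an expected usage
share (`dominance`), splits the remainder by a symmetric Dirichlet
partition, assigns each transcript annotation fields drawn to invert a
category sampled from `category_mix`, and per sample draws total gene depth
uniformly from `gene_depth_range`, perturbs proportions with Dirichlet
noise (concentration ∝ 1/`noise_dispersion`), zeroes non-dominant
transcripts with probability `dropout_rate`, and draws counts as a
multinomial at the drawn depth (conserving gene depth exactly). A single
seeded stream makes output byte-identical per seed; the seed and parameters
are recorded in a manifest.

Defaults — 20 genes of 2–10 transcripts, 6 samples, dominance 0.5, depth
100–1000 FLR/gene/sample, noise 0.05, dropout 0.1, with a category mix
skewed toward novel isoforms — reflect a modest targeted long-read study;
dominance 0.5 mirrors the common observation that a gene's principal
isoform carries only about half of its output. The generator does not
simulate splice structures, genomic coordinates, batch effects, length
bias, or the error modes of the upstream classifier; passing recovery tests
therefore demonstrates correctness of the normalization/filter/rank
machinery under the stated sampling model, not robustness to real-data
artifacts. Novel structural categories are drawn only from those with a
TALON novelty label (fusion and genic_intron excluded) so that fixtures
round-trip losslessly through both dialects.

## Numerical and design choices

* NFLR uses exact float division; the sum-to-100 invariant is asserted to
  1e-9 in tests.
* Floats in output tables are rendered at 4 decimal places — sub-read
  resolution for a percentage.
* Enum strings from input files match case-insensitively with `-`, `_` and
  space treated as equivalent; unrecognized values degrade to
  `other`/`unknown` with a warning instead of failing, since upstream tools
  add categories between versions.
* SVG output is deterministic (fixed hash salt, no date metadata), so
  repeated runs are byte-identical apart from the timestamped log.
* The per-gene HTML report is self-contained (figures embedded as data
  URIs, no network resources); it is assembled with plain string
  templating, which the small fixed layout does not justify a template
  engine for.
* The sweep-plot inset magnifies the 0–2 NFLR region, where the detected
  count changes fastest.
* Default thresholds (0.3 / 0.5 / 0.3) are explicit, conservative
  configuration values, fully overridable by config file or CLI flags.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: property
checks use up to 1000 random matrices of ≤ 8 transcripts × 4 samples;
recovery uses 200 simulated genes × 6 samples at depth 200–1000; the
end-to-end check uses 20 genes × 6 samples. These sizes are far past the
point where the arithmetic properties under test stop depending on size.

## Known limitations

* Only the SQANTI3 classification and TALON abundance dialects are parsed;
  junction/GTF outputs, genome FASTA and annotation handling are out of
  scope, as are between-gene normalization (TPM/CPM), differential
  expression and isoform-switching statistics.
* Category assignment inherits whatever the upstream ORF/NMD caller got
  wrong; it re-groups, it does not re-predict.
* With TALON input the seven-way categorization degenerates to a two-way
  known/novel split.
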