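"""NFLR normalization, summaries, sweeps, filtering and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoprio.expression import (
    FAIL_BELOW_MEAN,
    FAIL_INSUFFICIENT_SAMPLES,
    FilterConfig,
    FilterVerdict,
    NflrMatrix,
    apply_filters,
    compute_nflr,
    default_sweep_grid,
    rank_transcripts,
    summarize_nflr,
    sweep_detection_counts,
)
from isoprio.model import FlrMatrix


def nflr_from_counts(counts, genes=None, sample_ids=None):
    counts = np.asarray(counts)
    ids = [f"t{i}" for i in range(counts.shape[0])]
    gene_of = {t: (genes[i] if genes else "G1") for i, t in enumerate(ids)}
    flr = FlrMatrix(
        transcript_ids=ids,
        sample_ids=sample_ids or [f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
        gene_of=gene_of,
    )
    return compute_nflr(flr)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_worked_example_percentages(worked_example_flr):
    """Counts 40/20/10/10/10: the top transcript carries ~45% (40/90) of the
    gene's output and the others jointly ~55%."""
    nflr = compute_nflr(worked_example_flr)
    expected = 100 * np.array([40, 20, 10, 10, 10]) / 90
    np.testing.assert_allclose(nflr.nflr[:, 0], expected, atol=1e-12)
    assert nflr.nflr[0, 0] == pytest.approx(44.4444, abs=1e-4)
    assert nflr.nflr[1:, 0].sum() == pytest.approx(55.5556, abs=1e-4)


def test_singleton_gene_is_100_percent():
    nflr = nflr_from_counts([[7]])
    assert nflr.nflr[0, 0] == 100.0


def test_zero_total_sample_flagged_and_zeroed():
    nflr = nflr_from_counts([[3, 0], [1, 0]])
    assert nflr.nflr[:, 1].tolist() == [0.0, 0.0]
    assert nflr.zero_total_flags["G1"].tolist() == [False, True]
    np.testing.assert_allclose(nflr.nflr[:, 0].sum(), 100.0)


count_matrices = st.integers(1, 6).flatmap(
    lambda t: st.integers(1, 4).flatmap(
        lambda s: st.lists(
            st.lists(st.integers(0, 500), min_size=s, max_size=s),
            min_size=t,
            max_size=t,
        )
    )
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(count_matrices)
def test_nflr_sums_to_100_per_gene_per_sample(counts):
    """Within each gene, NFLR over transcripts sums to 100 in every sample
    where the gene has reads, and to 0 where it does not."""
    counts = np.array(counts)
    nflr = nflr_from_counts(counts)
    totals = counts.sum(axis=0)
    sums = nflr.nflr.sum(axis=0)
    for j, total in enumerate(totals):
        if total == 0:
            assert sums[j] == 0.0
        else:
            assert abs(sums[j] - 100.0) < 1e-9


@settings(max_examples=100, deadline=None, derandomize=True)
@given(count_matrices, st.integers(2, 50))
def test_scale_invariance_of_nflr(counts, k):
    """Multiplying a sample's counts by a constant leaves NFLR unchanged:
    usage is independent of absolute gene expression."""
    counts = np.array(counts)
    base = nflr_from_counts(counts)
    scaled = nflr_from_counts(counts * k)
    np.testing.assert_allclose(base.nflr, scaled.nflr, atol=1e-9)


def test_multi_gene_normalization_is_within_gene():
    nflr = nflr_from_counts([[10], [10], [80]], genes=["G1", "G1", "G2"])
    np.testing.assert_allclose(nflr.nflr[:, 0], [50.0, 50.0, 100.0])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def test_summary_constant_series():
    nflr = nflr_from_counts([[1, 1, 1], [9, 9, 9]])
    s = summarize_nflr(nflr)
    assert s.mean_nflr[0] == pytest.approx(10.0)
    assert s.sd_nflr[0] == 0.0
    assert s.n_samples_expressed[0] == 3


def test_summary_two_point_mean_and_sd():
    """NFLR series [0, 20] has mean 10 and sample SD 14.1421 (ddof=1)."""
    nflr = NflrMatrix(
        transcript_ids=["t0"],
        sample_ids=["s0", "s1"],
        nflr=np.array([[0.0, 20.0]]),
        gene_of={"t0": "G1"},
        zero_total_flags={"G1": np.array([True, False])},
    )
    s = summarize_nflr(nflr)
    assert s.mean_nflr[0] == pytest.approx(10.0)
    assert s.sd_nflr[0] == pytest.approx(14.1421, abs=1e-4)
    assert s.n_samples_expressed[0] == 1


def test_summary_single_sample_sd_zero(worked_example_flr):
    s = summarize_nflr(compute_nflr(worked_example_flr))
    assert s.mean_nflr[0] == pytest.approx(44.4444, abs=1e-4)
    assert (s.sd_nflr == 0).all()


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------


def make_nflr(values, genes=None):
    values = np.asarray(values, dtype=float)
    ids = [f"t{i}" for i in range(values.shape[0])]
    gene_of = {t: (genes[i] if genes else "G1") for i, t in enumerate(ids)}
    return NflrMatrix(
        transcript_ids=ids,
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        nflr=values,
        gene_of=gene_of,
        zero_total_flags={g: np.zeros(values.shape[1], bool) for g in set(gene_of.values())},
    )


def test_sweep_counts_by_hand():
    nflr = make_nflr([[50], [30], [15], [5]])
    curve = sweep_detection_counts(nflr, [0, 10, 20, 40])
    assert curve.counts_per_sample[:, 0].tolist() == [4, 3, 2, 1]


def test_sweep_zero_threshold_requires_positive_nflr():
    nflr = make_nflr([[0.0], [2.0]])
    curve = sweep_detection_counts(nflr, [0])
    assert curve.counts_per_sample[0, 0] == 1


def test_sweep_monotone_and_all_zero_column():
    rng = np.random.default_rng(11)
    nflr = make_nflr(np.column_stack([rng.uniform(0, 100, 20), np.zeros(20)]))
    curve = sweep_detection_counts(nflr, default_sweep_grid())
    assert (np.diff(curve.counts_per_sample, axis=0) <= 0).all()
    assert (curve.counts_per_sample[:, 1] == 0).all()


def test_sweep_rejects_empty_or_unsorted_grid():
    nflr = make_nflr([[1.0]])
    with pytest.raises(ValueError):
        sweep_detection_counts(nflr, [])
    with pytest.raises(ValueError):
        sweep_detection_counts(nflr, [1.0, 0.5])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def verdicts_for(values, **cfg):
    nflr = make_nflr(values)
    summary = summarize_nflr(nflr)
    config = FilterConfig(**{**dict(sweep_grid=[0.0, 1.0]), **cfg})
    return apply_filters(nflr, summary, config)


def test_filter_worked_cases():
    v = verdicts_for(
        [[2.0, 0.1, 0.1, 3.0]],
        per_sample_threshold=1.0,
        min_sample_fraction=0.5,
        mean_threshold=1.0,
    )["t0"]
    assert v.passed

    v = verdicts_for(
        [[1.2, 0.8]], per_sample_threshold=1.0, min_sample_fraction=1.0, mean_threshold=0.0
    )["t0"]
    assert not v.passed and v.fail_reasons == {FAIL_INSUFFICIENT_SAMPLES}


def test_zero_config_passes_everything():
    vs = verdicts_for(
        np.zeros((3, 2)), per_sample_threshold=0.0, min_sample_fraction=0.0, mean_threshold=0.0
    )
    assert all(v.passed for v in vs.values())


def test_fail_reasons_reported_per_condition():
    vs = verdicts_for(
        [[0.1, 0.1], [5.0, 0.1]],
        per_sample_threshold=1.0,
        min_sample_fraction=1.0,
        mean_threshold=1.0,
    )
    assert vs["t0"].fail_reasons == {FAIL_BELOW_MEAN, FAIL_INSUFFICIENT_SAMPLES}
    assert vs["t1"].fail_reasons == {FAIL_INSUFFICIENT_SAMPLES}


def brute_force_filter(values, per_sample_threshold, min_sample_fraction, mean_threshold):
    """Independent re-derivation: per transcript, check each condition by
    explicit loops over samples."""
    out = []
    n_samples = len(values[0])
    for row in values:
        mean = sum(row) / n_samples
        n_meeting = sum(1 for x in row if x >= per_sample_threshold)
        ok_mean = mean >= mean_threshold
        ok_frac = (n_meeting / n_samples) >= min_sample_fraction
        out.append(ok_mean and ok_frac)
    return out


nflr_matrices = st.integers(1, 8).flatmap(
    lambda t: st.integers(1, 4).flatmap(
        lambda s: st.lists(
            st.lists(
                st.floats(0, 100, allow_nan=False, width=32), min_size=s, max_size=s
            ),
            min_size=t,
            max_size=t,
        )
    )
)


@settings(max_examples=250, deadline=None, derandomize=True)
@given(
    nflr_matrices,
    st.floats(0, 5, allow_nan=False),
    st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
    st.floats(0, 5, allow_nan=False),
)
def test_filter_agrees_with_brute_force_oracle(values, pst, frac, mt):
    values = np.array(values, dtype=float)
    vs = verdicts_for(
        values, per_sample_threshold=pst, min_sample_fraction=frac, mean_threshold=mt
    )
    expected = brute_force_filter(values.tolist(), pst, frac, mt)
    got = [vs[f"t{i}"].passed for i in range(values.shape[0])]
    assert got == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    nflr_matrices,
    st.floats(0, 3, allow_nan=False),
    st.floats(0, 1, allow_nan=False),
    st.floats(0, 3, allow_nan=False),
    st.floats(0, 2, allow_nan=False),
    st.floats(0, 0.5, allow_nan=False),
    st.floats(0, 2, allow_nan=False),
)
def test_filter_monotone_in_every_threshold(values, pst, frac, mt, dpst, dfrac, dmt):
    """Raising any threshold never converts a failing transcript to passing."""
    values = np.array(values, dtype=float)
    base = verdicts_for(
        values, per_sample_threshold=pst, min_sample_fraction=frac, mean_threshold=mt
    )
    stricter = verdicts_for(
        values,
        per_sample_threshold=pst + dpst,
        min_sample_fraction=min(1.0, frac + dfrac),
        mean_threshold=mt + dmt,
    )
    for t, v in stricter.items():
        if v.passed:
            assert base[t].passed


def test_strict_all_samples_filter_is_min_sample_fraction_one():
    """min_sample_fraction=1 reproduces the expressed-in-every-sample rule."""
    values = np.array([[1.0, 1.0, 1.0], [1.0, 0.0, 1.0]])
    vs = verdicts_for(
        values, per_sample_threshold=0.5, min_sample_fraction=1.0, mean_threshold=0.0
    )
    assert vs["t0"].passed and not vs["t1"].passed


def test_single_sample_sweep_equals_passing_count():
    """For one sample, the sweep count at t equals the number of transcripts
    passing the filter with per-sample threshold t (mean 0, fraction 1)."""
    rng = np.random.default_rng(5)
    values = rng.uniform(0, 30, size=(12, 1))
    nflr = make_nflr(values)
    summary = summarize_nflr(nflr)
    for t in (0.5, 1.0, 5.0, 10.0):
        curve = sweep_detection_counts(nflr, [t])
        vs = apply_filters(
            nflr,
            summary,
            FilterConfig(
                per_sample_threshold=t,
                min_sample_fraction=1.0,
                mean_threshold=0.0,
                sweep_grid=[t],
            ),
        )
        assert curve.counts_per_sample[0, 0] == sum(v.passed for v in vs.values())


def test_verdict_consistency_enforced():
    with pytest.raises(ValueError):
        FilterVerdict(passed=True, fail_reasons=frozenset({FAIL_BELOW_MEAN}))


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(min_sample_fraction=1.5)
    with pytest.raises(ValueError):
        FilterConfig(sweep_grid=[])
    with pytest.raises(ValueError):
        FilterConfig(sweep_grid=[1.0, 1.0])


def test_filter_config_from_yaml(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text(
        "per_sample_threshold: 1.5\nmin_sample_fraction: 0.75\n"
        "mean_threshold: 2.0\nsweep_min: 0\nsweep_max: 5\nsweep_step: 0.5\n"
    )
    cfg = FilterConfig.from_yaml(p)
    assert cfg.per_sample_threshold == 1.5
    assert cfg.min_sample_fraction == 0.75
    assert cfg.mean_threshold == 2.0
    np.testing.assert_allclose(cfg.sweep_grid, np.arange(0, 5.26, 0.5))


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def test_rank_worked_example(worked_example_flr):
    nflr = compute_nflr(worked_example_flr)
    ranks = rank_transcripts(summarize_nflr(nflr), nflr.gene_of)
    assert ranks == {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}


def test_rank_single_transcript():
    nflr = nflr_from_counts([[5]])
    assert rank_transcripts(summarize_nflr(nflr), nflr.gene_of) == {"t0": 1}


def test_rank_tie_break_is_lexicographic():
    """Equal means: 'tx10' sorts before 'tx2' as strings, so it gets rank 1."""
    nflr = NflrMatrix(
        transcript_ids=["tx2", "tx10"],
        sample_ids=["s0"],
        nflr=np.array([[50.0], [50.0]]),
        gene_of={"tx2": "G1", "tx10": "G1"},
        zero_total_flags={"G1": np.array([False])},
    )
    ranks = rank_transcripts(summarize_nflr(nflr), nflr.gene_of)
    assert ranks == {"tx10": 1, "tx2": 2}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(count_matrices)
def test_rank1_attains_gene_maximum(counts):
    counts = np.array(counts)
    nflr = nflr_from_counts(counts)
    summary = summarize_nflr(nflr)
    ranks = rank_transcripts(summary, nflr.gene_of)
    means = dict(zip(summary.transcript_ids, summary.mean_nflr))
    top = [t for t, r in ranks.items() if r == 1]
    assert len(top) == 1
    assert means[top[0]] == max(means.values())
    assert sorted(ranks.values()) == list(range(1, counts.shape[0] + 1))
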