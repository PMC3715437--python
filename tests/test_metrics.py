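import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_protein, track_from_flags
from vtdisorder.metrics import (
    BinaryMask,
    apply_tm_mask,
    binarize_track,
    find_runs,
    read_summary_table,
    summarize_protein,
    write_summary_table,
)
from vtdisorder.records import ScoreTrack, Segment, TrackKind


def brute_force_runs(flags, excluded, k):
    """Independent run scan: maximal countable-True stretches, length >= k."""
    runs = []
    start = None
    for i, (flag, exc) in enumerate(zip(flags, excluded)):
        good = flag and not exc
        if good and start is None:
            start = i
        if not good and start is not None:
            runs.append((start + 1, i))
            start = None
        if exc and start is not None:  # defensive; excluded implies not good
            start = None
    if start is not None:
        runs.append((start + 1, len(flags)))
    return [(s, e) for s, e in runs if e - s + 1 >= k]


class TestBinarize:
    def test_threshold_is_inclusive(self):
        track = ScoreTrack(TrackKind.DISORDER, [0.2, 0.6, 0.5, 0.49])
        assert list(binarize_track(track)) == [False, True, True, False]

    def test_all_zero(self):
        track = ScoreTrack(TrackKind.DISORDER, [0.0] * 5)
        assert not binarize_track(track).any()

    def test_matches_elementwise_oracle(self, rng):
        scores = rng.uniform(size=1000)
        track = ScoreTrack(TrackKind.DISORDER, scores)
        assert binarize_track(track).sum() == sum(1 for s in scores if s >= 0.5)

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_threshold_rejected(self, threshold):
        track = ScoreTrack(TrackKind.DISORDER, [0.5])
        with pytest.raises(ValueError):
            binarize_track(track, threshold)


class TestTmMask:
    def test_excision_counts(self):
        mask = apply_tm_mask([True] * 10, [Segment(4, 6)])
        assert mask.effective_length == 7
        assert mask.n_true == 7

    def test_no_segments_is_identity(self):
        mask = apply_tm_mask([True, False, True], [])
        assert not mask.excluded.any()
        assert mask.n_true == 2

    def test_run_split_by_excised_segment(self):
        mask = apply_tm_mask([True] * 10, [Segment(4, 6)])
        runs = find_runs(mask, 1)
        assert [(r.span.start, r.span.end) for r in runs] == [(1, 3), (7, 10)]

    def test_join_policy_merges_across_excision(self):
        mask = apply_tm_mask([True] * 10, [Segment(4, 6)])
        (run,) = find_runs(mask, 1, join_excluded=True)
        assert (run.span.start, run.span.end) == (1, 10)
        assert sum(r.length for r in find_runs(mask, 7, join_excluded=True)) == 10

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            apply_tm_mask([True] * 10, [Segment(2, 5), Segment(4, 8)])


class TestFindRuns:
    def test_length_thresholding(self):
        flags = [True] * 40 + [False] + [True] * 29 + [False] + [True] * 100
        mask = BinaryMask(flags, [False] * len(flags))
        runs = find_runs(mask, 30)
        assert len(runs) == 2
        assert sum(r.length for r in runs) == 140

    def test_all_false_mask(self):
        mask = BinaryMask([False] * 20, [False] * 20)
        assert find_runs(mask, 1) == []

    def test_k1_recovers_flag_count(self, rng):
        flags = rng.uniform(size=300) < 0.5
        mask = BinaryMask(flags, [False] * 300)
        assert sum(r.length for r in find_runs(mask, 1)) == flags.sum()

    @given(data=st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force_scan(self, data):
        n = data.draw(st.integers(1, 200))
        flags = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        excluded = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        k = data.draw(st.integers(1, 50))
        mask = BinaryMask(flags, excluded)
        got = [(r.span.start, r.span.end) for r in find_runs(mask, k)]
        assert got == brute_force_runs(flags, excluded, k)


class TestSummarize:
    def test_known_content_fractions(self):
        protein = make_protein(248, "CLTA-like")
        track = track_from_flags([True] * 149 + [False] * 99)
        summary = summarize_protein(protein, track)
        assert round(100 * summary.disorder_content, 2) == 60.08

        protein = make_protein(770, "DAB2-like")
        track = track_from_flags([True] * 571 + [False] * 199)
        summary = summarize_protein(protein, track)
        assert round(100 * summary.disorder_content, 2) == 74.16

    def test_fully_ordered_protein(self):
        protein = make_protein(100)
        summary = summarize_protein(protein, track_from_flags([False] * 100),
                                    track_from_flags([False] * 100, TrackKind.BINDING))
        assert summary.disorder_content == 0.0
        assert all(v == 0.0 for v in summary.ldr_residue_ratio.values())
        assert not any(summary.has_ldr(k) for k in (30, 50, 100))
        assert summary.dbr_residue_ratio == 0.0

    def test_absent_binding_track_flagged_not_zero(self):
        summary = summarize_protein(make_protein(50), track_from_flags([True] * 50))
        assert summary.dbr_residue_ratio is None
        assert summary.n_dbr is None

    def test_short_protein_has_no_ldr(self):
        summary = summarize_protein(make_protein(10), track_from_flags([True] * 10))
        assert not summary.has_ldr(30)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            summarize_protein(make_protein(10), track_from_flags([True] * 9))

    def test_tm_excluded_from_both_numerator_and_denominator(self):
        protein = make_protein(100, tm=[Segment(41, 60)])
        summary = summarize_protein(protein, track_from_flags([True] * 100))
        assert summary.effective_length == 80
        assert summary.disorder_content == 1.0

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ldr_ratio_non_increasing_in_k(self, data):
        n = data.draw(st.integers(1, 150))
        flags = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        summary = summarize_protein(make_protein(n), track_from_flags(flags),
                                    k_values=(5, 10, 30, 50))
        ratios = [summary.ldr_residue_ratio[k] for k in (5, 10, 30, 50)]
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))
        assert all(r <= summary.disorder_content for r in ratios)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, data):
        n = data.draw(st.integers(1, 100))
        scores = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        track = ScoreTrack(TrackKind.DISORDER, scores)
        protein = make_protein(n)
        contents = [
            summarize_protein(protein, track, threshold=t).disorder_content
            for t in (0.3, 0.5, 0.7)
        ]
        assert contents[0] >= contents[1] >= contents[2]

    def test_adding_tm_never_increases_disordered_count(self, rng):
        flags = rng.uniform(size=120) < 0.5
        base = summarize_protein(make_protein(120), track_from_flags(flags))
        with_tm = summarize_protein(make_protein(120, tm=[Segment(30, 50)]),
                                    track_from_flags(flags))
        assert with_tm.disorder_content * with_tm.effective_length <= \
            base.disorder_content * base.effective_length + 1e-9


class TestSummaryTable:
    def test_round_trip(self, tmp_path):
        protein = make_protein(248)
        summaries = [
            summarize_protein(protein, track_from_flags([True] * 149 + [False] * 99),
                              track_from_flags([True] * 40 + [False] * 208, TrackKind.BINDING)),
            summarize_protein(make_protein(50, "P2"), track_from_flags([False] * 50)),
        ]
        path = tmp_path / "summary.tsv"
        write_summary_table(summaries, path)
        back = read_summary_table(path)
        assert [s.accession for s in back] == ["P1", "P2"]
        assert back[0].effective_length == 248
        assert round(back[0].disorder_content, 4) == round(summaries[0].disorder_content, 4)
        assert back[1].dbr_residue_ratio is None
        assert back[0].n_ldr == summaries[0].n_ldr
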