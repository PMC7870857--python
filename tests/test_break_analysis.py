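"""Run/switch statistics, thresholded histograms, and the clustering test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilbreaks.break_analysis import (
    InsufficientDataError,
    benjamini_hochberg,
    fraction_histogram,
    mixture_report,
    permutation_test_clustering,
    summarize_fibril,
    summarize_table,
)

from conftest import (
    brute_force_runs,
    brute_force_switches,
    exhaustive_clustering_p,
    make_table,
)

A, B, U = "A", "B", "UNASSIGNED"


# ------------------------------------------------------------- summaries

class TestSummarizeFibril:
    def test_mixed_fibril(self):
        s = summarize_fibril([A, A, A, B, B])
        assert (s.n_A, s.n_B, s.fraction_B) == (3, 2, pytest.approx(0.4))
        assert (s.n_runs, s.n_switches, s.purity_class) == (2, 1, "mixed")

    def test_pure_fibril(self):
        s = summarize_fibril([A, A, A])
        assert s.fraction_B == 0.0
        assert (s.n_switches, s.purity_class) == (0, "pure_A")

    def test_runs_span_unassigned_gaps(self):
        s = summarize_fibril([A, U, A, B, U, B, A])
        assert (s.n_runs, s.n_switches) == (3, 2)
        assert s.runs == (("A", 2), ("B", 2), ("A", 1))

    def test_empty_and_unlabeled(self):
        s = summarize_fibril([])
        assert (s.purity_class, s.fraction_B, s.n_runs) == ("unlabeled", None, 0)
        s = summarize_fibril([U, U])
        assert (s.purity_class, s.fraction_B) == ("unlabeled", None)

    def test_counts_conserved(self):
        s = summarize_fibril([A, U, B, B, U])
        assert s.n_A + s.n_B + s.n_unassigned == s.n_segments == 5

    @given(labels=st.lists(st.sampled_from([A, B, U]), max_size=12))
    @settings(max_examples=500, derandomize=True)
    def test_matches_brute_force_run_counter(self, labels):
        s = summarize_fibril(labels)
        assert list(s.runs) == brute_force_runs(labels)
        assert s.n_switches == brute_force_switches(labels)

    def test_exhaustive_short_sequences(self):
        # every label sequence of length <= 7 over {A, B, U}
        for n in range(8):
            for labels in itertools.product((A, B, U), repeat=n):
                s = summarize_fibril(labels)
                assert list(s.runs) == brute_force_runs(labels), labels

    def test_break_at_gap_splits_runs(self):
        # two A-segments 200 Å apart: one run normally, two with a 100 Å cap
        labels, pos = [A, A], [0.0, 200.0]
        assert summarize_fibril(labels, axial_pos=pos).n_runs == 1
        s = summarize_fibril(labels, axial_pos=pos, break_at_gap=100.0)
        assert s.n_runs == 2
        assert s.n_switches == 1

    def test_gap_measured_between_labeled_segments(self):
        # unassigned gap of 2 boxes: labeled neighbours are 67.2 Å apart
        labels, pos = [A, U, A], [0.0, 33.6, 67.2]
        assert summarize_fibril(labels, axial_pos=pos, break_at_gap=50.0).n_runs == 2
        assert summarize_fibril(labels, axial_pos=pos, break_at_gap=70.0).n_runs == 1


# ------------------------------------------------------------- histogram

def _summaries_from(fracs_and_counts):
    """[(n_A, n_B)] -> summaries via synthetic label sequences."""
    return [summarize_fibril([A] * na + [B] * nb) for na, nb in fracs_and_counts]


class TestFractionHistogram:
    def test_two_bin_example(self):
        summaries = _summaries_from([(1, 0), (1, 0), (0, 1), (1, 1)])
        hist = fraction_histogram(summaries, thresholds=(1,), n_bins=2)
        np.testing.assert_allclose(hist.percentages[1], [50.0, 50.0])
        assert hist.n_fibrils[1] == 4

    def test_threshold_membership_inclusive(self):
        summaries = _summaries_from([(2, 1)])  # 3 labeled segments
        hist = fraction_histogram(summaries, thresholds=(1, 3, 5))
        assert hist.n_fibrils[1] == 1
        assert hist.n_fibrils[3] == 1  # >= is inclusive
        assert hist.n_fibrils[5] == 0
        assert hist.empty_categories == (5,)

    def test_pure_B_lands_in_top_bin(self):
        hist = fraction_histogram(_summaries_from([(0, 3)]), thresholds=(1,))
        assert hist.counts[1][-1] == 1

    def test_percentages_sum_to_100(self, rng):
        summaries = _summaries_from(
            [(int(rng.integers(0, 20)), int(rng.integers(0, 20))) for _ in range(1000)]
        )
        hist = fraction_histogram(summaries, thresholds=(1, 5, 10, 20))
        for t in hist.thresholds:
            if t not in hist.empty_categories:
                assert hist.percentages[t].sum() == pytest.approx(100.0, abs=1e-9)

    def test_counts_non_increasing_in_threshold(self, rng):
        summaries = _summaries_from(
            [(int(rng.integers(0, 15)), int(rng.integers(0, 15))) for _ in range(500)]
        )
        hist = fraction_histogram(summaries, thresholds=(1, 5, 10, 20))
        ns = [hist.n_fibrils[t] for t in (1, 5, 10, 20)]
        assert ns == sorted(ns, reverse=True)

    def test_rejects_empty_input_and_bad_threshold(self):
        with pytest.raises(ValueError):
            fraction_histogram([])
        with pytest.raises(ValueError):
            fraction_histogram(_summaries_from([(1, 1)]), thresholds=(0,))


# ------------------------------------------------------- permutation test

class TestPermutationTest:
    def test_exact_p_on_single_block_fibril(self):
        # 5 A's then 5 B's: only 2 of C(10,5)=252 placements have <= 1 switch
        labels = [A] * 5 + [B] * 5
        assert exhaustive_clustering_p(labels) == pytest.approx(2 / 252)
        res = permutation_test_clustering(
            {("m", 1): labels}, n_permutations=100_000, seed=7
        )
        exact = 2 / 252
        sd = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(res.p_value - exact) < 3 * sd
        assert res.statistic_observed == 1

    def test_degenerate_two_segment_fibril(self):
        res = permutation_test_clustering({("m", 1): [A, B]}, 1000, seed=0)
        assert res.statistic_observed == 1
        assert res.p_value == 1.0

    def test_small_exhaustive_case(self):
        # [A,A,B,B]: 2 of 6 placements have <= 1 switch -> p = 1/3
        labels = [A, A, B, B]
        exact = exhaustive_clustering_p(labels)
        assert exact == pytest.approx(1 / 3)
        res = permutation_test_clustering({("m", 1): labels}, 20_000, seed=3)
        sd = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_value - exact) < 3 * sd

    def test_p_never_below_add_one_floor(self):
        res = permutation_test_clustering(
            {("m", 1): [A] * 20 + [B] * 20}, 500, seed=1
        )
        assert res.p_value >= 1 / 501

    def test_reproducible_given_seed(self, small_table):
        r1 = permutation_test_clustering(small_table, 2000, seed=42)
        r2 = permutation_test_clustering(small_table, 2000, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.null_mean == r2.null_mean

    def test_unassigned_skipped_and_pooled_over_fibrils(self):
        seqs = {("m", 1): [A, U, A, B, B], ("m", 2): [B, B, A]}
        res = permutation_test_clustering(seqs, 100, seed=0)
        assert res.statistic_observed == 2
        assert res.n_fibrils_tested == 2

    def test_accepts_segment_table(self, small_table):
        res = permutation_test_clustering(small_table, 500, seed=0)
        assert 0 < res.p_value <= 1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            permutation_test_clustering({("m", 1): [A], ("m", 2): [U, U]}, 100, 0)

    def test_per_fibril_reporting(self):
        seqs = {("m", 1): [A] * 6 + [B] * 6, ("m", 2): [A, B, A, B]}
        res = permutation_test_clustering(seqs, 2000, seed=5, per_fibril=True)
        assert len(res.per_fibril) == 2
        clustered = next(r for r in res.per_fibril if r["fibril_id"] == ["m", 1])
        alternating = next(r for r in res.per_fibril if r["fibril_id"] == ["m", 2])
        assert clustered["p_value"] < 0.05
        assert alternating["p_value"] > 0.5


def test_benjamini_hochberg_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.9, 0.04]
    adj = benjamini_hochberg(p)
    assert (adj >= np.asarray(p) - 1e-15).all()
    assert (adj <= 1.0).all()
    # BH preserves the significance ordering
    assert list(np.argsort(adj)) == list(np.argsort(p))


# --------------------------------------------------------- mixture report

class TestMixtureReport:
    def test_all_pure(self):
        summaries = _summaries_from([(3, 0), (0, 2)])
        rep = mixture_report(summaries)
        assert rep.proportions["mixed"] == 0.0
        assert rep.n_pure_A == 1 and rep.n_pure_B == 1

    def test_half_mixed(self):
        rep = mixture_report(
            [summarize_fibril([A, B]), summarize_fibril([A, A])], min_segments=1
        )
        assert rep.proportions["mixed"] == pytest.approx(0.5)

    def test_threshold_filters(self):
        rep = mixture_report(_summaries_from([(1, 1), (5, 5)]), min_segments=4)
        assert rep.n_fibrils == 1

    def test_proportions_sum_to_one(self, rng):
        summaries = _summaries_from(
            [(int(rng.integers(0, 5)), int(rng.integers(0, 5))) for _ in range(300)]
        )
        rep = mixture_report(summaries)
        if rep.n_fibrils:
            assert sum(rep.proportions.values()) == pytest.approx(1.0)

    def test_run_structures_listed(self):
        rep = mixture_report([summarize_fibril([A, A, B], fibril_id=("m", 1))])
        assert rep.run_structures == [
            {"fibril_id": ["m", 1], "runs": [["A", 2], ["B", 1]],
             "fraction_B": pytest.approx(1 / 3)}
        ]


def test_summarize_table_orders_by_fibril(small_table):
    summaries = summarize_table(small_table)
    assert [s.fibril_id for s in summaries] == [
        ("mic1.mrc", 1), ("mic1.mrc", 2), ("mic2.mrc", 1)
    ]
    assert sum(s.n_segments for s in summaries) == len(small_table)
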