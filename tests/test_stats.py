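import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from conftest import make_protein, track_from_flags
from vtdisorder.metrics import BinaryMask, DisorderSummary, summarize_protein
from vtdisorder.records import DomainHit, Segment
from vtdisorder.stats import (
    BackgroundCounts,
    classify_domain_context,
    compare_pathways,
    enrichment_test,
    group_summary,
    ldr_prevalence,
    rank_sum_test,
    select_highly_disordered,
)
from vtdisorder.synth import GroupSpec, sample_planted_contents


def summary(accession, dc, ldr30=0.0, dbr=None, n_ldr30=0):
    return DisorderSummary(
        accession=accession,
        length=100,
        effective_length=100,
        disorder_content=dc,
        ldr_residue_ratio={30: ldr30, 50: 0.0, 100: 0.0},
        n_ldr={30: n_ldr30, 50: 0, 100: 0},
        dbr_residue_ratio=dbr,
        n_dbr=None if dbr is None else 1,
    )


def enumeration_pvalues(a, b):
    """Exhaustive permutation oracle for the tie-free rank-sum test."""
    pooled = list(a) + list(b)
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)

    def u_of(indices):
        sample = [pooled[i] for i in indices]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(indices)]
        return sum(1 for x in sample for y in rest if x > y)

    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    total = len(us)
    p_less = sum(1 for u in us if u <= u_obs) / total
    p_greater = sum(1 for u in us if u >= u_obs) / total
    return {"less": p_less, "greater": p_greater,
            "two_sided": min(1.0, 2 * min(p_less, p_greater))}


def hypergeom_tail_oracle(k, n, K, N):
    """Exact upper-tail hypergeometric probability via integer arithmetic."""
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return float(total)


class TestGroupSummary:
    def test_mean_and_median(self):
        rows = group_summary(
            [summary("a", 0.10), summary("b", 0.20), summary("c", 0.30)],
            {"a": "G", "b": "G", "c": "G"},
        )
        assert rows[0].n_proteins == 3
        assert rows[0].mean_disorder_content == pytest.approx(0.20)
        assert rows[0].median_disorder_content == pytest.approx(0.20)

    def test_even_n_median_midpoint(self):
        rows = group_summary(
            [summary(x, dc) for x, dc in zip("abcd", [0.1, 0.2, 0.3, 0.4])],
            dict.fromkeys("abcd", "G"),
        )
        assert rows[0].median_disorder_content == pytest.approx(0.25)

    def test_multi_label_protein_counted_per_label(self):
        rows = group_summary(
            [summary("a", 0.5), summary("b", 0.1)],
            {"a": ["COPI", "COPII"], "b": ["COPI"]},
        )
        by_label = {r.group_label: r for r in rows}
        assert by_label["COPI"].n_proteins == 2
        assert by_label["COPII"].n_proteins == 1

    def test_planted_mean_recovered(self, rng):
        spec = GroupSpec("G", 100, target_mean_dc=0.28, dc_sd=0.05)
        values = sample_planted_contents(spec, rng)
        rows = group_summary(
            [summary(f"p{i}", v) for i, v in enumerate(values)],
            {f"p{i}": "G" for i in range(100)},
        )
        assert rows[0].mean_disorder_content == pytest.approx(0.28, abs=0.015)


class TestPrevalence:
    def test_fraction_per_k(self):
        summaries = [summary(f"p{i}", 0.5, n_ldr30=1 if i < 6 else 0) for i in range(10)]
        for s in summaries:  # the 35-residue LDR counts at k=30 but not k=50
            s.n_ldr[50] = 0
            s.n_ldr[100] = 0
        (row,) = ldr_prevalence(summaries, {s.accession: "G" for s in summaries})
        assert row.fraction_with_ldr[30] == pytest.approx(0.6)
        assert row.fraction_with_ldr[50] == 0.0

    def test_short_proteins_have_zero_prevalence(self):
        summaries = [
            summarize_protein(make_protein(20, f"p{i}"), track_from_flags([True] * 20))
            for i in range(4)
        ]
        (row,) = ldr_prevalence(summaries, {s.accession: "G" for s in summaries})
        assert all(v == 0.0 for v in row.fraction_with_ldr.values())

    def test_matches_brute_force_recount(self, rng):
        summaries = []
        for i in range(30):
            flags = rng.uniform(size=200) < 0.5
            summaries.append(summarize_protein(make_protein(200, f"p{i}"), track_from_flags(flags)))
        (row,) = ldr_prevalence(summaries, {s.accession: "G" for s in summaries})
        for k in (30, 50, 100):
            expected = sum(1 for s in summaries if s.n_ldr[k] > 0) / 30
            assert row.fraction_with_ldr[k] == pytest.approx(expected)


class TestRankSum:
    def test_exact_small_sample(self):
        assert rank_sum_test([1, 2], [3, 4], "less").p_value == pytest.approx(1 / 6)
        assert rank_sum_test([1, 2, 3], [4, 5, 6], "two_sided").p_value == pytest.approx(0.10)

    def test_degenerate_identical_samples(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_matches_enumeration_oracle(self, rng):
        for n1 in range(1, 6):
            for n2 in range(1, 11 - n1):
                values = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                a, b = values[:n1], values[n1:]
                oracle = enumeration_pvalues(a, b)
                for alternative in ("less", "greater", "two_sided"):
                    got = rank_sum_test(a, b, alternative).p_value
                    assert got == pytest.approx(oracle[alternative], abs=1e-12), (
                        n1, n2, alternative)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        a = np.round(rng.uniform(size=40), 1)  # forces ties
        b = np.round(rng.uniform(size=40) + 0.2, 1)
        res = rank_sum_test(a, b, "less")
        assert 0.0 < res.p_value < 0.05


class TestEnrichment:
    def test_zero_flagged_has_p_one(self):
        assert enrichment_test(0, 10, 50, 100, "greater").p_value == pytest.approx(1.0)

    def test_matches_direct_summation(self):
        p = enrichment_test(5, 10, 50, 100, "greater").p_value
        assert p == pytest.approx(hypergeom_tail_oracle(5, 10, 50, 100), rel=1e-9)

    def test_fully_flagged_closed_form(self):
        p = enrichment_test(8, 8, 8, 60, "greater").p_value
        assert p == pytest.approx(1 / math.comb(60, 8), rel=1e-9)

    def test_tails_overlap_at_observed_value(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 200))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, K + n - N), min(n, K) + 1))
            pg = enrichment_test(k, n, K, N, "greater").p_value
            pl = enrichment_test(k, n, K, N, "less").p_value
            assert pg + pl >= 1.0 - 1e-9

    def test_background_smaller_than_group_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(1, 50, 10, 20)


class TestComparePathways:
    @staticmethod
    def cohort(rng, mean_a, mean_b, n=30, sd=0.08):
        groups = {}
        summaries = []
        for label, mean in (("CLTR", mean_a), ("COPI", mean_b)):
            values = sample_planted_contents(GroupSpec(label, n, mean, sd), rng)
            for i, v in enumerate(values):
                acc = f"{label}{i}"
                summaries.append(summary(acc, float(v)))
                groups[acc] = label
        return summaries, groups

    def test_planted_effect_detected(self, rng):
        summaries, groups = self.cohort(rng, 0.28, 0.09)
        background = BackgroundCounts(1000, {30: 450, 50: 330, 100: 180})
        report = compare_pathways(summaries, groups, background)
        (entry,) = [e for e in report.pairwise if e.description.startswith("disorder_content")]
        assert entry.result.p_value < 0.01
        assert entry.p_adjusted is not None

    def test_null_pvalue_not_extreme(self, rng):
        summaries, groups = self.cohort(rng, 0.20, 0.20)
        background = BackgroundCounts(1000, {30: 450, 50: 330, 100: 180})
        report = compare_pathways(summaries, groups, background)
        (entry,) = [e for e in report.pairwise if e.description.startswith("disorder_content")]
        assert entry.result.p_value > 0.001

    def test_power_monotone_in_effect_size(self, rng):
        pvalues = []
        for mean_a in (0.10, 0.16, 0.26):
            rejections = 0
            for _ in range(40):
                summaries, groups = self.cohort(rng, mean_a, 0.10, n=25)
                a = [s.disorder_content for s in summaries if groups[s.accession] == "CLTR"]
                b = [s.disorder_content for s in summaries if groups[s.accession] == "COPI"]
                rejections += rank_sum_test(a, b).p_value < 0.05
            pvalues.append(rejections)
        assert pvalues[0] <= pvalues[1] <= pvalues[2]

    def test_missing_background_rejected(self):
        with pytest.raises(ValueError):
            compare_pathways([summary("a", 0.1)], {"a": "G"}, None)


class TestHighlyDisordered:
    def test_selection_rules(self):
        cohort = [
            summary("high_dc", 0.75, ldr30=0.05),
            summary("high_ldr", 0.40, ldr30=0.55),
            summary("low1", 0.10, ldr30=0.05),
            summary("low2", 0.12, ldr30=0.04),
        ]
        calls = {c.accession: c for c in select_highly_disordered(cohort)}
        assert calls["high_dc"].selected and calls["high_dc"].passed_dc
        assert calls["high_ldr"].selected and calls["high_ldr"].passed_ldr
        assert not calls["low1"].selected
        assert not calls["low2"].selected

    def test_max_rule_is_stricter_or_equal(self):
        cohort = [summary(f"p{i}", 0.1, ldr30=x) for i, x in enumerate([0.05, 0.1, 0.52, 0.6])]
        n_min = sum(c.selected for c in select_highly_disordered(cohort, ldr_rule="min"))
        n_max = sum(c.selected for c in select_highly_disordered(cohort, ldr_rule="max"))
        assert n_max <= n_min

    def test_requires_cohort(self):
        with pytest.raises(ValueError):
            select_highly_disordered([summary("a", 0.9)])


class TestDomainContext:
    def test_n_terminal_domain_with_disordered_tail(self):
        # single domain at the N-terminus, the rest ~90% disordered
        flags = [False] * 150 + [True] * 405 + [False] * 45
        mask = BinaryMask(flags, [False] * 600)
        ((_, label),) = classify_domain_context([DomainHit("ENTH", Segment(1, 150))], mask)
        assert label == "island_C"

    def test_central_domain_flanked_on_both_sides(self):
        flags = [True] * 100 + [False] * 50 + [True] * 100
        mask = BinaryMask(flags, [False] * 250)
        ((_, label),) = classify_domain_context([DomainHit("Sec16", Segment(101, 150))], mask)
        assert label == "island_both"

    def test_embedded_domain(self):
        flags = [False] * 250
        mask = BinaryMask(flags, [False] * 250)
        ((_, label),) = classify_domain_context([DomainHit("PK", Segment(101, 150))], mask)
        assert label == "embedded"

    def test_short_flank_does_not_qualify(self):
        flags = [True] * 20 + [False] * 50 + [True] * 100
        mask = BinaryMask(flags, [False] * 170)
        ((_, label),) = classify_domain_context([DomainHit("D", Segment(21, 70))], mask)
        assert label == "island_C"
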