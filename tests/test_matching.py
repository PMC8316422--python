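import itertools

import numpy as np
import pytest

from intratad.intervals import GenomicInterval, MotifHit, overlap_bp, reciprocal_overlap
from intratad.io import LoopRecord
from intratad.matching import (
    MatchParams,
    compare_conditions,
    integrate_patient_tads,
    loops_with_anchor_motifs,
    match_summary,
    match_tads,
    score_test,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def q(i, start, end, chrom="chr1"):
    return (f"q{i}", iv(start, end, chrom))


def r(i, start, end, chrom="chr1"):
    return (f"r{i}", iv(start, end, chrom))


class TestLoopMotifFilter:
    def motif(self, start, chrom="chr1", pvalue=1e-6):
        return MotifHit(GenomicInterval(chrom, start, start + 19, "+"),
                        "MA0139.1", 20.0, pvalue)

    def loop(self, a1, a2):
        return LoopRecord(iv(*a1), iv(*a2))

    def test_both_anchors_required(self):
        loops = [
            self.loop((0, 1000), (50_000, 51_000)),      # motifs in both
            self.loop((100_000, 101_000), (150_000, 151_000)),  # one only
        ]
        motifs = [self.motif(500), self.motif(50_500), self.motif(100_500)]
        kept = loops_with_anchor_motifs(loops, motifs)
        assert kept == [loops[0]]

    def test_no_motifs_empty(self):
        assert loops_with_anchor_motifs([self.loop((0, 1000), (5000, 6000))], []) == []

    def test_pvalue_cutoff_applied(self):
        loops = [self.loop((0, 1000), (5000, 6000))]
        weak = [self.motif(500, pvalue=1e-2), self.motif(5500, pvalue=1e-2)]
        assert loops_with_anchor_motifs(loops, weak, pvalue_max=1e-4) == []
        assert len(loops_with_anchor_motifs(loops, weak, pvalue_max=0.1)) == 1


class TestMatchTads:
    def test_identical_is_complete(self):
        (res,) = match_tads([q(0, 0, 1000)], [r(0, 0, 1000)])
        assert res.category == "complete" and res.overlap_fraction == 1.0
        assert res.subtype == "none"

    def test_query_contains_reference_include(self):
        (res,) = match_tads([q(0, 0, 1000)], [r(0, 100, 900)])
        assert (res.category, res.subtype) == ("partial", "include")
        assert res.overlap_fraction == pytest.approx(0.8)  # min(0.8, 1.0)

    def test_reference_contains_query_inside(self):
        (res,) = match_tads([q(0, 100, 900)], [r(0, 0, 1000)])
        assert (res.category, res.subtype) == ("partial", "inside")

    def test_disjoint_unmatched(self):
        (res,) = match_tads([q(0, 0, 1000)], [r(0, 5000, 6000)])
        assert res.category == "unmatched" and res.reference_id is None
        assert res.overlap_fraction == 0.0

    def test_displacement_by_midpoint(self):
        (res,) = match_tads([q(0, 0, 1000)], [r(0, 500, 1500)])
        assert (res.category, res.subtype) == ("partial", "displaced_upstream")
        (res,) = match_tads([q(0, 500, 1500)], [r(0, 0, 1000)])
        assert res.subtype == "displaced_downstream"

    def test_best_match_highest_overlap(self):
        refs = [r(0, 0, 2000), r(1, 0, 1100)]
        (res,) = match_tads([q(0, 0, 1000)], refs)
        assert res.reference_id == "r1"  # min-fraction 1000/1100 > 1000/2000

    def test_empty_reference_all_unmatched(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            results = match_tads([q(0, 0, 1000), q(1, 5000, 9000)], [])
        assert all(x.category == "unmatched" for x in results)
        assert "empty reference" in caplog.text

    def test_threshold_monotone_complete_count(self):
        rng = np.random.default_rng(13)
        queries = [q(i, int(s), int(s) + int(l))
                   for i, (s, l) in enumerate(zip(rng.integers(0, 50_000, 40),
                                                  rng.integers(100, 3000, 40)))]
        refs = [r(i, int(s), int(s) + int(l))
                for i, (s, l) in enumerate(zip(rng.integers(0, 50_000, 40),
                                               rng.integers(100, 3000, 40)))]
        counts = []
        for thr in (0.5, 0.75, 0.9, 0.95, 1.0):
            res = match_tads(queries, refs,
                             MatchParams(complete_threshold=thr,
                                         unchanged_threshold=0.5))
            counts.append(sum(1 for x in res if x.category == "complete"))
        assert counts == sorted(counts, reverse=True)

    def test_agrees_with_bruteforce_oracle(self):
        params = MatchParams()
        rng = np.random.default_rng(21)
        for _ in range(20):
            def mk(prefix, n):
                out = []
                for i in range(n):
                    chrom = "chr1" if rng.random() < 0.7 else "chr2"
                    s = int(rng.integers(0, 40_000))
                    out.append((f"{prefix}{i}", iv(s, s + int(rng.integers(50, 5000)), chrom)))
                return out

            queries = mk("q", int(rng.integers(1, 60)))
            refs = mk("r", int(rng.integers(1, 60)))
            results = match_tads(queries, refs, params)
            for (qid, qiv), res in zip(queries, results):
                cands = [
                    (rid, riv) for rid, riv in refs
                    if overlap_bp(qiv, riv) >= 1
                ]
                if not cands:
                    assert res.category == "unmatched"
                    continue
                best = max(
                    cands,
                    key=lambda c: (
                        min(reciprocal_overlap(qiv, c[1])),
                        overlap_bp(qiv, c[1]),
                        -c[1].start,
                        c[0],
                    ),
                )
                rid, riv = best
                assert res.reference_id == rid
                fq, fr = reciprocal_overlap(qiv, riv)
                if fq >= 0.95 and fr >= 0.95:
                    assert res.category == "complete"
                elif qiv.contains(riv):
                    assert res.subtype == "include"
                elif riv.contains(qiv):
                    assert res.subtype == "inside"
                elif qiv.midpoint <= riv.midpoint:
                    assert res.subtype == "displaced_upstream"
                else:
                    assert res.subtype == "displaced_downstream"


class TestMatchSummary:
    def test_reference_fractions(self):
        results = match_tads(
            [q(0, 0, 1000), q(1, 2000, 3000), q(2, 4000, 4500), q(3, 9000, 9900)],
            [r(0, 0, 1000), r(1, 2000, 3000), r(2, 4000, 4600)],
        )
        s = match_summary(results)
        assert s["category_fractions"] == {
            "complete": 0.5, "partial": 0.25, "unmatched": 0.25,
        }
        assert sum(s["category_fractions"].values()) == pytest.approx(1.0)

    def test_all_complete(self):
        results = match_tads([q(0, 0, 1000)], [r(0, 0, 1000)])
        s = match_summary(results)
        assert s["category_fractions"]["complete"] == 1.0
        assert s["subtype_fractions"] is None

    def test_subtype_fractions_partition_partials(self):
        results = match_tads(
            [q(0, 0, 1000), q(1, 2100, 2900), q(2, 4500, 5500), q(3, 8500, 9500)],
            [r(0, 100, 900), r(1, 2000, 3000), r(2, 4000, 5000), r(3, 9000, 10_000)],
        )
        s = match_summary(results)
        assert sum(s["subtype_fractions"].values()) == pytest.approx(1.0)
        assert s["subtype_fractions"]["include"] == 0.25
        assert s["subtype_fractions"]["inside"] == 0.25
        assert (
            s["subtype_fractions"]["displaced_upstream"]
            + s["subtype_fractions"]["displaced_downstream"]
            == pytest.approx(0.5)
        )

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            match_summary([])


class TestCompareConditions:
    def test_identical_sets_all_unchanged(self):
        x = [q(i, i * 10_000, i * 10_000 + 5000) for i in range(10)]
        res = compare_conditions(x, x)
        assert res["fraction_unchanged"] == 1.0
        assert res["fraction_different"] == 0.0

    def test_below_threshold_is_different(self):
        # best control overlap 0.74 < 0.75 (strict >)
        control = [r(0, 0, 10_000)]
        patient = [q(0, 2600, 10_000)]  # 7400/10000 = 0.74
        res = compare_conditions(control, patient)
        assert res["fraction_different_below_threshold"] == 1.0

    def test_exactly_at_threshold_is_different(self):
        control = [r(0, 0, 10_000)]
        patient = [q(0, 2500, 10_000)]  # exactly 0.75
        res = compare_conditions(control, patient)
        assert res["fraction_different"] == 1.0

    def test_missing_chromosome_is_unmatched(self):
        control = [r(0, 0, 10_000, chrom="chr1")]
        patient = [q(0, 0, 10_000, chrom="chr2")]
        res = compare_conditions(control, patient)
        assert res["fraction_different_unmatched"] == 1.0

    def test_empty_patient_is_error(self):
        with pytest.raises(ValueError):
            compare_conditions([r(0, 0, 1000)], [])


class TestIntegration:
    def test_identical_sets_integrate_to_one(self):
        from helpers_tads import make_simple_tad

        a = [make_simple_tad(0, 10_000, "t1")]
        b = [make_simple_tad(0, 10_000, "t2")]
        merged = integrate_patient_tads([a, b])
        assert len(merged) == 1

    def test_disjoint_sets_concatenate(self):
        from helpers_tads import make_simple_tad

        a = [make_simple_tad(0, 10_000, "t1")]
        b = [make_simple_tad(100_000, 120_000, "t2")]
        assert len(integrate_patient_tads([a, b])) == 2

    def test_near_duplicate_keeps_wider(self):
        from helpers_tads import make_simple_tad

        a = [make_simple_tad(0, 10_000, "narrow")]
        b = [make_simple_tad(0, 10_100, "wide")]
        merged = integrate_patient_tads([a, b])
        assert [t.tad_id for t in merged] == ["wide"]


class TestScoreTest:
    def test_identical_samples_p_one(self):
        res = score_test([1, 2, 3], [1, 2, 3])
        assert res.pvalue == pytest.approx(1.0)

    def test_all_tied_p_one(self):
        assert score_test([5, 5], [5, 5, 5]).pvalue == 1.0

    def test_separated_samples_exact_p(self):
        res = score_test([1, 2, 3], [10, 20, 30])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)
        assert (res.median_a, res.median_b) == (2.0, 20.0)

    def test_shift_invariance(self):
        a, b = [1.0, 5.0, 9.0, 2.0], [3.0, 7.0, 11.0]
        p0 = score_test(a, b).pvalue
        p1 = score_test([x + 100 for x in a], [x + 100 for x in b]).pvalue
        assert p0 == pytest.approx(p1)

    def test_exact_matches_scipy_exact_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(31)
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(2, 8)))
            b = rng.normal(size=int(rng.integers(2, 8)))
            ours = score_test(a, b).pvalue
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref), rel=1e-9)

    def test_large_samples_use_asymptotic(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0.8, 1, 60)
        res = score_test(a, b)
        assert res.method == "asymptotic"
        assert 0 < res.pvalue < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            score_test([], [1.0])
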