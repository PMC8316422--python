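"""Matching predicted loops against reference loop sets.

Classifies each query loop against a reference set (experimental Hi-C
loops, or loops predicted under another condition) as a complete match
(95% reciprocal overlap), a partial match with a subtype (include /
inside / displaced upstream / displaced downstream), or unmatched; picks
the best reference by overlap when several hit; compares conditions at
the 75% "unchanged" criterion; and tests score distributions with a
rank-sum (Wilcoxon / Mann-Whitney) test, exact at small sample sizes.

The ranking statistic (``overlap_fraction``) is the minimum of the two
reciprocal overlap fractions: symmetric, conservative, and making the 95%
complete-match rule a special case of the same statistic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval, overlap_bp, reciprocal_overlap

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "MatchParams",
    "loops_with_anchor_motifs",
    "match_tads",
    "match_summary",
    "compare_conditions",
    "integrate_patient_tads",
    "score_test",
]

Category = Literal["complete", "partial", "unmatched"]
Subtype = Literal["include", "inside", "displaced_upstream", "displaced_downstream", "none"]


@dataclass
class MatchResult:
    query_id: str
    reference_id: Optional[str]
    category: Category
    subtype: Subtype
    overlap_fraction: float


@dataclass
class MatchParams:
    """Thresholds for loop matching and condition comparison.

    complete_threshold : reciprocal overlap (both directions) at or above
        which a match is complete (default 0.95).
    unchanged_threshold : overlap above which a loop counts as unchanged
        between conditions (default 0.75, strict >).
    fraction_statistic : how the scalar overlap_fraction is derived from
        the two reciprocal fractions: "min" (default), "mean", or "query"
        (query-directional).
    """

    complete_threshold: float = 0.95
    unchanged_threshold: float = 0.75
    fraction_statistic: str = "min"

    def __post_init__(self) -> None:
        for name in ("complete_threshold", "unchanged_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.unchanged_threshold > self.complete_threshold:
            raise ValueError("unchanged_threshold must be <= complete_threshold")
        if self.fraction_statistic not in ("min", "mean", "query"):
            raise ValueError(
                f"unknown fraction_statistic {self.fraction_statistic!r}"
            )


def _id_span(item, default_prefix: str, i: int) -> tuple[str, GenomicInterval]:
    """Accept PredictedTAD, LoopRecord, (id, interval) pairs, or intervals."""
    if isinstance(item, GenomicInterval):
        return f"{default_prefix}_{i}", item
    if isinstance(item, tuple) and len(item) == 2:
        return str(item[0]), item[1]
    span = item.span
    ident = getattr(item, "tad_id", None) or getattr(item, "source_id", None)
    return ident or f"{default_prefix}_{i}", span


def _as_span_list(items: Sequence, prefix: str) -> list[tuple[str, GenomicInterval]]:
    return [_id_span(x, prefix, i) for i, x in enumerate(items)]


def loops_with_anchor_motifs(
    loops: Sequence, motifs: Sequence, pvalue_max: float = 1e-4
) -> list:
    """Keep loops with a CTCF motif hit at both anchors.

    A loop qualifies when each of its two anchor intervals overlaps at
    least one motif hit with p-value <= ``pvalue_max``.
    """
    trees: dict[str, IntervalTree] = {}
    for m in motifs:
        if m.pvalue <= pvalue_max:
            trees.setdefault(m.interval.chrom, IntervalTree()).addi(
                m.interval.start, m.interval.end
            )

    def _has_motif(iv: GenomicInterval) -> bool:
        t = trees.get(iv.chrom)
        return t is not None and bool(t.overlap(iv.start, iv.end))

    return [lp for lp in loops if _has_motif(lp.anchor1) and _has_motif(lp.anchor2)]


def _overlap_statistic(
    q: GenomicInterval, r: GenomicInterval, statistic: str
) -> float:
    fq, fr = reciprocal_overlap(q, r)
    if statistic == "min":
        return min(fq, fr)
    if statistic == "mean":
        return (fq + fr) / 2
    return fq  # query-directional


def match_tads(
    query: Sequence,
    reference: Sequence,
    params: Optional[MatchParams] = None,
) -> list[MatchResult]:
    """Classify every query loop span against the reference loop spans.

    For each query, all same-chromosome references with >= 1 bp overlap
    are candidates; the best is the one with the highest overlap_fraction
    (ties broken by larger raw overlap, then leftmost reference start).
    Complete requires both reciprocal fractions >= complete_threshold and
    is tested before the partial subtypes; containment is non-strict.
    Displacement direction follows the sign of query midpoint minus
    reference midpoint. Queries with no candidate are unmatched.
    """
    params = params or MatchParams()
    q_list = _as_span_list(query, "query")
    r_list = _as_span_list(reference, "ref")
    if not r_list:
        logger.warning("empty reference set: all %d queries unmatched", len(q_list))

    trees: dict[str, IntervalTree] = {}
    for j, (_, r) in enumerate(r_list):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, j)

    results: list[MatchResult] = []
    for qid, q in q_list:
        t = trees.get(q.chrom)
        best_j = None
        best_key = None
        if t is not None:
            for hit in t.overlap(q.start, q.end):
                j = hit.data
                rid, r = r_list[j]
                frac = _overlap_statistic(q, r, params.fraction_statistic)
                key = (frac, overlap_bp(q, r), -r.start, rid)
                if best_key is None or key > best_key:
                    best_key = key
                    best_j = j
        if best_j is None:
            results.append(MatchResult(qid, None, "unmatched", "none", 0.0))
            continue
        rid, r = r_list[best_j]
        fq, fr = reciprocal_overlap(q, r)
        frac = _overlap_statistic(q, r, params.fraction_statistic)
        if fq >= params.complete_threshold and fr >= params.complete_threshold:
            results.append(MatchResult(qid, rid, "complete", "none", frac))
        elif q.contains(r):
            results.append(MatchResult(qid, rid, "partial", "include", frac))
        elif r.contains(q):
            results.append(MatchResult(qid, rid, "partial", "inside", frac))
        else:
            sub = (
                "displaced_upstream"
                if q.midpoint <= r.midpoint
                else "displaced_downstream"
            )
            results.append(MatchResult(qid, rid, "partial", sub, frac))
    return results


def match_summary(
    results: Sequence[MatchResult], over_threshold: float = 0.75
) -> dict:
    """Category and partial-subtype fractions of a match run.

    Category fractions partition the input (sum to 1); subtype fractions
    partition the partial matches. Also reports the fraction of queries
    whose overlap_fraction strictly exceeds ``over_threshold``.
    """
    if not results:
        raise ValueError("cannot summarize an empty match list")
    n = len(results)
    cats = {"complete": 0, "partial": 0, "unmatched": 0}
    subs = {
        "include": 0,
        "inside": 0,
        "displaced_upstream": 0,
        "displaced_downstream": 0,
    }
    over = 0
    for r in results:
        cats[r.category] += 1
        if r.category == "partial":
            subs[r.subtype] += 1
        if r.overlap_fraction > over_threshold:
            over += 1
    n_partial = cats["partial"]
    return {
        "n": n,
        "category_fractions": {k: v / n for k, v in cats.items()},
        "subtype_fractions": (
            {k: v / n_partial for k, v in subs.items()} if n_partial else None
        ),
        "fraction_over_threshold": over / n,
        "over_threshold": over_threshold,
    }


def compare_conditions(
    control_tads: Sequence,
    patient_tads: Sequence,
    params: Optional[MatchParams] = None,
) -> dict:
    """Label each patient loop unchanged vs different against the control set.

    A patient loop is unchanged iff its best control match has
    overlap_fraction strictly > ``unchanged_threshold``; otherwise it is
    different, subdivided into unmatched (no overlapping control loop)
    and matched-below-threshold.
    """
    params = params or MatchParams()
    if not patient_tads:
        raise ValueError("patient TAD set is empty")
    results = match_tads(patient_tads, control_tads, params)
    n = len(results)
    labels = []
    unmatched = below = 0
    for r in results:
        if r.overlap_fraction > params.unchanged_threshold:
            labels.append((r.query_id, "unchanged"))
        elif r.category == "unmatched":
            labels.append((r.query_id, "different_unmatched"))
            unmatched += 1
        else:
            labels.append((r.query_id, "different_below_threshold"))
            below += 1
    return {
        "n": n,
        "labels": labels,
        "results": results,
        "fraction_unchanged": (n - unmatched - below) / n,
        "fraction_different": (unmatched + below) / n,
        "fraction_different_unmatched": unmatched / n,
        "fraction_different_below_threshold": below / n,
    }


def integrate_patient_tads(
    tad_sets: Sequence[Sequence], params=None, mode: str = "union"
):
    """Merge loop lists from several samples into one integrated list.

    "union" (default) concatenates the sets and collapses cross-set
    redundancy with the caller's rule (same upstream anchor interval plus
    98% reciprocal overlap; wider kept). "intersection" keeps loops of
    the first set whose span completely matches (95% reciprocal) a loop
    in every other set.
    """
    from .caller import CallerParams, remove_redundant

    if len(tad_sets) < 2:
        raise ValueError("integration needs >= 2 TAD sets")
    cparams = params if isinstance(params, CallerParams) else CallerParams()
    if mode == "union":
        merged = [t for s in tad_sets for t in s]
        return remove_redundant(merged, cparams)
    if mode == "intersection":
        mparams = MatchParams()
        base = list(tad_sets[0])
        keep = []
        for t in base:
            ok = True
            for other in tad_sets[1:]:
                res = match_tads([t], other, mparams)
                if res[0].category != "complete":
                    ok = False
                    break
            if ok:
                keep.append(t)
        return keep
    raise ValueError(f"unknown integration mode {mode!r}")


@dataclass
class ScoreTestResult:
    pvalue: float
    median_a: float
    median_b: float
    method: str


def _exact_rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value by full enumeration.

    Enumerates all C(n, n_a) assignments of the pooled observations to
    group A via a subset-sum dynamic program over doubled midranks
    (integer-valued, tie-safe) and doubles the smaller tail.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks2 = np.round(2 * rankdata(pooled)).astype(int)  # doubled midranks
    n, na = len(pooled), len(a)
    obs = int(ranks2[:na].sum())

    max_sum = int(ranks2.sum())
    # count[k][s] = number of k-subsets of the pooled items with doubled
    # rank sum s
    count = np.zeros((na + 1, max_sum + 1), dtype=float)
    count[0][0] = 1.0
    for r in ranks2:
        for k in range(min(na, n) - 1, -1, -1):
            nz = np.nonzero(count[k])[0]
            count[k + 1][nz + r] += count[k][nz]
    dist = count[na]
    total = dist.sum()
    lower = dist[: obs + 1].sum() / total
    upper = dist[obs:].sum() / total
    return float(min(1.0, 2 * min(lower, upper)))


def score_test(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> ScoreTestResult:
    """Two-sided rank-sum test comparing two score distributions.

    Exact enumeration of the permutation distribution when the pooled
    sample size is <= 20 (tie-safe); the normal approximation with tie
    correction otherwise. Two samples with all values tied give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return ScoreTestResult(1.0, med_a, med_b, "degenerate")
    if a.size + b.size <= 20:
        p = _exact_rank_sum_pvalue(a, b)
        return ScoreTestResult(p, med_a, med_b, "exact")
    from scipy.stats import mannwhitneyu

    stat = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return ScoreTestResult(float(stat.pvalue), med_a, med_b, "asymptotic")
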