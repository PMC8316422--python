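"""In silico intra-TAD loop prediction from cohesin + CTCF ChIP-seq.

The predictor rests on two structural features of TAD/loop boundaries:
(i) anchors are co-bound by cohesin and CTCF, and (ii) the CTCF motifs of
the two anchors of a loop point toward each other (convergent
orientation). An anchor is a cohesin peak overlapping a CTCF peak that
contains an oriented CTCF motif; its score is the geometric mean of the
cohesin peak strength and the motif log-odds score. Convergent anchor
pairs within a span cap become candidate loops when the weaker anchor
carries at least the minimum proportion (default 40%) of the stronger
anchor's score; near-identical loops sharing an upstream anchor are
collapsed to the wider one at 98% reciprocal overlap; each surviving loop
is scored by the geometric mean of its two anchor scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval, MotifHit, Peak, overlap_bp, reciprocal_overlap

__all__ = [
    "Anchor",
    "PredictedTAD",
    "CallerParams",
    "motif_score_shift",
    "build_anchors",
    "enumerate_candidate_loops",
    "remove_redundant",
    "summarize_tads",
    "call_tads",
]

Orientation = Literal["forward", "reverse"]


@dataclass
class Anchor:
    """A cohesin+CTCF co-bound site with CTCF motif orientation.

    ``anchor_score`` is the geometric mean of the cohesin peak strength
    and the (shifted-positive) CTCF motif score.
    """

    interval: GenomicInterval
    orientation: Orientation
    cohesin_score: float
    ctcf_score: float
    anchor_id: str = ""
    anchor_score: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cohesin_score <= 0 or self.ctcf_score <= 0:
            raise ValueError(
                f"anchor {self.anchor_id or self.interval}: component scores "
                "must be positive for a geometric mean"
            )
        self.anchor_score = math.sqrt(self.cohesin_score * self.ctcf_score)


@dataclass
class PredictedTAD:
    """A convergent anchor pair: forward upstream, reverse downstream."""

    upstream: Anchor
    downstream: Anchor
    tad_id: str = ""
    combined_score: float = field(init=False)

    def __post_init__(self) -> None:
        if self.upstream.orientation != "forward":
            raise ValueError("upstream anchor must carry a forward (+) motif")
        if self.downstream.orientation != "reverse":
            raise ValueError("downstream anchor must carry a reverse (-) motif")
        if self.upstream.interval.chrom != self.downstream.interval.chrom:
            raise ValueError("TAD anchors must share a chromosome")
        if self.upstream.interval.start >= self.downstream.interval.start:
            raise ValueError("upstream anchor must precede downstream anchor")
        self.combined_score = math.sqrt(
            self.upstream.anchor_score * self.downstream.anchor_score
        )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.upstream.interval.chrom,
            self.upstream.interval.start,
            self.downstream.interval.end,
        )


@dataclass
class CallerParams:
    """Tunable parameters of the loop caller.

    min_proportion : the weaker anchor of a pair must carry at least this
        fraction of the stronger anchor's score (default 0.40).
    max_span : maximum loop span in bp (default 3 Mb, typical TAD scale).
    redundancy_overlap : reciprocal-overlap threshold at which two loops
        sharing an upstream anchor collapse to the wider one (default 0.98).
    motif_pvalue_max : FIMO p-value cutoff for usable motif hits.
    pairing_rule : "balance" applies min_proportion within each pair;
        "global_fraction" instead requires every anchor's score to reach
        min_proportion of the chromosome-wide maximum before pairing.
    """

    min_proportion: float = 0.40
    max_span: int = 3_000_000
    redundancy_overlap: float = 0.98
    motif_pvalue_max: float = 1e-4
    pairing_rule: str = "balance"

    def __post_init__(self) -> None:
        for name in ("min_proportion", "redundancy_overlap"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_span <= 0:
            raise ValueError("max_span must be positive")
        if self.pairing_rule not in ("balance", "global_fraction"):
            raise ValueError(f"unknown pairing_rule {self.pairing_rule!r}")


def motif_score_shift(motifs: Sequence[MotifHit]) -> float:
    """Additive shift making all motif scores strictly positive.

    FIMO log-odds scores can be <= 0; geometric means need positive
    inputs, so when any usable score is <= 0 every score is shifted by
    ``1 - min(score)``. Zero when all scores are already positive.
    """
    if not motifs:
        return 0.0
    lo = min(m.score for m in motifs)
    return 0.0 if lo > 0 else 1.0 - lo


def build_anchors(
    cohesin_peaks: Sequence[Peak],
    ctcf_peaks: Sequence[Peak],
    motifs: Sequence[MotifHit],
    params: Optional[CallerParams] = None,
) -> list[Anchor]:
    """Identify cohesin+CTCF co-bound anchor sites with motif orientation.

    An anchor is emitted for every cohesin peak that overlaps (>= 1 bp) a
    CTCF peak containing at least one motif hit passing the p-value
    cutoff. The anchor interval is the cohesin peak; its orientation and
    CTCF score come from the best-scoring motif among the overlapping
    CTCF peaks. When several cohesin peaks overlap one CTCF peak each
    yields its own anchor (deduplication happens at the loop-redundancy
    stage).
    """
    params = params or CallerParams()
    usable = [m for m in motifs if m.pvalue <= params.motif_pvalue_max]
    shift = motif_score_shift(usable)

    # best motif per CTCF peak
    motif_trees: dict[str, IntervalTree] = {}
    for idx, m in enumerate(usable):
        motif_trees.setdefault(m.interval.chrom, IntervalTree()).addi(
            m.interval.start, m.interval.end, idx
        )

    ctcf_best: list[Optional[MotifHit]] = []
    ctcf_trees: dict[str, IntervalTree] = {}
    for ci, cp in enumerate(ctcf_peaks):
        t = motif_trees.get(cp.interval.chrom)
        best: Optional[MotifHit] = None
        if t is not None:
            for hit in t.overlap(cp.interval.start, cp.interval.end):
                m = usable[hit.data]
                if best is None or m.score > best.score:
                    best = m
        ctcf_best.append(best)
        if best is not None:
            ctcf_trees.setdefault(cp.interval.chrom, IntervalTree()).addi(
                cp.interval.start, cp.interval.end, ci
            )

    anchors: list[Anchor] = []
    for i, cp in enumerate(cohesin_peaks):
        t = ctcf_trees.get(cp.interval.chrom)
        if t is None:
            continue
        best: Optional[MotifHit] = None
        for hit in t.overlap(cp.interval.start, cp.interval.end):
            m = ctcf_best[hit.data]
            if m is not None and (best is None or m.score > best.score):
                best = m
        if best is None:
            continue
        if cp.score <= 0:
            raise ValueError(
                f"cohesin peak {cp.name or str(cp.interval)} has nonpositive "
                "score; cannot compute anchor geometric mean"
            )
        ctcf_score = best.score + shift
        if ctcf_score <= 0:
            raise ValueError("motif score nonpositive after shift")
        anchors.append(
            Anchor(
                interval=cp.interval,
                orientation="forward" if best.interval.strand == "+" else "reverse",
                cohesin_score=cp.score,
                ctcf_score=ctcf_score,
                anchor_id=f"anchor_{i}",
            )
        )
    anchors.sort(key=lambda a: (a.interval.chrom, a.interval.start))
    for i, a in enumerate(anchors):
        a.anchor_id = f"anchor_{i:05d}"
    return anchors


def enumerate_candidate_loops(
    anchors: Sequence[Anchor], params: Optional[CallerParams] = None
) -> list[PredictedTAD]:
    """Pair convergent anchors into candidate loops (pre-redundancy).

    Every (forward, reverse) anchor pair on one chromosome with the
    forward anchor upstream and span <= ``max_span`` is a candidate; it is
    kept when it passes the minimum-proportion rule (see
    :class:`CallerParams`). The combined score is the geometric mean of
    the two anchor scores, making the accepted set invariant to a global
    rescaling of all peak and motif scores.
    """
    params = params or CallerParams()
    by_chrom: dict[str, list[Anchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.interval.chrom, []).append(a)

    tads: list[PredictedTAD] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda a: a.interval.start)
        if params.pairing_rule == "global_fraction":
            top = max(a.anchor_score for a in group)
            group = [
                a for a in group if a.anchor_score >= params.min_proportion * top
            ]
        fwd = [a for a in group if a.orientation == "forward"]
        rev = [a for a in group if a.orientation == "reverse"]
        for f in fwd:
            for r in rev:
                if f.interval.start >= r.interval.start:
                    continue
                if r.interval.end - f.interval.start > params.max_span:
                    continue
                if params.pairing_rule == "balance":
                    lo = min(f.anchor_score, r.anchor_score)
                    hi = max(f.anchor_score, r.anchor_score)
                    if lo < params.min_proportion * hi:
                        continue
                tads.append(PredictedTAD(upstream=f, downstream=r))
    tads.sort(key=lambda t: (t.span.chrom, t.span.start, t.span.end))
    for i, t in enumerate(tads):
        t.tad_id = f"tad_{i:05d}"
    return tads


def remove_redundant(
    tads: Sequence[PredictedTAD], params: Optional[CallerParams] = None
) -> list[PredictedTAD]:
    """Collapse redundant loops, keeping the wider of each redundant pair.

    Two loops are redundant when they share the same upstream anchor
    (identical anchor id / interval) and reciprocally overlap by at least
    ``redundancy_overlap`` in both directions. Collapsing is applied
    widest-first within each upstream-anchor group until a fixed point;
    the operation is idempotent and never increases the loop count.
    """
    params = params or CallerParams()
    groups: dict[tuple, list[PredictedTAD]] = {}
    for t in tads:
        key = (
            t.upstream.interval.chrom,
            t.upstream.interval.start,
            t.upstream.interval.end,
        )
        groups.setdefault(key, []).append(t)

    kept: list[PredictedTAD] = []
    for group in groups.values():
        group = sorted(group, key=lambda t: (-t.span.length, t.span.start))
        accepted: list[PredictedTAD] = []
        for t in group:
            redundant = False
            for k in accepted:
                fa, fb = reciprocal_overlap(t.span, k.span)
                if fa >= params.redundancy_overlap and fb >= params.redundancy_overlap:
                    redundant = True
                    break
            if not redundant:
                accepted.append(t)
        kept.extend(accepted)
    kept.sort(key=lambda t: (t.span.chrom, t.span.start, t.span.end))
    return kept


def summarize_tads(tads: Sequence[PredictedTAD]) -> dict[str, float]:
    """Count, median span and IQR (linear-interpolation quartiles)."""
    if not tads:
        raise ValueError("cannot summarize an empty TAD list")
    spans = np.array([t.span.length for t in tads], dtype=float)
    q25, q50, q75 = np.percentile(spans, [25, 50, 75])
    return {
        "count": len(tads),
        "median_span": float(q50),
        "iqr_span": float(q75 - q25),
    }


def call_tads(
    cohesin_peaks: Sequence[Peak],
    ctcf_peaks: Sequence[Peak],
    motifs: Sequence[MotifHit],
    params: Optional[CallerParams] = None,
) -> list[PredictedTAD]:
    """Full prediction chain: anchors -> candidate loops -> redundancy removal."""
    params = params or CallerParams()
    anchors = build_anchors(cohesin_peaks, ctcf_peaks, motifs, params)
    candidates = enumerate_candidate_loops(anchors, params)
    final = remove_redundant(candidates, params)
    for i, t in enumerate(final):
        t.tad_id = f"tad_{i:05d}"
    return final
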