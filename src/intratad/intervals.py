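"""Genomic coordinate primitives and interval arithmetic.

All coordinates are 0-based half-open throughout the package. Inputs in
1-based inclusive conventions (FIMO, printed coordinates) are converted at
the I/O boundary, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

Strand = Literal["+", "-", "."]

__all__ = [
    "GenomicInterval",
    "Peak",
    "MotifHit",
    "overlap_bp",
    "reciprocal_overlap",
    "nearest_neighbor_distances",
    "fraction_within",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start : int
        0-based inclusive start, ``0 <= start < end``.
    end : int
        Exclusive end.
    strand : {"+", "-", "."}
        Optional strand; "." when strand is meaningless.
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, other: "GenomicInterval") -> bool:
        """Non-strict containment: ``other`` lies within ``self``."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class Peak:
    """A called ChIP-seq peak.

    ``score`` is the caller's strength (e.g. Macs2 signalValue);
    ``fold_change`` the log fold-change over input when available, used by
    the LFC > 5 filter for dubious peaks.
    """

    interval: GenomicInterval
    score: float = 0.0
    summit_offset: Optional[int] = None
    fold_change: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )


@dataclass
class MotifHit:
    """A stranded motif occurrence (e.g. a FIMO CTCF MA0139.1 hit)."""

    interval: GenomicInterval
    motif_id: str
    score: float
    pvalue: float = 1.0

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("motif hits must be stranded (+ or -)")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"motif p-value must be in (0, 1], got {self.pvalue}")


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float]:
    """Overlap as a fraction of each interval's length.

    Returns ``(overlap/len(a), overlap/len(b))``; ``(0.0, 0.0)`` for
    intervals on different chromosomes. A pair passes a reciprocal-overlap
    threshold ``t`` iff both fractions are >= ``t``.
    """
    ov = overlap_bp(a, b)
    return ov / a.length, ov / b.length


def _peak_distance(a: Peak, b: Peak, convention: str) -> int:
    if convention == "midpoint":
        return abs(a.interval.midpoint - b.interval.midpoint)
    if convention == "gap":
        lo, hi = (a, b) if a.interval.start <= b.interval.start else (b, a)
        return max(0, hi.interval.start - lo.interval.end)
    raise ValueError(f"unknown distance convention {convention!r}")


def nearest_neighbor_distances(
    peaks: Sequence[Peak], convention: str = "midpoint"
) -> tuple[list[int], int]:
    """Distance from each peak to its nearest same-chromosome neighbor.

    Peaks alone on their chromosome have no neighbor; they are excluded
    from the distance list and counted in the second return value.

    Parameters
    ----------
    peaks : sequence of Peak
    convention : {"midpoint", "gap"}
        "midpoint": absolute midpoint-to-midpoint distance (default).
        "gap": edge-to-edge gap, 0 for overlapping or abutting peaks.

    Returns
    -------
    (distances, n_without_neighbor)
        ``distances`` holds one value per peak that has a neighbor, in the
        sorted (chrom, start) order of those peaks.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)

    distances: list[int] = []
    lonely = 0
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: p.interval.start)
        if len(group) < 2:
            lonely += len(group)
            continue
        if convention == "midpoint":
            # nearest distinct midpoint is adjacent once midpoints are sorted
            order = sorted(range(len(group)), key=lambda k: group[k].interval.midpoint)
            mids = [group[k].interval.midpoint for k in order]
            nearest = [0] * len(group)
            for rank, k in enumerate(order):
                cand = []
                if rank > 0:
                    cand.append(mids[rank] - mids[rank - 1])
                if rank + 1 < len(mids):
                    cand.append(mids[rank + 1] - mids[rank])
                nearest[k] = min(cand)
            distances.extend(nearest)
        else:
            for i, p in enumerate(group):
                distances.append(
                    min(
                        _peak_distance(p, q, convention)
                        for j, q in enumerate(group)
                        if j != i
                    )
                )
    return distances, lonely


def fraction_within(
    distances: Sequence[int], d: int
) -> tuple[Optional[float], int]:
    """Fraction and count of neighbor distances strictly below ``d``.

    Mirrors peak-spacing summaries of the form "N peaks (x%) located
    within < d bp" of another peak. Empty input yields ``(None, 0)``.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if not distances:
        return None, 0
    count = sum(1 for x in distances if x < d)
    return count / len(distances), count
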