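"""Peak-landscape annotation and spacing statistics.

Reproduces the descriptive genomics around a peak set: per-peak feature
flags (CpG island, promoter, enhancer, CTCF co-binding, GC > 60%), signed
distance to the nearest TSS, exclusive category pies, pairwise set-overlap
(Venn) fractions, a shuffle-based null for peak spacing, and +/- 500 bp
signal windows around peak midpoints.

Feature overlap uses the standard >= 1 bp rule (configurable to a
midpoint-in-feature rule); reciprocal-overlap requirements are reserved
for loop matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval, Peak, fraction_within, nearest_neighbor_distances
from .io import gc_fraction

__all__ = [
    "TSS",
    "AnnotationTracks",
    "PeakAnnotation",
    "annotate_peaks",
    "exclusive_categories",
    "set_overlap_fraction",
    "spacing_null",
    "window_signal",
]


@dataclass(frozen=True)
class TSS:
    """A transcription start site as a point with gene orientation."""

    chrom: str
    position: int
    gene: str = ""
    strand: str = "+"


@dataclass
class AnnotationTracks:
    """The reference tracks a peak set is annotated against."""

    cpg_islands: list[GenomicInterval] = field(default_factory=list)
    tss: list[TSS] = field(default_factory=list)
    enhancers: list[GenomicInterval] = field(default_factory=list)
    ctcf_peaks: list[Peak] = field(default_factory=list)
    genome: Optional[object] = None  # pyfaidx.Fasta or mapping chrom -> seq


@dataclass
class PeakAnnotation:
    """Per-peak feature flags and TSS distance."""

    peak: Peak
    gc_over_60: Optional[bool]
    in_cpg: bool
    in_promoter: bool
    in_enhancer: bool
    at_ctcf: bool
    tss_distance: Optional[int]


def _tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _hits(trees: Mapping[str, IntervalTree], iv: GenomicInterval, rule: str) -> bool:
    t = trees.get(iv.chrom)
    if t is None:
        return False
    if rule == "any_bp":
        return bool(t.overlap(iv.start, iv.end))
    if rule == "midpoint":
        return bool(t.at(iv.midpoint))
    raise ValueError(f"unknown overlap rule {rule!r}")


def promoter_intervals(
    tss: Sequence[TSS], window: tuple[int, int] = (-1000, 100)
) -> list[GenomicInterval]:
    """Strand-aware promoter windows around TSS points.

    ``window`` is (upstream, downstream) in gene orientation; the default
    -1000/+100 bp follows the Homer "promoter-TSS" convention.
    """
    up, down = window
    out = []
    for t in tss:
        if t.strand == "+":
            lo, hi = t.position + up, t.position + down
        else:
            lo, hi = t.position - down, t.position - up
        lo = max(0, lo)
        if hi > lo:
            out.append(GenomicInterval(t.chrom, lo, hi))
    return out


def annotate_peaks(
    peaks: Sequence[Peak],
    tracks: AnnotationTracks,
    promoter_window: tuple[int, int] = (-1000, 100),
    gc_threshold: float = 0.60,
    overlap_rule: str = "any_bp",
) -> tuple[list[PeakAnnotation], dict[str, Optional[float]]]:
    """Flag every peak against the annotation tracks.

    A feature flag is true iff the peak overlaps >= 1 bp of a feature
    interval (or, under ``overlap_rule="midpoint"``, its midpoint falls
    inside one). GC is computed from the genome sequence under the peak
    and classified against ``gc_threshold`` (default: GC > 60%). The
    signed TSS distance is peak midpoint minus TSS in gene orientation,
    negative upstream of the TSS.

    Returns the per-peak annotations and a summary of non-exclusive
    fractions (the share of peaks with each flag set); fractions are None
    when undefined (no genome for GC, empty input).
    """
    cpg_t = _tree(tracks.cpg_islands)
    enh_t = _tree(tracks.enhancers)
    prom_t = _tree(promoter_intervals(tracks.tss, promoter_window))
    ctcf_t = _tree(p.interval for p in tracks.ctcf_peaks)

    tss_by_chrom: dict[str, list[TSS]] = {}
    for t in tracks.tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    for group in tss_by_chrom.values():
        group.sort(key=lambda t: t.position)

    annotations: list[PeakAnnotation] = []
    for p in peaks:
        iv = p.interval
        gc: Optional[bool] = None
        if tracks.genome is not None:
            frac = gc_fraction(iv, tracks.genome)
            gc = None if frac is None else frac > gc_threshold
        tdist: Optional[int] = None
        group = tss_by_chrom.get(iv.chrom)
        if group:
            mid = iv.midpoint
            best = min(group, key=lambda t: abs(mid - t.position))
            raw = mid - best.position
            tdist = raw if best.strand == "+" else -raw
        annotations.append(
            PeakAnnotation(
                peak=p,
                gc_over_60=gc,
                in_cpg=_hits(cpg_t, iv, overlap_rule),
                in_promoter=_hits(prom_t, iv, overlap_rule),
                in_enhancer=_hits(enh_t, iv, overlap_rule),
                at_ctcf=_hits(ctcf_t, iv, overlap_rule),
                tss_distance=tdist,
            )
        )

    def _frac(flag: str) -> Optional[float]:
        vals = [getattr(a, flag) for a in annotations]
        vals = [v for v in vals if v is not None]
        if not vals:
            return None
        return sum(vals) / len(vals)

    summary = {
        "gc_over_60": _frac("gc_over_60"),
        "in_cpg": _frac("in_cpg"),
        "in_promoter": _frac("in_promoter"),
        "in_enhancer": _frac("in_enhancer"),
        "at_ctcf": _frac("at_ctcf"),
    }
    return annotations, summary


def exclusive_categories(
    annotations: Sequence[PeakAnnotation],
) -> dict[str, float]:
    """Partition peaks into promoter-only / enhancer-only / both / other.

    The four fractions sum to 1. Typically applied to the CpG-island
    subset of a peak set (pie-chart style breakdowns).
    """
    if not annotations:
        raise ValueError("exclusive_categories needs a nonempty input")
    counts = {"promoter_only": 0, "enhancer_only": 0, "promoter_and_enhancer": 0, "other": 0}
    for a in annotations:
        if a.in_promoter and a.in_enhancer:
            counts["promoter_and_enhancer"] += 1
        elif a.in_promoter:
            counts["promoter_only"] += 1
        elif a.in_enhancer:
            counts["enhancer_only"] += 1
        else:
            counts["other"] += 1
    n = len(annotations)
    return {k: v / n for k, v in counts.items()}


def set_overlap_fraction(
    set_a: Sequence[Peak], set_b: Sequence[Peak]
) -> tuple[Optional[float], Optional[float]]:
    """Venn-style overlap between two peak sets.

    Returns ``(fraction of A overlapping >= 1 peak of B, fraction of B
    overlapping >= 1 peak of A)`` under the >= 1 bp rule; a fraction is
    None when its set is empty.
    """
    trees_b = _tree(p.interval for p in set_b)
    trees_a = _tree(p.interval for p in set_a)

    def _frac(src: Sequence[Peak], trees) -> Optional[float]:
        if not src:
            return None
        hit = sum(1 for p in src if _hits(trees, p.interval, "any_bp"))
        return hit / len(src)

    return _frac(set_a, trees_b), _frac(set_b, trees_a)


@dataclass
class SpacingNullResult:
    observed_fraction: float
    observed_count: int
    null_fractions: np.ndarray
    pvalue: float


def spacing_null(
    peaks: Sequence[Peak],
    chrom_sizes: Mapping[str, int],
    d: int = 2000,
    n_shuffles: int = 100,
    seed: int = 0,
    convention: str = "midpoint",
) -> SpacingNullResult:
    """Compare peak spacing against a uniform-placement null.

    The observed statistic is the fraction of peaks whose nearest
    same-chromosome neighbor lies within < ``d`` bp. Each shuffle places
    the same number of peaks per chromosome, preserving peak lengths,
    uniformly at random (no overlap constraint). The empirical p-value is
    the add-one upper-tail estimate
    ``(1 + #{null >= observed}) / (n_shuffles + 1)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    for p in peaks:
        size = chrom_sizes.get(p.interval.chrom)
        if size is None:
            raise ValueError(f"no size for chromosome {p.interval.chrom}")
        if p.interval.length > size:
            raise ValueError(
                f"peak {p.interval} longer than its chromosome ({size} bp)"
            )

    dists, _ = nearest_neighbor_distances(peaks, convention)
    obs_frac, obs_count = fraction_within(dists, d) if dists else (0.0, 0)
    obs_frac = 0.0 if obs_frac is None else obs_frac

    lengths_by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        lengths_by_chrom.setdefault(p.interval.chrom, []).append(p.interval.length)

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled: list[Peak] = []
        for chrom, lengths in lengths_by_chrom.items():
            size = chrom_sizes[chrom]
            for L in lengths:
                start = int(rng.integers(0, size - L + 1))
                shuffled.append(Peak(GenomicInterval(chrom, start, start + L)))
        nd, _ = nearest_neighbor_distances(shuffled, convention)
        f, _ = fraction_within(nd, d) if nd else (0.0, 0)
        null[i] = 0.0 if f is None else f

    pvalue = (1 + int(np.sum(null >= obs_frac))) / (n_shuffles + 1)
    return SpacingNullResult(obs_frac, obs_count, null, pvalue)


def window_signal(
    peaks: Sequence[Peak],
    reads: Sequence[GenomicInterval],
    half_window: int = 500,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Read-midpoint coverage in a window around each peak midpoint.

    Returns an ``(n_peaks, 2*half_window + 1)`` matrix of read-midpoint
    counts per position (column ``half_window`` is the peak midpoint) and
    the columnwise mean profile. Window positions that fall off the
    chromosome (below 0, or past the size when ``chrom_sizes`` is given)
    are NaN and excluded from the mean.
    """
    width = 2 * half_window + 1
    mat = np.zeros((len(peaks), width))

    read_mids: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for r in reads:
        tmp.setdefault(r.chrom, []).append(r.midpoint)
    for chrom, mids in tmp.items():
        read_mids[chrom] = np.sort(np.asarray(mids))

    for i, p in enumerate(peaks):
        mid = p.interval.midpoint
        lo = mid - half_window
        hi = mid + half_window
        mids = read_mids.get(p.interval.chrom)
        if mids is not None and mids.size:
            sel = mids[(mids >= lo) & (mids <= hi)]
            if sel.size:
                np.add.at(mat[i], sel - lo, 1)
        if lo < 0:
            mat[i, : -lo] = np.nan
        if chrom_sizes is not None:
            size = chrom_sizes.get(p.interval.chrom)
            if size is not None and hi >= size:
                mat[i, width - (hi - size + 1) :] = np.nan

    if len(peaks):
        import warnings

        with warnings.catch_warnings():
            # all-NaN columns (fully truncated positions) mean "no data"
            warnings.simplefilter("ignore", category=RuntimeWarning)
            profile = np.nanmean(mat, axis=0)
    else:
        profile = np.zeros(width)
    return mat, profile
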