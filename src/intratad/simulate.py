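"""Synthetic data with planted ground truth.

Generates inputs carrying exactly the statistical structure the analysis
assumes — convergently oriented CTCF motifs co-bound by cohesin at loop
anchors, score balance obeying the pairing rule, GC-heterogeneous
sequence with CpG-island-like segments, decoy peaks, spike-in read
counts, and a "patient" perturbation that moves cohesin score mass away
from CTCF anchors — so every pipeline stage can be tested against known
truth without downloads.

All generators are deterministic given their seed. Planted loops are
separated by more than the caller's span cap so that cross-loop
convergent pairs are excluded by construction and a noise-free run must
recover every planted loop exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .caller import CallerParams
from .intervals import GenomicInterval, MotifHit, Peak
from .io import LoopRecord

__all__ = [
    "PlantedLoop",
    "SyntheticTruth",
    "make_genome",
    "plant_loops",
    "add_noise",
    "make_patient",
    "make_hic_reference",
    "make_spike_counts",
    "score_recovery",
    "write_truth",
]

DEFAULT_CHROM_SIZES = {"chr1": 150_000_000, "chr2": 150_000_000}

_MOTIF_WIDTH = 19  # CTCF MA0139.1 core motif width
_ANCHOR_WIDTH = 400
_CTCF_PEAK_PAD = 50
_READ_LEN = 50


@dataclass
class PlantedLoop:
    loop_id: str
    span: GenomicInterval
    fwd_anchor: GenomicInterval
    rev_anchor: GenomicInterval
    fwd_score: float
    rev_score: float


@dataclass
class SyntheticTruth:
    """Planted inputs plus full ground truth for recovery tests."""

    chrom_sizes: dict[str, int]
    planted_loops: list[PlantedLoop]
    cohesin_peaks: list[Peak]
    ctcf_peaks: list[Peak]
    motifs: list[MotifHit]
    nipbl_peaks: list[Peak] = field(default_factory=list)
    noise_peaks: list[Peak] = field(default_factory=list)
    cpg_segments: list[GenomicInterval] = field(default_factory=list)
    genome: Optional[dict[str, str]] = None
    params: dict = field(default_factory=dict)
    seed: int = 0
    # perturbation bookkeeping: loop_id -> reason it is no longer callable
    destroyed_loops: dict[str, str] = field(default_factory=dict)

    def intact_loops(self) -> list[PlantedLoop]:
        """Planted loops whose anchor signature survived all perturbations."""
        return [l for l in self.planted_loops if l.loop_id not in self.destroyed_loops]


def make_genome(
    chrom_sizes: Mapping[str, int],
    base_gc: float = 0.40,
    island_gc: float = 0.75,
    island_density: float = 10.0,
    island_length_range: tuple[int, int] = (500, 2000),
    seed: int = 0,
    max_retries_per_island: int = 100,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Generate i.i.d. sequence with embedded CpG-island-like segments.

    Bases are drawn independently with GC probability ``base_gc`` outside
    islands and ``island_gc`` inside. ``island_density`` is islands per
    Mb (default 10, roughly the human genome's CpG-island density);
    island positions are uniform without overlap (re-drawn up to a retry
    cap), lengths uniform in ``island_length_range``.

    Returns the sequences (chrom -> string) and the island intervals.
    """
    if not (0 < base_gc < island_gc < 1):
        raise ValueError("require 0 < base_gc < island_gc < 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    islands: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        p_bg = [(1 - base_gc) / 2, base_gc / 2, base_gc / 2, (1 - base_gc) / 2]
        seq = rng.choice(4, size=size, p=p_bg)
        n_islands = int(round(island_density * size / 1e6))
        placed: list[tuple[int, int]] = []
        for _ in range(n_islands):
            ok = False
            for _try in range(max_retries_per_island):
                L = int(rng.integers(island_length_range[0], island_length_range[1] + 1))
                if L >= size:
                    continue
                s = int(rng.integers(0, size - L + 1))
                if all(s + L <= a or s >= b for a, b in placed):
                    placed.append((s, s + L))
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"could not place {n_islands} non-overlapping islands on "
                    f"{chrom} ({size} bp) within the retry cap"
                )
        p_is = [(1 - island_gc) / 2, island_gc / 2, island_gc / 2, (1 - island_gc) / 2]
        for s, e in sorted(placed):
            seq[s:e] = rng.choice(4, size=e - s, p=p_is)
            islands.append(GenomicInterval(chrom, s, e))
        sequences[chrom] = "".join(bases[seq])
    return sequences, islands


def plant_loops(
    n_loops: int,
    span_range: tuple[int, int] = (150_000, 400_000),
    anchor_score_range: tuple[float, float] = (100.0, 1000.0),
    chrom_sizes: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    caller_params: Optional[CallerParams] = None,
    min_balance: float = 0.7,
    n_nipbl_per_loop: float = 1.0,
) -> SyntheticTruth:
    """Plant convergent-anchor loops with full cohesin/CTCF/motif support.

    Each loop contributes a forward-motif anchor at its start and a
    reverse-motif anchor at its end: a cohesin peak, a slightly wider
    CTCF peak, and a centered CTCF motif with the planted strand. Anchor
    scores are drawn from ``anchor_score_range`` with the weaker anchor
    of each pair at least ``min_balance`` of the stronger, so every
    planted loop passes the caller's minimum-proportion rule with margin
    (``min_balance`` must be >= the rule's threshold or the configuration
    is rejected). Loops are packed left to right with inter-loop gaps
    exceeding the caller's span cap, which excludes cross-loop pairs.

    NIPBL-like peaks (one per loop by default) are scattered at random
    positions as a cohesin-loader track for the patient perturbation.
    """
    params = caller_params or CallerParams()
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    if min_balance < params.min_proportion:
        raise ValueError(
            f"min_balance {min_balance} below the caller's minimum proportion "
            f"{params.min_proportion}: planted loops would not all be callable"
        )
    if span_range[0] < 3 * _ANCHOR_WIDTH:
        raise ValueError("span_range too small for anchor geometry")
    rng = np.random.default_rng(seed)

    gap = params.max_span + 10_000
    chroms = sorted(chrom_sizes)
    cursors = {c: 50_000 for c in chroms}

    loops: list[PlantedLoop] = []
    cohesin: list[Peak] = []
    ctcf: list[Peak] = []
    motifs: list[MotifHit] = []

    def _anchor(chrom: str, start: int, strand: str, anchor_score: float, name: str):
        iv = GenomicInterval(chrom, start, start + _ANCHOR_WIDTH)
        motif_score = float(rng.uniform(15.0, 25.0))
        cohesin_score = anchor_score**2 / motif_score
        cohesin.append(Peak(iv, score=cohesin_score, fold_change=10.0, name=name))
        ctcf_iv = GenomicInterval(
            chrom, max(0, start - _CTCF_PEAK_PAD), start + _ANCHOR_WIDTH + _CTCF_PEAK_PAD
        )
        ctcf.append(Peak(ctcf_iv, score=anchor_score, name=name + "_ctcf"))
        m_start = iv.midpoint - _MOTIF_WIDTH // 2
        motifs.append(
            MotifHit(
                GenomicInterval(chrom, m_start, m_start + _MOTIF_WIDTH, strand),
                motif_id="MA0139.1",
                score=motif_score,
                pvalue=1e-6,
            )
        )

    ci = 0
    for k in range(n_loops):
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            if cursors[chrom] + span <= chrom_sizes[chrom] - 50_000:
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"infeasible packing: loop {k} of span {span} does not fit "
                "on any chromosome with the required separation"
            )
        start = cursors[chrom]
        cursors[chrom] = start + span + gap

        s_strong = float(rng.uniform(*anchor_score_range))
        s_weak = s_strong * float(rng.uniform(min_balance, 1.0))
        if rng.random() < 0.5:
            s_fwd, s_rev = s_strong, s_weak
        else:
            s_fwd, s_rev = s_weak, s_strong

        loop_id = f"planted_{k:04d}"
        fwd = GenomicInterval(chrom, start, start + _ANCHOR_WIDTH)
        rev_start = start + span - _ANCHOR_WIDTH
        rev = GenomicInterval(chrom, rev_start, rev_start + _ANCHOR_WIDTH)
        _anchor(chrom, start, "+", s_fwd, loop_id + "_f")
        _anchor(chrom, rev_start, "-", s_rev, loop_id + "_r")
        loops.append(
            PlantedLoop(
                loop_id=loop_id,
                span=GenomicInterval(chrom, fwd.start, rev.end),
                fwd_anchor=fwd,
                rev_anchor=rev,
                fwd_score=s_fwd,
                rev_score=s_rev,
            )
        )

    nipbl: list[Peak] = []
    n_nipbl = int(round(n_nipbl_per_loop * n_loops))
    for j in range(n_nipbl):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, chrom_sizes[chrom] - _ANCHOR_WIDTH))
        nipbl.append(
            Peak(
                GenomicInterval(chrom, s, s + _ANCHOR_WIDTH),
                score=float(rng.uniform(50, 500)),
                fold_change=float(rng.uniform(5.5, 12.0)),
                name=f"nipbl_{j:04d}",
            )
        )

    return SyntheticTruth(
        chrom_sizes=chrom_sizes,
        planted_loops=loops,
        cohesin_peaks=cohesin,
        ctcf_peaks=ctcf,
        motifs=motifs,
        nipbl_peaks=nipbl,
        params={
            "n_loops": n_loops,
            "span_range": span_range,
            "anchor_score_range": anchor_score_range,
            "min_balance": min_balance,
            "caller_params": params,
        },
        seed=seed,
    )


def add_noise(
    truth: SyntheticTruth,
    decoy_peak_density: float = 0.2,
    score_jitter_sd: float = 0.1,
    orientation_flip_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticTruth:
    """Perturb a planted truth with decoys, score jitter, and strand flips.

    * Decoy cohesin-only and CTCF-only peaks (each ``decoy_peak_density``
      per planted peak of its kind) are inserted uniformly; CTCF decoys
      carry a random-strand motif. Neither kind is co-bound, so decoys do
      not create anchors on their own.
    * Multiplicative log-normal jitter (sigma ``score_jitter_sd``) on
      every cohesin peak and motif score.
    * An exact fraction ``orientation_flip_rate`` of all motif rows has
      its strand flipped (rows sampled without replacement).

    Every perturbation is recorded; planted loops whose anchors are no
    longer convergent, or whose post-jitter score balance falls below the
    caller's minimum proportion, are listed in ``destroyed_loops``.
    """
    for name, v in (
        ("decoy_peak_density", decoy_peak_density),
        ("orientation_flip_rate", orientation_flip_rate),
    ):
        if not (0 <= v < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    if score_jitter_sd < 0:
        raise ValueError("score_jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    params: CallerParams = truth.params.get("caller_params", CallerParams())
    chroms = sorted(truth.chrom_sizes)

    cohesin = [replace(p) for p in truth.cohesin_peaks]
    ctcf = [replace(p) for p in truth.ctcf_peaks]
    motifs = [replace(m) for m in truth.motifs]
    n_planted_motifs = len(motifs)
    noise_peaks: list[Peak] = []

    # decoy peaks
    n_dec_coh = int(round(decoy_peak_density * len(cohesin)))
    n_dec_ctcf = int(round(decoy_peak_density * len(ctcf)))
    for j in range(n_dec_coh):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, truth.chrom_sizes[chrom] - _ANCHOR_WIDTH))
        p = Peak(
            GenomicInterval(chrom, s, s + _ANCHOR_WIDTH),
            score=float(rng.uniform(50, 500)),
            name=f"decoy_cohesin_{j:04d}",
        )
        cohesin.append(p)
        noise_peaks.append(p)
    for j in range(n_dec_ctcf):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, truth.chrom_sizes[chrom] - _ANCHOR_WIDTH))
        p = Peak(
            GenomicInterval(chrom, s, s + _ANCHOR_WIDTH),
            score=float(rng.uniform(50, 500)),
            name=f"decoy_ctcf_{j:04d}",
        )
        ctcf.append(p)
        noise_peaks.append(p)
        strand = "+" if rng.random() < 0.5 else "-"
        m_start = p.interval.midpoint - _MOTIF_WIDTH // 2
        motifs.append(
            MotifHit(
                GenomicInterval(chrom, m_start, m_start + _MOTIF_WIDTH, strand),
                motif_id="MA0139.1",
                score=float(rng.uniform(15.0, 25.0)),
                pvalue=1e-6,
            )
        )

    # score jitter (log-normal, keeps scores positive)
    if score_jitter_sd > 0:
        for p in cohesin:
            p.score *= float(rng.lognormal(0.0, score_jitter_sd))
        for m in motifs:
            m.score *= float(rng.lognormal(0.0, score_jitter_sd))

    # exact-fraction strand flips across all motif rows
    n_flip = int(round(orientation_flip_rate * len(motifs)))
    flipped = set()
    if n_flip:
        flipped = set(rng.choice(len(motifs), size=n_flip, replace=False).tolist())
        for idx in flipped:
            m = motifs[idx]
            new_strand = "-" if m.interval.strand == "+" else "+"
            motifs[idx] = replace(
                m,
                interval=GenomicInterval(
                    m.interval.chrom, m.interval.start, m.interval.end, new_strand
                ),
            )

    # bookkeeping: which planted loops lost their callable signature
    destroyed = dict(truth.destroyed_loops)
    for k, loop in enumerate(truth.planted_loops):
        fwd_idx, rev_idx = 2 * k, 2 * k + 1
        if fwd_idx in flipped or rev_idx in flipped:
            destroyed.setdefault(loop.loop_id, "motif strand flipped")
            continue
        a_f = math.sqrt(cohesin[fwd_idx].score * motifs[fwd_idx].score)
        a_r = math.sqrt(cohesin[rev_idx].score * motifs[rev_idx].score)
        if min(a_f, a_r) < params.min_proportion * max(a_f, a_r):
            destroyed.setdefault(loop.loop_id, "score balance broken by jitter")

    out = replace(
        truth,
        cohesin_peaks=cohesin,
        ctcf_peaks=ctcf,
        motifs=motifs,
        noise_peaks=truth.noise_peaks + noise_peaks,
        destroyed_loops=destroyed,
    )
    out.params = dict(truth.params)
    out.params["noise"] = {
        "decoy_peak_density": decoy_peak_density,
        "score_jitter_sd": score_jitter_sd,
        "orientation_flip_rate": orientation_flip_rate,
        "n_flipped": n_flip,
        "flipped_planted": sorted(i for i in flipped if i < n_planted_motifs),
        "seed": seed,
    }
    return out


def make_patient(
    truth: SyntheticTruth,
    nipbl_loss_fraction: float = 0.5,
    redistribution_fraction: float = 0.3,
    seed: int = 0,
) -> SyntheticTruth:
    """Derive a "patient" condition by redistributing cohesin occupancy.

    Emulates reduced cohesin-loader function: a fraction of NIPBL-like
    peaks disappears, and a fraction of planted anchors loses its cohesin
    peak, whose score mass reappears as a cohesin-only peak at a
    CpG-island-like position (or a random position when no islands are
    available). Loops losing either anchor are recorded as destroyed.

    The affected-anchor set is the prefix of a seed-derived permutation,
    so at a fixed seed the sets for increasing ``redistribution_fraction``
    are nested and the number of destroyed loops is non-decreasing.
    """
    for name, v in (
        ("nipbl_loss_fraction", nipbl_loss_fraction),
        ("redistribution_fraction", redistribution_fraction),
    ):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = sorted(truth.chrom_sizes)

    n_anchors = 2 * len(truth.planted_loops)
    perm = rng.permutation(n_anchors)
    k = int(round(redistribution_fraction * n_anchors))
    affected = set(perm[:k].tolist())

    cohesin: list[Peak] = []
    relocated: list[Peak] = []
    destroyed = dict(truth.destroyed_loops)
    for idx, p in enumerate(truth.cohesin_peaks):
        if idx < n_anchors and idx in affected:
            loop = truth.planted_loops[idx // 2]
            destroyed.setdefault(loop.loop_id, "cohesin redistributed off anchor")
            if truth.cpg_segments:
                target = truth.cpg_segments[int(rng.integers(len(truth.cpg_segments)))]
                s = target.start
                chrom = target.chrom
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(0, truth.chrom_sizes[chrom] - _ANCHOR_WIDTH))
            moved = Peak(
                GenomicInterval(chrom, s, s + max(_ANCHOR_WIDTH, 1)),
                score=p.score,
                name=p.name + "_relocated",
            )
            relocated.append(moved)
        else:
            cohesin.append(replace(p))
    cohesin.extend(relocated)

    n_nipbl_lost = int(round(nipbl_loss_fraction * len(truth.nipbl_peaks)))
    keep_nipbl = list(truth.nipbl_peaks)
    if n_nipbl_lost:
        drop = set(
            rng.choice(len(keep_nipbl), size=n_nipbl_lost, replace=False).tolist()
        )
        keep_nipbl = [p for i, p in enumerate(keep_nipbl) if i not in drop]

    out = replace(
        truth,
        cohesin_peaks=cohesin,
        nipbl_peaks=keep_nipbl,
        destroyed_loops=destroyed,
    )
    out.params = dict(truth.params)
    out.params["patient"] = {
        "nipbl_loss_fraction": nipbl_loss_fraction,
        "redistribution_fraction": redistribution_fraction,
        "n_anchors_affected": k,
        "seed": seed,
    }
    return out


def make_hic_reference(
    truth: SyntheticTruth,
    boundary_jitter_frac: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
    anchor_width: int = 10_000,
) -> list[LoopRecord]:
    """Emit the planted loops as an experimental-style Hi-C loop list.

    Boundaries are jittered by a Gaussian with sd ``boundary_jitter_frac``
    x loop span (rounded); an exact fraction ``fn_rate`` of planted loops
    is dropped and ``fp_rate`` x n spurious loops are added at random
    positions. Anchors are ``anchor_width`` intervals at the span ends.
    """
    for name, v in (
        ("boundary_jitter_frac", boundary_jitter_frac),
        ("fp_rate", fp_rate),
        ("fn_rate", fn_rate),
    ):
        if not (0 <= v < 1):
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(truth.planted_loops)
    drop = set()
    n_fn = int(round(fn_rate * n))
    if n_fn:
        drop = set(rng.choice(n, size=n_fn, replace=False).tolist())

    loops: list[LoopRecord] = []
    for i, pl in enumerate(truth.planted_loops):
        if i in drop:
            continue
        span = pl.span
        w = min(anchor_width, span.length // 4)
        w = max(w, 1)
        s, e = span.start, span.end
        if boundary_jitter_frac > 0:
            sd = boundary_jitter_frac * span.length
            s = s + int(round(rng.normal(0, sd)))
            e = e + int(round(rng.normal(0, sd)))
            s = max(0, s)
            e = min(truth.chrom_sizes[span.chrom], e)
            if e - s < 2 * w + 1:
                e = s + 2 * w + 1
        loops.append(
            LoopRecord(
                anchor1=GenomicInterval(span.chrom, s, s + w),
                anchor2=GenomicInterval(span.chrom, e - w, e),
                source_id=f"hic_{pl.loop_id}",
            )
        )

    chroms = sorted(truth.chrom_sizes)
    n_fp = int(round(fp_rate * n))
    span_range = truth.params.get("span_range", (150_000, 400_000))
    for j in range(n_fp):
        chrom = chroms[int(rng.integers(len(chroms)))]
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        s = int(rng.integers(0, truth.chrom_sizes[chrom] - span))
        w = min(anchor_width, span // 4)
        loops.append(
            LoopRecord(
                anchor1=GenomicInterval(chrom, s, s + w),
                anchor2=GenomicInterval(chrom, s + span - w, s + span),
                source_id=f"hic_fp_{j:04d}",
            )
        )
    return loops


def make_spike_counts(
    n_samples: int = 3,
    depth_range: tuple[int, int] = (80_000, 120_000),
    spike_fraction: float = 0.05,
    seed: int = 0,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    make_reads: bool = False,
):
    """Simulate spike-in calibrated sample depths (and optional read BEDs).

    Each sample's total depth is uniform in ``depth_range``; its spike
    read count is Binomial(depth, spike_fraction) — the same spike
    proportion across samples, as a spike-in protocol guarantees — and
    host reads are the remainder. With ``make_reads`` the host reads are
    materialized as positional records on the given chromosomes.

    Returns ``(samples, reads_by_sample)``; the reads mapping is empty
    unless requested.
    """
    from .calibration import SpikeSample

    if not (0 < spike_fraction < 1):
        raise ValueError("spike_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    chroms = sorted(chrom_sizes)
    samples = []
    reads: dict[str, list[GenomicInterval]] = {}
    for i in range(n_samples):
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        spike = int(rng.binomial(depth, spike_fraction))
        spike = min(max(spike, 1), depth - 1)
        host = depth - spike
        sid = f"sample_{i}"
        samples.append(
            SpikeSample(sample_id=sid, host_reads=host, spike_reads=spike)
        )
        if make_reads:
            ch_idx = rng.integers(0, len(chroms), size=host)
            lst = []
            for c in range(len(chroms)):
                nsel = int(np.sum(ch_idx == c))
                if not nsel:
                    continue
                starts = rng.integers(
                    0, chrom_sizes[chroms[c]] - _READ_LEN, size=nsel
                )
                lst.extend(
                    GenomicInterval(chroms[c], int(s), int(s) + _READ_LEN)
                    for s in starts
                )
            reads[sid] = lst
    return samples, reads


def score_recovery(
    called_tads: Sequence,
    truth: SyntheticTruth,
    complete_threshold: float = 0.95,
    require_intact: bool = True,
) -> dict:
    """Recall/precision of a called loop set against the planted truth.

    A planted loop is recovered when some called loop completely matches
    its span (both reciprocal fractions >= ``complete_threshold``); a
    called loop is a true positive when it completely matches some
    planted loop. Recall's denominator is the set of planted loops whose
    anchor signature survived the recorded perturbations
    (``require_intact=True``, default) — a loop whose motif was flipped
    or whose anchor lost cohesin carries no callable signal, so it
    measures the noise process, not the caller. ``recall_all_planted``
    reports the all-planted-loops denominator alongside.
    """
    from .intervals import reciprocal_overlap

    targets = truth.intact_loops() if require_intact else truth.planted_loops
    all_planted = truth.planted_loops

    def _complete(a: GenomicInterval, b: GenomicInterval) -> bool:
        fa, fb = reciprocal_overlap(a, b)
        return fa >= complete_threshold and fb >= complete_threshold

    called_spans = [t.span for t in called_tads]
    recovered = sum(
        1 for pl in targets if any(_complete(pl.span, s) for s in called_spans)
    )
    recovered_all = sum(
        1 for pl in all_planted if any(_complete(pl.span, s) for s in called_spans)
    )
    tp = sum(
        1 for s in called_spans if any(_complete(pl.span, s) for pl in all_planted)
    )
    return {
        "n_planted": len(all_planted),
        "n_intact": len(targets),
        "n_called": len(called_spans),
        "recall": recovered / len(targets) if targets else None,
        "recall_all_planted": (
            recovered_all / len(all_planted) if all_planted else None
        ),
        "precision": tp / len(called_spans) if called_spans else None,
    }


def write_truth(truth: SyntheticTruth, outdir) -> dict[str, Path]:
    """Write a truth's inputs as standard files accepted by the readers."""
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohesin": outdir / "cohesin.narrowPeak",
        "ctcf": outdir / "ctcf.narrowPeak",
        "motifs": outdir / "motifs.tsv",
        "loops": outdir / "planted_loops.bedpe",
        "chrom_sizes": outdir / "chrom.sizes",
        "truth_table": outdir / "truth.tsv",
    }
    tio.write_narrowpeak(truth.cohesin_peaks, paths["cohesin"])
    tio.write_narrowpeak(truth.ctcf_peaks, paths["ctcf"])
    tio.write_fimo_tsv(truth.motifs, paths["motifs"])
    tio.write_loops_bedpe(
        [
            LoopRecord(pl.fwd_anchor, pl.rev_anchor, pl.loop_id)
            for pl in truth.planted_loops
        ],
        paths["loops"],
    )
    with open(paths["chrom_sizes"], "w") as fh:
        for c in sorted(truth.chrom_sizes):
            fh.write(f"{c}\t{truth.chrom_sizes[c]}\n")
    with open(paths["truth_table"], "w") as fh:
        fh.write("loop_id\tchrom\tstart\tend\tfwd_score\trev_score\tstatus\n")
        for pl in truth.planted_loops:
            status = truth.destroyed_loops.get(pl.loop_id, "intact")
            fh.write(
                f"{pl.loop_id}\t{pl.span.chrom}\t{pl.span.start}\t{pl.span.end}"
                f"\t{pl.fwd_score:g}\t{pl.rev_score:g}\t{status}\n"
            )
    if truth.nipbl_peaks:
        paths["nipbl"] = outdir / "nipbl.narrowPeak"
        tio.write_narrowpeak(truth.nipbl_peaks, paths["nipbl"])
    if truth.genome is not None:
        paths["genome"] = outdir / "genome.fa"
        with open(paths["genome"], "w") as fh:
            for c in sorted(truth.genome):
                fh.write(f">{c}\n")
                seq = truth.genome[c]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    return paths
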