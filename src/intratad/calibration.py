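"""Spike-in calibrated normalization and peak filtering.

A fixed proportion of foreign-genome (e.g. mouse mm10) chromatin is added
to every ChIP sample before immunoprecipitation; because that proportion
is constant, differences in spike-genome read yield measure technical
depth differences. Samples are equalized by downsampling every sample to
the smallest spike-genome read count, after which host-genome signal is
quantitatively comparable across samples.

Also implements the peak-level table filters applied downstream of peak
calling: the LFC > 5 filter for dubious peaks and the -log10 adjusted
p > 2 filter on differential-enrichment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .intervals import Peak

__all__ = [
    "SpikeSample",
    "spike_scale_factors",
    "downsample_reads",
    "downsample_counts",
    "filter_peaks_lfc",
    "filter_differential_significance",
]


@dataclass
class SpikeSample:
    """Per-sample unique read counts in host and spike genomes."""

    sample_id: str
    host_reads: int
    spike_reads: int
    downsample_factor: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.host_reads <= 0:
            raise ValueError(f"{self.sample_id}: host_reads must be positive")
        if self.spike_reads < 0:
            raise ValueError(f"{self.sample_id}: spike_reads must be >= 0")


def spike_scale_factors(samples: Sequence[SpikeSample]) -> list[SpikeSample]:
    """Set each sample's downsample factor from its spike-in read count.

    The target is the minimum spike count across samples; sample *i*
    receives factor ``target / spike_reads_i``, so the shallowest-spike
    sample has factor exactly 1 and all others are thinned down to match
    its spike coverage.
    """
    if len(samples) < 2:
        raise ValueError("calibration needs at least 2 samples")
    for s in samples:
        if s.spike_reads == 0:
            raise ValueError(
                f"{s.sample_id}: zero spike-in reads, calibration impossible"
            )
    target = min(s.spike_reads for s in samples)
    return [
        replace(s, downsample_factor=target / s.spike_reads) for s in samples
    ]


def downsample_reads(
    reads: Sequence,
    factor: float,
    seed: int,
    exact: bool = False,
) -> list:
    """Thin a read list, keeping each read with probability ``factor``.

    Parameters
    ----------
    reads : sequence
        Read records (any objects); order of kept reads is preserved.
    factor : float in (0, 1]
        Retention probability. 1.0 returns the input unchanged.
    exact : bool
        When True, keep exactly ``round(factor * n)`` reads drawn without
        replacement (hypergeometric-style thinning) instead of independent
        Bernoulli draws; useful for small deterministic tests.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"downsample factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    n = len(reads)
    if exact:
        k = int(round(factor * n))
        keep = np.zeros(n, dtype=bool)
        keep[rng.choice(n, size=k, replace=False)] = True
    else:
        keep = rng.random(n) < factor
    return [r for r, k in zip(reads, keep) if k]


def downsample_counts(
    counts: Union[Sequence[int], np.ndarray], factor: float, seed: int
) -> np.ndarray:
    """Binomially thin a vector of per-bin read counts."""
    if not (0 < factor <= 1):
        raise ValueError(f"downsample factor must be in (0, 1], got {factor}")
    counts = np.asarray(counts, dtype=np.int64)
    if factor == 1.0:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.binomial(counts, factor)


def filter_peaks_lfc(
    peaks: Iterable[Peak], threshold: float = 5.0
) -> list[Peak]:
    """Drop dubious peaks: keep those with fold change strictly > threshold.

    Every peak must carry a ``fold_change``; a missing value is an error
    naming the peak rather than a silent pass-through.
    """
    kept = []
    for p in peaks:
        if p.fold_change is None:
            raise ValueError(
                f"peak {p.name or str(p.interval)} has no fold_change; "
                "cannot apply LFC filter"
            )
        if p.fold_change > threshold:
            kept.append(p)
    return kept


def filter_differential_significance(
    rows: Sequence,
    threshold: float = 2.0,
    p_column: str = "adj_pvalue",
):
    """Keep differential-enrichment rows with -log10(adjusted p) > threshold.

    ``rows`` may be a pandas DataFrame (filtered on ``p_column``) or a
    sequence of mappings. Equivalent to keeping adjusted p < 10**(-threshold),
    with the boundary excluded: adjusted p = 0.01 fails a threshold of 2.
    """
    import pandas as pd

    cutoff = 10.0 ** (-threshold)

    if isinstance(rows, pd.DataFrame):
        p = rows[p_column].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("adjusted p-values must be in (0, 1]")
        return rows[p < cutoff]

    out = []
    for row in rows:
        p = float(row[p_column])
        if not (0 < p <= 1):
            raise ValueError(f"adjusted p-value {p} outside (0, 1]")
        if p < cutoff:
            out.append(row)
    return out
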