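import numpy as np
import pytest

from intratad.caller import CallerParams
from intratad.intervals import GenomicInterval, Peak
from intratad.simulate import plant_loops


@pytest.fixture(scope="session")
def small_truth():
    """A 20-loop planted scenario shared by read-only tests."""
    return plant_loops(n_loops=20, seed=42)


@pytest.fixture
def tiny_fasta(tmp_path):
    """A two-chromosome FASTA with known GC structure."""
    path = tmp_path / "tiny.fa"
    path.write_text(
        ">chr1\n" + "GGCC" * 25 + "ATAT" * 25 + "\n"  # 100 GC-rich + 100 AT
        ">chr2\n" + "GATC" * 50 + "\n"  # 200 bp at 50% GC
    )
    return path


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1", "chr2")):
    """Random desk-scale intervals for brute-force oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, 100_000))
        length = int(rng.integers(1, 5_000))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_peaks(rng: np.random.Generator, n: int, **kw):
    return [Peak(iv, score=float(rng.uniform(1, 100))) for iv in random_intervals(rng, n, **kw)]
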