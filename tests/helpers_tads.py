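"""Shared builders for predicted-loop objects in tests."""

from intratad.caller import Anchor, PredictedTAD
from intratad.intervals import GenomicInterval


def make_simple_tad(
    start: int, end: int, tad_id: str, chrom: str = "chr1",
    score: float = 10.0, anchor_width: int = 400
) -> PredictedTAD:
    up = Anchor(
        interval=GenomicInterval(chrom, start, start + anchor_width),
        orientation="forward",
        cohesin_score=score,
        ctcf_score=score,
        anchor_id=f"{tad_id}_up",
    )
    down = Anchor(
        interval=GenomicInterval(chrom, end - anchor_width, end),
        orientation="reverse",
        cohesin_score=score,
        ctcf_score=score,
        anchor_id=f"{tad_id}_down",
    )
    return PredictedTAD(upstream=up, downstream=down, tad_id=tad_id)
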