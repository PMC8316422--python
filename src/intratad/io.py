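"""Readers and writers for the standard formats the pipeline touches.

Strict dialect handling: structural errors are rejected with the offending
line number rather than silently repaired. Chromosome names are normalized
to the UCSC "chr" namespace on input so ENCODE/GEO/UCSC tracks mix safely.

Coordinate conventions per format:

* BED / narrowPeak / BEDPE: 0-based half-open, consumed as-is.
* FIMO TSV and printed genomic coordinates: 1-based inclusive, converted
  to 0-based half-open on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .intervals import GenomicInterval, MotifHit, Peak

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "LoopRecord",
    "normalize_chrom",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_fimo_tsv",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "write_tads_bedpe",
    "write_anchors_bed",
    "gc_fraction",
    "open_fasta",
]


class FormatError(ValueError):
    """A structural problem in an input file."""


@dataclass
class LoopRecord:
    """A chromatin loop given by its two anchors (e.g. a Hi-C loop call).

    ``span`` runs from the first anchor's start to the second anchor's
    end; both anchors must share a chromosome (inter-chromosomal rows are
    rejected at parse time).
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor1.start > self.anchor2.start:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.anchor1.chrom,
            min(self.anchor1.start, self.anchor2.start),
            max(self.anchor1.end, self.anchor2.end),
        )


def normalize_chrom(name: str) -> str:
    """Map a chromosome label into the "chr" namespace ("1" -> "chr1")."""
    name = name.strip()
    if not name:
        raise FormatError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


def read_narrowpeak(
    path: Union[str, Path], score_column: str = "auto"
) -> list[Peak]:
    """Parse a BED3+ / narrowPeak file into :class:`Peak` records.

    Parameters
    ----------
    score_column : {"auto", "score", "signalValue"}
        Where peak strength comes from. "score" is BED column 5,
        "signalValue" narrowPeak column 7. "auto" (default) uses
        signalValue when >= 10 columns are present (Macs2 narrowPeak puts
        the informative strength there), else column 5.

    narrowPeak column 10 (summit offset) is honored when present; the
    conventional -1 means "no summit".
    """
    if score_column not in ("auto", "score", "signalValue"):
        raise ValueError(f"unknown score_column {score_column!r}")
    peaks: list[Peak] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path.name}:{lineno}: expected >= 4 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path.name}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3]
            use_signal = score_column == "signalValue" or (
                score_column == "auto" and len(fields) >= 10
            )
            try:
                if use_signal:
                    if len(fields) < 7:
                        raise FormatError(
                            f"{path.name}:{lineno}: signalValue requested "
                            "but fewer than 7 columns"
                        )
                    score = float(fields[6])
                else:
                    score = float(fields[4]) if len(fields) >= 5 else 0.0
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: non-numeric score"
                ) from exc
            summit: Optional[int] = None
            if len(fields) >= 10:
                s = int(float(fields[9]))
                if s >= 0:
                    summit = s
            fold = None
            if len(fields) >= 7:
                try:
                    fold = float(fields[6])
                except ValueError:
                    fold = None
            peaks.append(
                Peak(
                    interval=GenomicInterval(
                        normalize_chrom(fields[0]), start, end
                    ),
                    score=score,
                    summit_offset=summit,
                    fold_change=fold,
                    name=name,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: Union[str, Path]) -> None:
    """Write peaks as 10-column narrowPeak (signalValue = score)."""
    with open(path, "w") as fh:
        for p in peaks:
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name or ".",
                        f"{min(1000, int(round(p.score)))}",
                        ".",
                        f"{p.score:.10g}",  # signalValue: the operative strength
                        "-1",
                        "-1",
                        str(summit),
                    ]
                )
                + "\n"
            )


_FIMO_REQUIRED = ("motif_id", "sequence_name", "start", "stop", "strand", "score")


def read_fimo_tsv(path: Union[str, Path]) -> list[MotifHit]:
    """Parse a FIMO 5.x TSV of motif occurrences.

    FIMO reports 1-based inclusive start/stop; these are converted to the
    package's 0-based half-open convention. Comment (#) and blank lines
    are skipped.
    """
    path = Path(path)
    hits: list[MotifHit] = []
    header: Optional[dict[str, int]] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                missing = [c for c in _FIMO_REQUIRED if c not in header]
                if missing:
                    raise FormatError(
                        f"{path.name}: FIMO header missing column(s) "
                        + ", ".join(missing)
                    )
                continue
            try:
                start1 = int(fields[header["start"]])
                stop1 = int(fields[header["stop"]])
                strand = fields[header["strand"]]
                score = float(fields[header["score"]])
                pcol = header.get("p-value", header.get("pvalue"))
                pvalue = float(fields[pcol]) if pcol is not None else 1.0
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path.name}:{lineno}: malformed FIMO row"
                ) from exc
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path.name}:{lineno}: invalid strand {strand!r}"
                )
            lo, hi = min(start1, stop1), max(start1, stop1)
            hits.append(
                MotifHit(
                    interval=GenomicInterval(
                        normalize_chrom(fields[header["sequence_name"]]),
                        lo - 1,
                        hi,
                        strand,
                    ),
                    motif_id=fields[header["motif_id"]],
                    score=score,
                    pvalue=pvalue,
                )
            )
    if header is None:
        raise FormatError(f"{path.name}: no FIMO header found")
    return hits


def write_fimo_tsv(hits: Iterable[MotifHit], path: Union[str, Path]) -> None:
    """Write motif hits back out in FIMO 5.x TSV layout (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(
            "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand"
            "\tscore\tp-value\tq-value\tmatched_sequence\n"
        )
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.motif_id,
                        ".",
                        h.interval.chrom,
                        str(h.interval.start + 1),
                        str(h.interval.end),
                        h.interval.strand,
                        f"{h.score:g}",
                        f"{h.pvalue:g}",
                        ".",
                        ".",
                    ]
                )
                + "\n"
            )


def read_loops_bedpe(
    path: Union[str, Path], dialect: str = "bedpe"
) -> list[LoopRecord]:
    """Parse a loop list in BEDPE layout.

    Parameters
    ----------
    dialect : {"bedpe", "rao"}
        "bedpe": plain chrom1,start1,end1,chrom2,start2,end2 leading
        columns. "rao": the GSE63525 loop-list dialect — a header line and
        chromosome names without the "chr" prefix; names are normalized.

    Inter-chromosomal rows are skipped; the skipped count is reported as a
    logging warning.
    """
    if dialect not in ("bedpe", "rao"):
        raise ValueError(f"unknown BEDPE dialect {dialect!r}")
    path = Path(path)
    loops: list[LoopRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path.name}:{lineno}: expected >= 6 columns"
                )
            # rao files carry a header row; detect non-numeric coordinates
            try:
                s1, e1 = int(fields[1]), int(fields[2])
                s2, e2 = int(fields[4]), int(fields[5])
            except ValueError:
                if lineno == 1:
                    continue
                raise FormatError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                )
            c1 = normalize_chrom(fields[0])
            c2 = normalize_chrom(fields[3])
            if c1 != c2:
                skipped += 1
                continue
            name = fields[6] if len(fields) >= 7 and fields[6] else f"loop_{lineno}"
            loops.append(
                LoopRecord(
                    anchor1=GenomicInterval(c1, s1, e1),
                    anchor2=GenomicInterval(c2, s2, e2),
                    source_id=name,
                )
            )
    if skipped:
        logger.warning(
            "%s: skipped %d inter-chromosomal loop row(s)", path.name, skipped
        )
    return loops


def write_loops_bedpe(
    loops: Iterable[LoopRecord], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                "\t".join(
                    [
                        lp.anchor1.chrom,
                        str(lp.anchor1.start),
                        str(lp.anchor1.end),
                        lp.anchor2.chrom,
                        str(lp.anchor2.start),
                        str(lp.anchor2.end),
                        lp.source_id or ".",
                    ]
                )
                + "\n"
            )


def write_tads_bedpe(tads: Iterable, path: Union[str, Path]) -> None:
    """Write predicted TADs as BEDPE with the combined score in column 8."""
    with open(path, "w") as fh:
        for t in tads:
            u, d = t.upstream.interval, t.downstream.interval
            fh.write(
                "\t".join(
                    [
                        u.chrom,
                        str(u.start),
                        str(u.end),
                        d.chrom,
                        str(d.start),
                        str(d.end),
                        t.tad_id,
                        f"{t.combined_score:.6g}",
                    ]
                )
                + "\n"
            )


def write_anchors_bed(anchors: Iterable, path: Union[str, Path]) -> None:
    """Write anchors as BED6 with the anchor score and motif orientation."""
    with open(path, "w") as fh:
        for a in anchors:
            strand = "+" if a.orientation == "forward" else "-"
            fh.write(
                "\t".join(
                    [
                        a.interval.chrom,
                        str(a.interval.start),
                        str(a.interval.end),
                        a.anchor_id,
                        f"{a.anchor_score:.6g}",
                        strand,
                    ]
                )
                + "\n"
            )


def open_fasta(path: Union[str, Path]):
    """Open an (indexed) FASTA for random access via pyfaidx."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def gc_fraction(
    interval: GenomicInterval, genome: Union[Mapping, "object"]
) -> Optional[float]:
    """GC content of the sequence under ``interval``.

    ``genome`` is a pyfaidx.Fasta handle or any mapping of chromosome name
    to sequence string. N bases are excluded from the denominator; an
    all-N interval has undefined GC and returns ``None``.

    Raises
    ------
    KeyError
        If the chromosome is absent from the genome.
    """
    chrom = interval.chrom
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom][interval.start : interval.end]
    seq = str(seq).upper()
    denom = sum(1 for b in seq if b != "N")
    if denom == 0:
        return None
    gc = sum(1 for b in seq if b in "GC")
    return gc / denom
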