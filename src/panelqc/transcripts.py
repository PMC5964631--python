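"""Poor-quality intervals and simplified transcript (c.) coordinates.

A *poor-quality interval* is a maximal run of consecutive positions whose
QCOV falls below a cutoff (default 15 high-quality reads). To make such
intervals actionable for variant review, their genomic endpoints are
translated into coding-sequence coordinates of every overlapping
transcript, using a simplified HGVS-like c. notation:

* exonic coding base N (5'->3' on the transcript strand)  -> ``c.N``
* intronic, k bases into the intron after coding base N   -> ``c.N+k``
* intronic, k bases before coding base N                  -> ``c.N-k``
* 5' UTR, N bases before the first coding base            -> ``c.-N``
* 3' UTR, N bases after the last coding base              -> ``c.*N``

Positions in the 5' half of an intron anchor to the upstream exon (+k),
the 3' half to the downstream exon (-k); the exact midpoint anchors
upstream. Full CSN-style normalisation (repeats, protein notation) is out
of scope — c. coordinates here only localize intervals on a transcript.

Transcript database format (tab-separated, one transcript per line)::

    id  gene  chrom  strand  coding_start  coding_end  exon_starts  exon_ends

where exon_starts/exon_ends are comma-separated 0-based half-open genomic
coordinates sorted by genomic position, and coding_start/coding_end are the
0-based genomic positions of the first and last coding base in transcript
5'->3' order (so coding_start > coding_end on the minus strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from intervaltree import IntervalTree

from .pileup import PerBaseProfile, QualityConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "TranscriptIndex",
    "PoorInterval",
    "OUT_OF_TRANSCRIPT",
    "find_poor_intervals",
    "genomic_to_transcript",
    "load_transcript_db",
    "annotate_poor_intervals",
]

OUT_OF_TRANSCRIPT = "out-of-transcript"


@dataclass(frozen=True)
class Transcript:
    """One coding transcript: exon structure plus CDS boundaries.

    ``exons`` are 0-based half-open genomic intervals sorted by genomic
    coordinate and non-overlapping. ``coding_start``/``coding_end`` are the
    genomic positions (0-based) of the first/last coding base in transcript
    order.
    """

    id: str
    gene: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    coding_start: int
    coding_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: strand must be '+' or '-'")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"transcript {self.id}: empty exon ({start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"transcript {self.id}: exons overlap or are unsorted")
            prev_end = end
        for label, pos in (("coding_start", self.coding_start), ("coding_end", self.coding_end)):
            if not any(start <= pos < end for start, end in self.exons):
                raise ValueError(f"transcript {self.id}: {label} {pos} is not exonic")

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic (start, end) half-open span from first to last exon."""
        return self.exons[0][0], self.exons[-1][1]

    def _offset(self, gpos: int) -> Optional[int]:
        """0-based transcript-order offset of an exonic genomic position."""
        walked = 0
        exon_iter = self.exons if self.strand == "+" else reversed(self.exons)
        for start, end in exon_iter:
            if start <= gpos < end:
                within = (gpos - start) if self.strand == "+" else (end - 1 - gpos)
                return walked + within
            walked += end - start
        return None


def _format_offset(t: int, cds_start_t: int, cds_end_t: int) -> str:
    if t < cds_start_t:
        return f"c.-{cds_start_t - t}"
    if t <= cds_end_t:
        return f"c.{t - cds_start_t + 1}"
    return f"c.*{t - cds_end_t}"


def genomic_to_transcript(pos: int, tx: Transcript) -> str:
    """Simplified c. coordinate of a 1-based genomic position on ``tx``.

    Returns the sentinel ``"out-of-transcript"`` for positions outside the
    transcript's exon span.
    """
    g = pos - 1
    span_start, span_end = tx.span
    if not (span_start <= g < span_end):
        return OUT_OF_TRANSCRIPT

    cds_start_t = tx._offset(tx.coding_start)
    cds_end_t = tx._offset(tx.coding_end)

    t = tx._offset(g)
    if t is not None:
        return _format_offset(t, cds_start_t, cds_end_t)

    # intronic: locate the flanking exons in genomic order
    for (left_start, left_end), (right_start, right_end) in zip(tx.exons, tx.exons[1:]):
        if left_end <= g < right_start:
            break
    else:  # pragma: no cover - span check above makes this unreachable
        return OUT_OF_TRANSCRIPT

    if tx.strand == "+":
        k_up = g - (left_end - 1)          # distance past upstream exon's last base
        k_down = right_start - g           # distance before downstream exon's first base
        t_up = tx._offset(left_end - 1)
        t_down = tx._offset(right_start)
    else:
        k_up = right_start - g             # upstream exon (transcript order) is the right one
        k_down = g - (left_end - 1)
        t_up = tx._offset(right_start)
        t_down = tx._offset(left_end - 1)

    if k_up <= k_down:  # 5' half of the intron (midpoint anchors upstream)
        return f"{_format_offset(t_up, cds_start_t, cds_end_t)}+{k_up}"
    return f"{_format_offset(t_down, cds_start_t, cds_end_t)}-{k_down}"


class TranscriptIndex:
    """Interval-indexed transcript lookup supporting overlap queries."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts = tuple(transcripts)
        self._trees: Dict[str, IntervalTree] = {}
        for tx in transcripts:
            start, end = tx.span
            self._trees.setdefault(tx.chrom, IntervalTree()).addi(start, end, tx)

    def overlapping(self, chrom: str, start: int, end: int) -> List[Transcript]:
        """Transcripts whose exon span overlaps [start, end) (0-based) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda tx: (tx.span, tx.id))

    def __len__(self) -> int:
        return len(self.transcripts)


def load_transcript_db(path: Union[str, Path]) -> TranscriptIndex:
    """Load the tab-separated transcript database (format in module docstring)."""
    path = Path(path)
    transcripts: List[Transcript] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 tab-separated fields, got {len(fields)}")
            try:
                tx = Transcript(
                    id=fields[0],
                    gene=fields[1],
                    chrom=fields[2],
                    strand=fields[3],
                    coding_start=int(fields[4]),
                    coding_end=int(fields[5]),
                    exons=tuple(
                        (int(s), int(e))
                        for s, e in zip(fields[6].split(","), fields[7].split(","))
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            transcripts.append(tx)
    return TranscriptIndex(transcripts)


@dataclass(frozen=True)
class PoorInterval:
    """Maximal run of positions with QCOV below the poor cutoff.

    ``start``/``end`` are 1-based inclusive genomic coordinates; every
    position inside has QCOV < cutoff and the in-region flanks do not.
    ``annotations`` holds (transcript id, c. of start, c. of end) triples.
    """

    region_name: str
    chrom: str
    start: int
    end: int
    min_qcov: int
    annotations: Tuple[Tuple[str, str, str], ...] = ()


def find_poor_intervals(profile: PerBaseProfile, cfg: QualityConfig) -> List[PoorInterval]:
    """Maximal sub-intervals of the region with QCOV < cfg.qcov_poor_cutoff.

    Returned in coordinate order; the poor intervals and the QCOV >= cutoff
    positions exactly tile the region.
    """
    intervals: List[PoorInterval] = []
    run_start = None
    for i, q in enumerate(profile.qcov):
        poor = q < cfg.qcov_poor_cutoff
        if poor and run_start is None:
            run_start = i
        elif not poor and run_start is not None:
            intervals.append(_make_interval(profile, run_start, i))
            run_start = None
    if run_start is not None:
        intervals.append(_make_interval(profile, run_start, len(profile.qcov)))
    return intervals


def _make_interval(profile: PerBaseProfile, i0: int, i1: int) -> PoorInterval:
    return PoorInterval(
        region_name=profile.region.name,
        chrom=profile.region.chrom,
        start=int(profile.positions[i0]),
        end=int(profile.positions[i1 - 1]),
        min_qcov=int(profile.qcov[i0:i1].min()),
    )


def annotate_poor_intervals(
    intervals: Sequence[PoorInterval],
    db: Optional[TranscriptIndex],
) -> List[PoorInterval]:
    """Attach c. coordinates of every overlapping transcript to each interval.

    With no database the intervals pass through with empty annotations
    (the transcript output is optional).
    """
    if db is None:
        return list(intervals)
    annotated = []
    for interval in intervals:
        hits = db.overlapping(interval.chrom, interval.start - 1, interval.end)
        annotations = tuple(
            (tx.id, genomic_to_transcript(interval.start, tx), genomic_to_transcript(interval.end, tx))
            for tx in hits
        )
        annotated.append(
            PoorInterval(
                region_name=interval.region_name,
                chrom=interval.chrom,
                start=interval.start,
                end=interval.end,
                min_qcov=interval.min_qcov,
                annotations=annotations,
            )
        )
    return annotated
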