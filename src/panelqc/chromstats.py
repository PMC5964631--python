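"""Chromosome-level read accounting: total, on-target and off-target reads.

Quantifies how much of the sequencing data is useless for variant calling
inside the panel: for each chromosome (in BAM header contig order) the
total eligible mapped reads (RC), those overlapping at least one target
region (RCIN) and the rest (RCOUT), plus genome-wide mapped/unmapped/total
counts. A read is on-target iff its reference span (alignment start..end,
deletions and N skips included) overlaps any target region on its
chromosome; a read overlapping several regions is counted once. Only
primary alignments are counted, so each template end contributes one count;
unmapped reads appear only in the totals row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

import pysam
from intervaltree import IntervalTree

from .pileup import QualityConfig, _open_bam
from .regions import TargetRegion

__all__ = ["ChromRow", "ChromStats", "summarize_chromosomes", "build_region_index"]


@dataclass(frozen=True)
class ChromRow:
    chrom: str
    rc: int
    rcin: int
    rcout: int


@dataclass(frozen=True)
class ChromStats:
    """Per-chromosome rows plus whole-file totals (mapped + unmapped = total)."""

    rows: Tuple[ChromRow, ...]
    mapped: int
    unmapped: int

    @property
    def total(self) -> int:
        return self.mapped + self.unmapped


def build_region_index(regions: Iterable[TargetRegion]) -> Dict[str, IntervalTree]:
    """Per-chromosome interval tree for on/off-target overlap queries."""
    trees: Dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(region.start, region.end)
    return trees


def summarize_chromosomes(
    bam: Union[str, Path, pysam.AlignmentFile],
    regions: Iterable[TargetRegion],
    cfg: QualityConfig,
) -> ChromStats:
    """Count RC/RCIN/RCOUT per chromosome and mapped/unmapped totals.

    Eligibility matches the pileup engine (primary, non-QC-fail, duplicate
    toggle applies); the unmapped total counts reads failing only the
    "mapped" test under the same remaining filters. Chromosomes with zero
    reads still emit a row.
    """
    trees = build_region_index(regions)
    # always reopen: fetch(until_eof=True) streams from the handle's current
    # file position, which region fetches elsewhere may have moved
    if isinstance(bam, pysam.AlignmentFile):
        bam = bam.filename.decode()
    with _open_bam(bam) as handle:
        counts: Dict[str, List[int]] = {ref: [0, 0] for ref in handle.references}  # rc, rcin
        unmapped = 0
        for read in handle.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary or read.is_qcfail:
                continue
            if read.is_duplicate and not cfg.count_duplicates:
                continue
            if read.is_unmapped:
                unmapped += 1
                continue
            chrom = read.reference_name
            entry = counts[chrom]
            entry[0] += 1
            tree = trees.get(chrom)
            if tree is not None and tree.overlaps(read.reference_start, read.reference_end):
                entry[1] += 1
        rows = tuple(
            ChromRow(chrom=ref, rc=rc, rcin=rcin, rcout=rc - rcin)
            for ref, (rc, rcin) in counts.items()
        )
    mapped = sum(row.rc for row in rows)
    return ChromStats(rows=rows, mapped=mapped, unmapped=unmapped)
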