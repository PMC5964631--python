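"""Brute-force reference computation of every metric, for the test suite.

Everything here is recomputed from :class:`~panelqc.fixtures.ReadSpec`
lists by direct nested iteration over reads and positions, with plain
Python lists and :func:`statistics.median` — deliberately sharing no code
(and no numpy vectorisation, histogram medians or interval trees) with the
production engine in :mod:`panelqc.pileup`, :mod:`panelqc.summary` and
:mod:`panelqc.chromstats`. On small fixtures the engine must agree with
this oracle exactly; keep it slow and obvious.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .fixtures import ReadSpec
from .regions import TargetRegion

__all__ = ["OracleProfile", "OracleSummary", "oracle_profile", "oracle_summary", "oracle_chrom_stats"]


@dataclass
class OracleProfile:
    """Per-position metric lists; None marks an undefined value."""

    positions: List[int]
    cov: List[int]
    qcov: List[int]
    medbq: List[Optional[float]]
    flbq: List[Optional[float]]
    medmq: List[Optional[float]]
    flmq: List[Optional[float]]


@dataclass
class OracleSummary:
    rc: int
    medcov: float
    mincov: int
    medqcov: float
    minqcov: int
    maxflmq: Optional[float]
    maxflbq: Optional[float]


def _eligible(spec: ReadSpec, count_duplicates: bool) -> bool:
    if not spec.is_mapped or spec.secondary or spec.supplementary or spec.qcfail:
        return False
    if spec.duplicate and not count_duplicates:
        return False
    return True


def _mq_is_low(mq: int, cutoff: int) -> bool:
    # 255 = "unavailable" fails any positive cutoff
    if cutoff == 0:
        return False
    return mq < cutoff or mq == 255


def _columns(spec: ReadSpec) -> Dict[int, Optional[int]]:
    """Covered 0-based genomic position -> BQ (None for spanning deletions).

    Walks the CIGAR base by base; aligned bases and deletions cover, N
    skips / insertions / clips do not.
    """
    columns: Dict[int, Optional[int]] = {}
    ref = spec.start - 1
    query = 0
    for length, op in spec.cigar_ops:
        if op in "M=X":
            for i in range(length):
                columns[ref + i] = spec.base_qualities[query + i]
            ref += length
            query += length
        elif op == "D":
            for i in range(length):
                columns[ref + i] = None
            ref += length
        elif op == "N":
            ref += length
        elif op in "IS":
            query += length
        # H and P consume nothing
    return columns


def oracle_profile(
    reads: Sequence[ReadSpec],
    region: TargetRegion,
    bq_cutoff: int = 10,
    mq_cutoff: int = 20,
    count_duplicates: bool = True,
    strand: Optional[str] = None,
) -> OracleProfile:
    """Recompute the per-base profile by iterating every read at every position."""
    candidates = []
    for spec in reads:
        if not _eligible(spec, count_duplicates) or spec.chrom != region.chrom:
            continue
        if strand == "+" and spec.reverse:
            continue
        if strand == "-" and not spec.reverse:
            continue
        candidates.append((spec, _columns(spec)))

    profile = OracleProfile([], [], [], [], [], [], [])
    for gpos0 in range(region.start, region.end):
        covering: List[ReadSpec] = []
        bases: List[int] = []
        qcov = 0
        for spec, columns in candidates:
            if gpos0 not in columns:
                continue
            bq = columns[gpos0]
            covering.append(spec)
            if bq is not None:
                bases.append(bq)
                if bq >= bq_cutoff and not _mq_is_low(spec.mapping_quality, mq_cutoff):
                    qcov += 1
        profile.positions.append(gpos0 + 1)
        profile.cov.append(len(covering))
        profile.qcov.append(qcov)
        profile.medbq.append(float(statistics.median(bases)) if bases else None)
        profile.flbq.append(
            sum(1 for b in bases if b < bq_cutoff) / len(bases) if bases else None
        )
        profile.medmq.append(
            float(statistics.median(s.mapping_quality for s in covering)) if covering else None
        )
        profile.flmq.append(
            sum(1 for s in covering if _mq_is_low(s.mapping_quality, mq_cutoff)) / len(covering)
            if covering
            else None
        )
    return profile


def oracle_summary(
    reads: Sequence[ReadSpec],
    region: TargetRegion,
    bq_cutoff: int = 10,
    mq_cutoff: int = 20,
    count_duplicates: bool = True,
) -> OracleSummary:
    """Region summary recomputed from the oracle profile and an overlap scan."""
    profile = oracle_profile(reads, region, bq_cutoff, mq_cutoff, count_duplicates)
    rc = 0
    for spec in reads:
        if not _eligible(spec, count_duplicates) or spec.chrom != region.chrom:
            continue
        if spec.start - 1 < region.end and spec.reference_end > region.start:
            rc += 1
    flmq = [v for v in profile.flmq if v is not None]
    flbq = [v for v in profile.flbq if v is not None]
    return OracleSummary(
        rc=rc,
        medcov=float(statistics.median(profile.cov)),
        mincov=min(profile.cov),
        medqcov=float(statistics.median(profile.qcov)),
        minqcov=min(profile.qcov),
        maxflmq=max(flmq) if flmq else None,
        maxflbq=max(flbq) if flbq else None,
    )


def oracle_chrom_stats(
    reads: Sequence[ReadSpec],
    regions: Sequence[TargetRegion],
    count_duplicates: bool = True,
) -> Tuple[Dict[str, Tuple[int, int, int]], int, int]:
    """Per-chromosome (RC, RCIN, RCOUT) plus (mapped, unmapped) totals."""
    per_chrom: Dict[str, List[int]] = {}
    unmapped = 0
    for spec in reads:
        if spec.secondary or spec.supplementary or spec.qcfail:
            continue
        if spec.duplicate and not count_duplicates:
            continue
        if not spec.is_mapped:
            unmapped += 1
            continue
        entry = per_chrom.setdefault(spec.chrom, [0, 0])
        entry[0] += 1
        on_target = any(
            r.chrom == spec.chrom and spec.start - 1 < r.end and spec.reference_end > r.start
            for r in regions
        )
        if on_target:
            entry[1] += 1
    mapped = sum(rc for rc, _ in per_chrom.values())
    return (
        {chrom: (rc, rcin, rc - rcin) for chrom, (rc, rcin) in per_chrom.items()},
        mapped,
        unmapped,
    )
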