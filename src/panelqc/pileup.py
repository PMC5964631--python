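"""Per-base pileup metrics: COV, QCOV, MEDBQ, FLBQ, MEDMQ, FLMQ.

The six position-specific metrics are computed for every base of a target
region from the mapped reads of an indexed BAM:

COV    number of eligible reads whose alignment covers the position
       (aligned match/mismatch base, or a deletion spanning it);
MEDBQ  median Phred base quality of the read bases aligned to the position;
FLBQ   fraction of those read bases with BQ strictly below the BQ cutoff;
MEDMQ  median mapping quality of the covering reads;
FLMQ   fraction of covering reads with low mapping quality;
QCOV   "quality coverage": covering reads with MQ >= mq_cutoff that also
       contribute an aligned base with BQ >= bq_cutoff.

Semantics worth spelling out because they decide clinical flags:

* quality comparisons are inclusive: BQ >= bq_cutoff and MQ >= mq_cutoff
  pass; "low" means strictly below the cutoff;
* a read whose deletion spans a position covers it (COV, MEDMQ, FLMQ) but
  contributes no base, so it cannot count toward QCOV and is absent from
  MEDBQ/FLBQ;
* soft clips and N (skip) operations do not cover positions; insertions
  sit between positions and affect nothing;
* MQ 255 means "mapping quality unavailable" (SAM spec) and is treated as
  failing any mq_cutoff > 0 — an unknown quality must never silently pass
  a clinical threshold — while still contributing its stored value to MEDMQ;
* eligible reads are mapped, primary (not secondary/supplementary), not
  QC-fail; duplicate-flagged reads are excluded iff count_duplicates is
  false;
* fractions are undefined (NaN) exactly when their denominator is zero;
  medians likewise.

Median of an even-sized multiset is the mean of the two middle values.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Tuple, Union

import numpy as np
import pysam

from .regions import TargetRegion

logger = logging.getLogger(__name__)

__all__ = [
    "QualityConfig",
    "PerBaseProfile",
    "compute_profile",
    "compute_directional_profiles",
    "count_overlapping_reads",
]

# CIGAR operation codes (BAM numeric encoding)
_CONSUMES_BOTH = (0, 7, 8)  # M, =, X
_DELETION = 2
_REF_SKIP = 3
_INSERTION = 1
_SOFT_CLIP = 4

_MAX_BQ = 93  # Phred+33 printable ceiling
_MQ_UNAVAILABLE = 255


@dataclass(frozen=True)
class QualityConfig:
    """Quality cutoffs and counting switches.

    Parameters
    ----------
    bq_cutoff : int
        Phred base-quality threshold; a base with BQ >= cutoff is "good".
    mq_cutoff : int
        Phred mapping-quality threshold; a read with MQ >= cutoff is "good".
    count_duplicates : bool
        Include duplicate-flagged (0x400) reads in every metric.
    direction_split : bool
        Also compute forward-/reverse-only profiles.
    qcov_poor_cutoff : int
        Positions with QCOV strictly below this form poor-quality intervals.
    """

    bq_cutoff: int = 10
    mq_cutoff: int = 20
    count_duplicates: bool = True
    direction_split: bool = False
    qcov_poor_cutoff: int = 15

    def __post_init__(self) -> None:
        for attr in ("bq_cutoff", "mq_cutoff", "qcov_poor_cutoff"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0, got {getattr(self, attr)}")

    def mq_passes(self, mq: int) -> bool:
        """Inclusive MQ test; MQ 255 (unavailable) fails any cutoff > 0."""
        if self.mq_cutoff == 0:
            return True
        return mq != _MQ_UNAVAILABLE and mq >= self.mq_cutoff


@dataclass
class PerBaseProfile:
    """Arrays of the six per-base metrics over one region.

    ``positions`` holds 1-based inclusive genomic coordinates. Undefined
    metric values (zero denominator) are NaN in the float arrays.
    """

    region: TargetRegion
    positions: np.ndarray
    cov: np.ndarray
    qcov: np.ndarray
    medbq: np.ndarray
    flbq: np.ndarray
    medmq: np.ndarray
    flmq: np.ndarray
    strand: Optional[str] = None  # None (both), "+" or "-"
    forward: Optional["PerBaseProfile"] = field(default=None, repr=False)
    reverse: Optional["PerBaseProfile"] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.positions)


def _is_eligible(read: pysam.AlignedSegment, cfg: QualityConfig) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_qcfail:
        return False
    if read.is_duplicate and not cfg.count_duplicates:
        return False
    return True


@contextmanager
def _open_bam(bam: Union[str, Path, pysam.AlignmentFile]) -> Iterator[pysam.AlignmentFile]:
    if isinstance(bam, pysam.AlignmentFile):
        yield bam
    else:
        with pysam.AlignmentFile(str(bam), "rb") as handle:
            yield handle


def _require_index(bam: pysam.AlignmentFile) -> None:
    if not bam.has_index():
        raise FileNotFoundError(
            f"BAM index (.bai) missing for {bam.filename.decode()!r}; "
            "run 'samtools index' first"
        )


def _medians_from_counts(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Per-row median of a value histogram; NaN where the row is empty.

    counts[i, v] is the multiplicity of value v at position i; totals[i]
    is the row sum. Even-sized rows take the mean of the two middle values.
    """
    medians = np.full(len(totals), np.nan)
    for i in np.nonzero(totals)[0]:
        cum = np.cumsum(counts[i])
        n = int(totals[i])
        lo = int(np.searchsorted(cum, (n - 1) // 2 + 1))
        hi = int(np.searchsorted(cum, n // 2 + 1))
        medians[i] = (lo + hi) / 2.0
    return medians


def compute_profile(
    region: TargetRegion,
    bam: Union[str, Path, pysam.AlignmentFile],
    cfg: QualityConfig,
    strand: Optional[str] = None,
) -> PerBaseProfile:
    """Compute the per-base metric profile of ``region``.

    Parameters
    ----------
    region : TargetRegion
    bam : path or open :class:`pysam.AlignmentFile`
        Coordinate-sorted, indexed BAM of mapped reads.
    cfg : QualityConfig
    strand : {None, "+", "-"}
        Restrict to forward ("+") or reverse ("-") reads; None uses both.

    Returns
    -------
    PerBaseProfile
        Metric arrays over the region; all-zero COV (with a warning) when
        the region's chromosome is absent from the BAM header.
    """
    if strand not in (None, "+", "-"):
        raise ValueError(f"strand must be None, '+' or '-', got {strand!r}")

    length = region.length
    cov = np.zeros(length, dtype=np.int64)
    qcov = np.zeros(length, dtype=np.int64)
    n_bases = np.zeros(length, dtype=np.int64)
    low_bq = np.zeros(length, dtype=np.int64)
    low_mq = np.zeros(length, dtype=np.int64)
    bq_counts = np.zeros((length, _MAX_BQ + 1), dtype=np.int64)
    mq_counts = np.zeros((length, _MQ_UNAVAILABLE + 1), dtype=np.int64)

    with _open_bam(bam) as handle:
        if region.chrom not in handle.references:
            logger.warning(
                "chromosome %r (region %s) absent from BAM header %s; "
                "emitting all-zero profile (note: 'chr' prefix dialects are "
                "never auto-reconciled)",
                region.chrom,
                region.name,
                sorted(handle.references)[:5],
            )
        else:
            _require_index(handle)
            for read in handle.fetch(region.chrom, region.start, region.end):
                if not _is_eligible(read, cfg):
                    continue
                if strand == "+" and read.is_reverse:
                    continue
                if strand == "-" and not read.is_reverse:
                    continue
                _accumulate_read(
                    read, region, cfg, cov, qcov, n_bases, low_bq, low_mq,
                    bq_counts, mq_counts,
                )

    with np.errstate(invalid="ignore", divide="ignore"):
        flbq = np.where(n_bases > 0, low_bq / np.maximum(n_bases, 1), np.nan)
        flmq = np.where(cov > 0, low_mq / np.maximum(cov, 1), np.nan)

    return PerBaseProfile(
        region=region,
        positions=np.arange(region.start + 1, region.end + 1, dtype=np.int64),
        cov=cov,
        qcov=qcov,
        medbq=_medians_from_counts(bq_counts, n_bases),
        flbq=flbq,
        medmq=_medians_from_counts(mq_counts, cov),
        flmq=flmq,
        strand=strand,
    )


def _accumulate_read(
    read: pysam.AlignedSegment,
    region: TargetRegion,
    cfg: QualityConfig,
    cov: np.ndarray,
    qcov: np.ndarray,
    n_bases: np.ndarray,
    low_bq: np.ndarray,
    low_mq: np.ndarray,
    bq_counts: np.ndarray,
    mq_counts: np.ndarray,
) -> None:
    mq = read.mapping_quality
    mq_ok = cfg.mq_passes(mq)
    quals = read.query_qualities
    ref_pos = read.reference_start
    query_pos = 0
    for op, op_len in read.cigartuples:
        if op in _CONSUMES_BOTH:
            lo = max(ref_pos, region.start)
            hi = min(ref_pos + op_len, region.end)
            if lo < hi:
                i0 = lo - region.start
                i1 = hi - region.start
                idx = np.arange(i0, i1)
                q = np.asarray(
                    quals[query_pos + (lo - ref_pos): query_pos + (hi - ref_pos)],
                    dtype=np.int64,
                )
                cov[i0:i1] += 1
                n_bases[i0:i1] += 1
                low_bq[i0:i1] += q < cfg.bq_cutoff
                if mq_ok:
                    qcov[i0:i1] += q >= cfg.bq_cutoff
                else:
                    low_mq[i0:i1] += 1
                np.add.at(bq_counts, (idx, np.clip(q, 0, _MAX_BQ)), 1)
                mq_counts[i0:i1, min(mq, _MQ_UNAVAILABLE)] += 1
            ref_pos += op_len
            query_pos += op_len
        elif op == _DELETION:
            lo = max(ref_pos, region.start)
            hi = min(ref_pos + op_len, region.end)
            if lo < hi:
                i0 = lo - region.start
                i1 = hi - region.start
                cov[i0:i1] += 1
                mq_counts[i0:i1, min(mq, _MQ_UNAVAILABLE)] += 1
                if not mq_ok:
                    low_mq[i0:i1] += 1
            ref_pos += op_len
        elif op == _REF_SKIP:
            ref_pos += op_len
        elif op in (_INSERTION, _SOFT_CLIP):
            query_pos += op_len
        # hard clip / padding consume neither


def compute_directional_profiles(
    region: TargetRegion,
    bam: Union[str, Path, pysam.AlignmentFile],
    cfg: QualityConfig,
) -> Tuple[PerBaseProfile, PerBaseProfile]:
    """Forward-only and reverse-only profiles (strand-specific bias check).

    The two profiles use identical metric definitions restricted to reads
    on each strand; their COV/QCOV arrays sum to the unsplit profile's.
    """
    with _open_bam(bam) as handle:
        fwd = compute_profile(region, handle, cfg, strand="+")
        rev = compute_profile(region, handle, cfg, strand="-")
    return fwd, rev


def count_overlapping_reads(
    region: TargetRegion,
    bam: Union[str, Path, pysam.AlignmentFile],
    cfg: QualityConfig,
) -> int:
    """RC: eligible reads whose alignment overlaps the region by >=1 reference base.

    Counted from the read list, not the profile: a read's reference span
    (including deletions and N skips) can overlap a region even where it
    contributes no aligned base.
    """
    with _open_bam(bam) as handle:
        if region.chrom not in handle.references:
            return 0
        _require_index(handle)
        return sum(
            1
            for read in handle.fetch(region.chrom, region.start, region.end)
            if _is_eligible(read, cfg)
        )
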