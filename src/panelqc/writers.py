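"""Tab-separated output writers for the four result files.

All files share the same conventions: a single header line starting '#',
tab-separated columns, undefined values written as '.', medians to one
decimal place, fractions to three. Outputs carry no timestamps, so repeated
runs on identical inputs are byte-identical. Genomic coordinates in every
output are 1-based inclusive.

Files (for output prefix P):
  P_summary.txt   per-chromosome RC/RCIN/RCOUT plus mapped/unmapped/total
  P_regions.txt   one row per BED region with the summary metrics + status
  P_profiles.txt  per-base metric rows, regions separated by a '#' line
  P_poor.txt      poor-quality intervals with transcript c. coordinates
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence, TextIO, Union

from .chromstats import ChromStats
from .pileup import PerBaseProfile
from .summary import RegionSummary
from .transcripts import PoorInterval

if TYPE_CHECKING:  # pragma: no cover
    from .runner import RegionResult

__all__ = [
    "format_median",
    "format_fraction",
    "write_summary",
    "write_regions",
    "write_profiles",
    "write_poor",
]

MISSING = "."


def format_median(value: Optional[float]) -> str:
    """Median to one decimal place; '.' when undefined."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    return f"{value:.1f}"


def format_fraction(value: Optional[float]) -> str:
    """Fraction to three decimal places; '.' when undefined."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    return f"{value:.3f}"


def write_summary(stats: ChromStats, path: Union[str, Path]) -> None:
    with Path(path).open("w") as out:
        out.write("#CHROM\tRC\tRCIN\tRCOUT\n")
        for row in stats.rows:
            out.write(f"{row.chrom}\t{row.rc}\t{row.rcin}\t{row.rcout}\n")
        out.write(f"MAPPED\t{stats.mapped}\t{MISSING}\t{MISSING}\n")
        out.write(f"UNMAPPED\t{stats.unmapped}\t{MISSING}\t{MISSING}\n")
        out.write(f"TOTAL\t{stats.total}\t{MISSING}\t{MISSING}\n")


_REGION_COLUMNS = (
    "#REGION\tCHROM\tSTART\tEND\tRC\tMEDCOV\tMINCOV\tMEDQCOV\tMINQCOV"
    "\tMAXFLMQ\tMAXFLBQ\tSTATUS\tFAILED_METRICS"
)


def _summary_fields(s: RegionSummary) -> str:
    return "\t".join(
        (
            str(s.rc),
            format_median(s.medcov),
            str(s.mincov),
            format_median(s.medqcov),
            str(s.minqcov),
            format_fraction(s.maxflmq),
            format_fraction(s.maxflbq),
        )
    )


def write_regions(summaries: Sequence[RegionSummary], path: Union[str, Path]) -> None:
    """Region rows in BED order; START/END are 1-based inclusive."""
    with Path(path).open("w") as out:
        header = _REGION_COLUMNS
        if summaries and summaries[0].forward is not None:
            directional = "\t".join(
                f"{m}_{tag}"
                for tag in ("FWD", "REV")
                for m in ("RC", "MEDCOV", "MINCOV", "MEDQCOV", "MINQCOV", "MAXFLMQ", "MAXFLBQ")
            )
            header = f"{header}\t{directional}"
        out.write(header + "\n")
        for s in summaries:
            region = s.region
            row = (
                f"{region.name}\t{region.chrom}\t{region.start + 1}\t{region.end}\t"
                f"{_summary_fields(s)}\t{s.status}\t"
                f"{','.join(s.failed_metrics) if s.failed_metrics else MISSING}"
            )
            if s.forward is not None and s.reverse is not None:
                row = f"{row}\t{_summary_fields(s.forward)}\t{_summary_fields(s.reverse)}"
            out.write(row + "\n")


_PROFILE_COLUMNS = "#REGION\tCHROM\tPOS\tCOV\tQCOV\tMEDBQ\tFLBQ\tMEDMQ\tFLMQ"
_DIRECTIONAL_PROFILE_COLUMNS = "\t".join(
    f"{m}_{tag}"
    for tag in ("FWD", "REV")
    for m in ("COV", "QCOV", "MEDBQ", "FLBQ", "MEDMQ", "FLMQ")
)


def _profile_row(profile: PerBaseProfile, i: int) -> str:
    return "\t".join(
        (
            str(int(profile.cov[i])),
            str(int(profile.qcov[i])),
            format_median(float(profile.medbq[i])),
            format_fraction(float(profile.flbq[i])),
            format_median(float(profile.medmq[i])),
            format_fraction(float(profile.flmq[i])),
        )
    )


def write_profiles(
    results: Iterable["RegionResult"],
    path: Union[str, Path],
    direction_split: bool = False,
) -> None:
    """Per-base rows for each region, blocks separated by a '# <name>' line."""
    with Path(path).open("w") as out:
        header = _PROFILE_COLUMNS
        if direction_split:
            header = f"{header}\t{_DIRECTIONAL_PROFILE_COLUMNS}"
        out.write(header + "\n")
        for result in results:
            profile = result.profile
            region = profile.region
            out.write(f"# {region.name}\n")
            for i in range(len(profile)):
                row = (
                    f"{region.name}\t{region.chrom}\t{int(profile.positions[i])}\t"
                    f"{_profile_row(profile, i)}"
                )
                if direction_split and result.forward is not None:
                    row = (
                        f"{row}\t{_profile_row(result.forward, i)}"
                        f"\t{_profile_row(result.reverse, i)}"
                    )
                out.write(row + "\n")


def write_poor(intervals: Sequence[PoorInterval], gene_of: dict, path: Union[str, Path]) -> None:
    """Poor intervals with gene label and transcript c. coordinate annotations.

    ``gene_of`` maps region name -> gene label. Annotations from several
    transcripts are semicolon-separated; '.' when none.
    """
    with Path(path).open("w") as out:
        out.write("#REGION\tGENE\tCHROM\tSTART\tEND\tMIN_QCOV\tTRANSCRIPTS\n")
        for iv in intervals:
            annotation = (
                ";".join(f"{tx_id}:{c_start}..{c_end}" for tx_id, c_start, c_end in iv.annotations)
                or MISSING
            )
            out.write(
                f"{iv.region_name}\t{gene_of.get(iv.region_name, MISSING)}\t{iv.chrom}\t"
                f"{iv.start}\t{iv.end}\t{iv.min_qcov}\t{annotation}\n"
            )
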