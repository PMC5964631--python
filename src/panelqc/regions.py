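"""Target regions: BED parsing and the coordinate conventions used everywhere else.

Input BED intervals are 0-based half-open (standard BED). All user-facing
output positions are 1-based inclusive genomic coordinates. Chromosome-name
dialects ("chr7" vs "7") are deliberately never reconciled: a mismatch
between BED and BAM is surfaced as a diagnostic, since silent renaming is a
clinical-grade failure mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

logger = logging.getLogger(__name__)

__all__ = ["TargetRegion", "BedError", "parse_bed", "write_bed"]


class BedError(ValueError):
    """Raised for malformed BED input (bad coordinates, empty file)."""


@dataclass(frozen=True)
class TargetRegion:
    """One named target interval (typically an exon of a panel gene).

    Attributes
    ----------
    name : str
        Region label, conventionally ``GENE_EXON`` (e.g. ``"PMS2_12"``).
    chrom : str
        Chromosome name exactly as spelled in the BED file.
    start : int
        0-based inclusive genomic start.
    end : int
        0-based exclusive genomic end (half-open, BED convention).
    """

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise BedError(
                f"region {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if not self.name:
            raise BedError("region name must be non-empty")

    @property
    def length(self) -> int:
        """Number of profiled positions (= end - start)."""
        return self.end - self.start

    @property
    def gene(self) -> str:
        """Gene label: text before the last underscore, else the whole name."""
        head, sep, _ = self.name.rpartition("_")
        return head if sep else self.name

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}({self.chrom}:{self.start}-{self.end})"


_SKIP_PREFIXES = ("#", "track", "browser")


def parse_bed(path: Union[str, Path]) -> List[TargetRegion]:
    """Parse target regions from a BED file, preserving file order.

    Lines must have >=3 tab-separated fields (chrom, start, end); a 4th
    field, when present, is the region name, otherwise ``chrom:start-end``
    is synthesized. Comment/track/browser lines and blank lines are skipped.

    Raises
    ------
    BedError
        On a missing file, non-integer coordinates, zero-length intervals
        (naming the offending line number) or a file with no regions.
    """
    path = Path(path)
    if not path.exists():
        raise BedError(f"BED file not found: {path}")

    regions: List[TargetRegion] = []
    seen_names: set = set()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedError(f"{path}:{lineno}: non-integer coordinates: {exc}") from None
            if start >= end:
                raise BedError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            if name in seen_names:
                logger.warning("duplicate region name %r at %s:%d", name, path, lineno)
            seen_names.add(name)
            regions.append(TargetRegion(name=name, chrom=chrom, start=start, end=end))

    if not regions:
        raise BedError(f"{path}: no regions found")
    return regions


def write_bed(regions: Iterable[TargetRegion], path: Union[str, Path]) -> None:
    """Write regions back to 4-column BED (round-trips with :func:`parse_bed`)."""
    with Path(path).open("w") as handle:
        for region in regions:
            handle.write(f"{region.chrom}\t{region.start}\t{region.end}\t{region.name}\n")
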