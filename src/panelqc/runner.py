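"""Run orchestration: BED + BAM + config in, four result files out.

This is the library entry point the CLI wraps: :func:`run` computes
everything and returns in-memory results; :func:`run_and_write` also writes
the four tab-separated output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional

import pysam

from .config import ConfigError, RunConfig
from .chromstats import ChromStats, summarize_chromosomes
from .pileup import (
    PerBaseProfile,
    compute_directional_profiles,
    compute_profile,
    count_overlapping_reads,
)
from .regions import TargetRegion, parse_bed
from .summary import RegionSummary, apply_flags, summarize_region
from .transcripts import (
    PoorInterval,
    annotate_poor_intervals,
    find_poor_intervals,
    load_transcript_db,
)
from . import writers

logger = logging.getLogger(__name__)

__all__ = ["RegionResult", "RunResult", "run", "run_and_write", "output_paths"]


@dataclass
class RegionResult:
    """Everything computed for one target region."""

    region: TargetRegion
    profile: PerBaseProfile
    summary: RegionSummary
    poor_intervals: List[PoorInterval]
    forward: Optional[PerBaseProfile] = None
    reverse: Optional[PerBaseProfile] = None


@dataclass
class RunResult:
    regions: List[RegionResult]
    chrom_stats: ChromStats
    config: RunConfig

    @property
    def flagged(self) -> List[RegionResult]:
        return [r for r in self.regions if r.summary.status == "FLAG"]


def output_paths(prefix: Path) -> Dict[str, Path]:
    prefix = Path(prefix)
    return {
        kind: prefix.parent / f"{prefix.name}_{kind}.txt"
        for kind in ("summary", "regions", "profiles", "poor")
    }


def run(config: RunConfig) -> RunResult:
    """Execute the full evaluation and return in-memory results."""
    config.validate_paths()
    cfg = config.quality
    regions = parse_bed(config.bed)
    tx_db = (
        load_transcript_db(config.outputs.transcript_db)
        if config.outputs.transcript_db is not None
        else None
    )

    results: List[RegionResult] = []
    with pysam.AlignmentFile(str(config.bam), "rb") as bam:
        for region in regions:
            profile = compute_profile(region, bam, cfg)
            rc = count_overlapping_reads(region, bam, cfg)
            summary = apply_flags(summarize_region(profile, rc), config.flags)
            forward = reverse = None
            if cfg.direction_split:
                forward, reverse = compute_directional_profiles(region, bam, cfg)
                summary = replace(
                    summary,
                    forward=apply_flags(
                        summarize_region(forward, _strand_rc(region, bam, cfg, "+")),
                        config.flags,
                    ),
                    reverse=apply_flags(
                        summarize_region(reverse, _strand_rc(region, bam, cfg, "-")),
                        config.flags,
                    ),
                )
            poor = annotate_poor_intervals(find_poor_intervals(profile, cfg), tx_db)
            results.append(
                RegionResult(
                    region=region,
                    profile=profile,
                    summary=summary,
                    poor_intervals=poor,
                    forward=forward,
                    reverse=reverse,
                )
            )
        chrom_stats = summarize_chromosomes(bam, regions, cfg)

    logger.info(
        "%d/%d regions flagged; %d mapped reads (%d unmapped)",
        sum(1 for r in results if r.summary.status == "FLAG"),
        len(results),
        chrom_stats.mapped,
        chrom_stats.unmapped,
    )
    return RunResult(regions=results, chrom_stats=chrom_stats, config=config)


def _strand_rc(region, bam, cfg, strand: str) -> int:
    from .pileup import _is_eligible  # strand-restricted overlap count

    count = 0
    if region.chrom in bam.references:
        for read in bam.fetch(region.chrom, region.start, region.end):
            if not _is_eligible(read, cfg):
                continue
            if (strand == "+") != (not read.is_reverse):
                continue
            count += 1
    return count


def run_and_write(config: RunConfig) -> RunResult:
    """Run the evaluation and write the four output files.

    Output writability is checked before computation starts (fail fast).
    """
    paths = output_paths(config.prefix)
    out_dir = Path(config.prefix).resolve().parent
    if not out_dir.is_dir():
        raise ConfigError(f"output directory does not exist: {out_dir}")
    probe = out_dir / f".{Path(config.prefix).name}.write-probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ConfigError(f"output directory not writable: {out_dir}: {exc}") from None

    result = run(config)

    writers.write_summary(result.chrom_stats, paths["summary"])
    writers.write_regions([r.summary for r in result.regions], paths["regions"])

    mode = config.outputs.profiles
    if mode == "flagged":
        profiled = [r for r in result.regions if r.summary.status == "FLAG"]
    elif mode == "none":
        profiled = []
    else:
        profiled = result.regions
    writers.write_profiles(profiled, paths["profiles"], config.quality.direction_split)

    if config.outputs.poor:
        gene_of = {r.region.name: r.region.gene for r in result.regions}
        intervals = [iv for r in result.regions for iv in r.poor_intervals]
        writers.write_poor(intervals, gene_of, paths["poor"])

    return result
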