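"""INI run configuration: quality cutoffs, flag criteria, output options.

The configuration file has three sections, all optional::

    [quality]
    bq_cutoff = 10          ; Phred BQ threshold (inclusive pass)
    mq_cutoff = 20          ; Phred MQ threshold (inclusive pass)
    qcov_poor_cutoff = 15   ; QCOV below this defines poor intervals
    count_duplicates = true ; include 0x400-flagged reads
    direction = false       ; also emit forward/reverse-split metrics

    [flags]
    MINQCOV_min = 50        ; <METRIC>_min / <METRIC>_max, any Table-2 metric
    MAXFLBQ_max = 0.2

    [outputs]
    profiles = all          ; all | flagged | none
    poor = true             ; write the poor-interval file
    transcript_db = db.txt  ; optional transcript database path

Missing keys take the documented defaults; unknown keys are logged as
warnings; a non-numeric threshold is a hard error.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

from .pileup import QualityConfig
from .summary import FlagCriteria

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "OutputOptions", "RunConfig", "parse_config"]


class ConfigError(ValueError):
    """Raised for unparseable or invalid configuration input."""


_QUALITY_KEYS = {"bq_cutoff", "mq_cutoff", "qcov_poor_cutoff", "count_duplicates", "direction"}
_OUTPUT_KEYS = {"profiles", "poor", "transcript_db"}
_PROFILE_MODES = ("all", "flagged", "none")


@dataclass(frozen=True)
class OutputOptions:
    profiles: str = "all"  # all | flagged | none
    poor: bool = True
    transcript_db: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.profiles not in _PROFILE_MODES:
            raise ConfigError(
                f"outputs.profiles must be one of {_PROFILE_MODES}, got {self.profiles!r}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs: input paths, cutoffs, criteria, outputs."""

    bam: Path
    bed: Path
    prefix: Path
    quality: QualityConfig = field(default_factory=QualityConfig)
    flags: FlagCriteria = field(default_factory=FlagCriteria)
    outputs: OutputOptions = field(default_factory=OutputOptions)

    def validate_paths(self) -> None:
        """Fail fast, before any computation starts."""
        for label, path in (("BAM", self.bam), ("BED", self.bed)):
            if not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")
        if self.outputs.transcript_db is not None and not Path(self.outputs.transcript_db).exists():
            raise ConfigError(f"transcript database not found: {self.outputs.transcript_db}")
        out_dir = Path(self.prefix).resolve().parent
        if not out_dir.is_dir():
            raise ConfigError(f"output directory does not exist: {out_dir}")


def _get_int(section: configparser.SectionProxy, key: str, default: int) -> int:
    if key not in section:
        return default
    try:
        return int(section[key])
    except ValueError:
        raise ConfigError(f"[{section.name}] {key} must be an integer, got {section[key]!r}") from None


def _get_bool(section: configparser.SectionProxy, key: str, default: bool) -> bool:
    if key not in section:
        return default
    try:
        return section.getboolean(key)
    except ValueError:
        raise ConfigError(f"[{section.name}] {key} must be a boolean, got {section[key]!r}") from None


def parse_config(
    ini_path: Optional[Union[str, Path]],
) -> Tuple[QualityConfig, FlagCriteria, OutputOptions]:
    """Parse an INI file into (QualityConfig, FlagCriteria, OutputOptions).

    ``ini_path=None`` (no --config given) returns all defaults and no flag
    criteria; an empty file does the same.
    """
    parser = configparser.ConfigParser()
    if ini_path is not None:
        ini_path = Path(ini_path)
        if not ini_path.exists():
            raise ConfigError(f"configuration file not found: {ini_path}")
        try:
            parser.read(ini_path)
        except configparser.Error as exc:
            raise ConfigError(f"unparseable INI file {ini_path}: {exc}") from None

    for section in parser.sections():
        if section not in ("quality", "flags", "outputs"):
            logger.warning("unknown configuration section [%s] ignored", section)

    quality_section = parser["quality"] if parser.has_section("quality") else parser["DEFAULT"]
    for key in quality_section:
        if key not in _QUALITY_KEYS:
            logger.warning("unknown key %r in [quality] ignored", key)
    quality = QualityConfig(
        bq_cutoff=_get_int(quality_section, "bq_cutoff", 10),
        mq_cutoff=_get_int(quality_section, "mq_cutoff", 20),
        qcov_poor_cutoff=_get_int(quality_section, "qcov_poor_cutoff", 15),
        count_duplicates=_get_bool(quality_section, "count_duplicates", True),
        direction_split=_get_bool(quality_section, "direction", False),
    )

    criteria = FlagCriteria()
    if parser.has_section("flags"):
        for key, raw in parser["flags"].items():
            key_upper = key.upper()
            if key_upper.endswith("_MIN"):
                metric, bound = key_upper[:-4], "minimum"
            elif key_upper.endswith("_MAX"):
                metric, bound = key_upper[:-4], "maximum"
            else:
                raise ConfigError(
                    f"[flags] key {key!r} must end in _min or _max (e.g. MINQCOV_min)"
                )
            try:
                threshold = float(raw)
            except ValueError:
                raise ConfigError(f"[flags] {key} must be numeric, got {raw!r}") from None
            try:
                criteria.add(metric, bound, threshold)
            except ValueError as exc:
                raise ConfigError(str(exc)) from None

    outputs = OutputOptions()
    if parser.has_section("outputs"):
        section = parser["outputs"]
        for key in section:
            if key not in _OUTPUT_KEYS:
                logger.warning("unknown key %r in [outputs] ignored", key)
        tx_db = section.get("transcript_db") or None
        outputs = OutputOptions(
            profiles=section.get("profiles", "all").lower(),
            poor=_get_bool(section, "poor", True),
            transcript_db=Path(tx_db) if tx_db else None,
        )

    return quality, criteria, outputs
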