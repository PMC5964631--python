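"""Region-level summary metrics and PASS/FLAG logic.

Each target region is reduced to seven summary metrics:

RC       total eligible mapped reads overlapping the region,
MEDCOV   median of the per-base COV values,
MINCOV   minimum COV,
MEDQCOV  median of QCOV,
MINQCOV  minimum QCOV,
MAXFLMQ  maximum FLMQ (undefined when FLMQ is undefined everywhere),
MAXFLBQ  maximum FLBQ (likewise),

and checked against user-declared criteria: a *minimum* bound fails when
the metric is below the threshold, a *maximum* bound fails when it exceeds
the threshold. An undefined (NaN) value never fails a maximum bound (no
evidence of low quality) but always fails a minimum bound (no evidence of
sufficient coverage — the conservative reading for clinical QC). A region
is FLAG iff at least one criterion fails, else PASS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .pileup import PerBaseProfile
from .regions import TargetRegion

logger = logging.getLogger(__name__)

__all__ = [
    "SUMMARY_METRICS",
    "RegionSummary",
    "FlagCriteria",
    "summarize_region",
    "apply_flags",
]

SUMMARY_METRICS = ("RC", "MEDCOV", "MINCOV", "MEDQCOV", "MINQCOV", "MAXFLMQ", "MAXFLBQ")

#: metrics for which each bound type is conventional
_MINIMUM_METRICS = frozenset({"RC", "MEDCOV", "MINCOV", "MEDQCOV", "MINQCOV"})
_MAXIMUM_METRICS = frozenset({"MAXFLMQ", "MAXFLBQ"})

PASS = "PASS"
FLAG = "FLAG"


@dataclass(frozen=True)
class RegionSummary:
    """Summary metrics for one region, plus its PASS/FLAG status.

    ``maxflmq``/``maxflbq`` are NaN when undefined at every position.
    ``status`` is None until :func:`apply_flags` has run.
    """

    region: TargetRegion
    rc: int
    medcov: float
    mincov: int
    medqcov: float
    minqcov: int
    maxflmq: float
    maxflbq: float
    status: Optional[str] = None
    failed_metrics: Tuple[str, ...] = ()
    forward: Optional["RegionSummary"] = field(default=None, repr=False)
    reverse: Optional["RegionSummary"] = field(default=None, repr=False)

    def metric(self, name: str) -> float:
        """Metric value by its conventional symbol (case-insensitive)."""
        try:
            return getattr(self, name.lower())
        except AttributeError:
            raise KeyError(f"unknown summary metric {name!r}") from None


class FlagCriteria:
    """Mapping metric symbol -> (bound type, threshold).

    Bound types are ``"minimum"`` and ``"maximum"``. Any Table-2-style
    summary metric may be constrained; a minimum bound on a fraction metric
    (or maximum on a coverage metric) is accepted but logged as unusual.
    """

    def __init__(self, criteria: Optional[Mapping[str, Tuple[str, float]]] = None):
        self._criteria: Dict[str, Tuple[str, float]] = {}
        for metric, (bound, threshold) in (criteria or {}).items():
            self.add(metric, bound, threshold)

    def add(self, metric: str, bound: str, threshold: float) -> None:
        metric = metric.upper()
        if metric not in SUMMARY_METRICS:
            raise ValueError(
                f"unknown summary metric {metric!r} in flag criteria; "
                f"expected one of {', '.join(SUMMARY_METRICS)}"
            )
        if bound not in ("minimum", "maximum"):
            raise ValueError(f"bound must be 'minimum' or 'maximum', got {bound!r}")
        conventional = (
            metric in _MINIMUM_METRICS if bound == "minimum" else metric in _MAXIMUM_METRICS
        )
        if not conventional:
            logger.warning("unusual flag criterion: %s bound on %s", bound, metric)
        self._criteria[metric] = (bound, float(threshold))

    def items(self):
        return self._criteria.items()

    def __len__(self) -> int:
        return len(self._criteria)

    def __bool__(self) -> bool:
        return bool(self._criteria)

    def __eq__(self, other) -> bool:
        return isinstance(other, FlagCriteria) and self._criteria == other._criteria

    def __repr__(self) -> str:
        return f"FlagCriteria({self._criteria!r})"


def summarize_region(profile: PerBaseProfile, rc: int) -> RegionSummary:
    """Reduce a per-base profile to region summary metrics (status unset).

    Medians, minima and maxima run over ALL positions of the region;
    MAXFLMQ/MAXFLBQ are NaN iff the fraction is undefined at every position.
    ``rc`` comes from the read-overlap count, not from the profile.
    """
    if len(profile) == 0:
        raise ValueError(f"empty profile for region {profile.region.name}")
    flmq_defined = ~np.isnan(profile.flmq)
    flbq_defined = ~np.isnan(profile.flbq)
    return RegionSummary(
        region=profile.region,
        rc=int(rc),
        medcov=float(np.median(profile.cov)),
        mincov=int(profile.cov.min()),
        medqcov=float(np.median(profile.qcov)),
        minqcov=int(profile.qcov.min()),
        maxflmq=float(profile.flmq[flmq_defined].max()) if flmq_defined.any() else math.nan,
        maxflbq=float(profile.flbq[flbq_defined].max()) if flbq_defined.any() else math.nan,
    )


def apply_flags(summary: RegionSummary, criteria: FlagCriteria) -> RegionSummary:
    """Evaluate flag criteria and return the summary with status set.

    Tightening any minimum threshold can only move regions PASS -> FLAG,
    never the reverse (and symmetrically for maximum bounds).
    """
    failed: List[str] = []
    for metric, (bound, threshold) in criteria.items():
        value = summary.metric(metric)
        undefined = isinstance(value, float) and math.isnan(value)
        if bound == "minimum":
            if undefined or value < threshold:
                failed.append(metric)
        else:  # maximum: undefined never fails (no evidence of low quality)
            if not undefined and value > threshold:
                failed.append(metric)
    return replace(
        summary,
        status=FLAG if failed else PASS,
        failed_metrics=tuple(failed),
    )
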