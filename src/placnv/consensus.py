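"""Per-sample consensus CNVs from parallel multi-algorithm call sets.

SNP-array CNV callers disagree substantially, so a call is only trusted when
at least two independent algorithms report the same event on the same sample.
Two same-type calls identify the same event when their reciprocal overlap is
at least 40% (configurable); calls are chained by single linkage, and every
connected component supported by the required number of distinct callers
becomes one consensus CNV whose interval is the union span of its members.

Calls from a confidence-reporting caller (a log Bayes Factor in the default
setup) can first be filtered with :func:`filter_by_confidence`; callers that
report no confidence are never filtered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._linkage import linkage_components
from .genome import GenomicInterval, reciprocal_overlap

__all__ = [
    "DUPLICATION",
    "DELETION",
    "CNV_TYPES",
    "CnvCall",
    "ConsensusCnv",
    "filter_by_confidence",
    "build_consensus",
]

DUPLICATION = "dup"
DELETION = "del"
CNV_TYPES = (DUPLICATION, DELETION)


@dataclass(frozen=True)
class CnvCall:
    """One raw CNV call from one algorithm on one sample."""

    sample_id: str
    caller_id: str
    interval: GenomicInterval
    cnv_type: str
    confidence: Optional[float] = None  # log Bayes Factor where the caller reports one

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(
                f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}"
            )


@dataclass(frozen=True)
class ConsensusCnv:
    """A per-sample CNV supported by >= 2 independent callers.

    ``interval`` is the union span of the member calls; ``intersect_interval``
    is the common core (``None`` when single-linkage chaining leaves no base
    shared by all members) and is reported for diagnostics only.
    """

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    supporting_callers: frozenset[str]
    members: tuple[CnvCall, ...]
    intersect_interval: Optional[GenomicInterval] = None

    @property
    def length_bp(self) -> int:
        return self.interval.length_bp

    @property
    def n_callers(self) -> int:
        return len(self.supporting_callers)


def filter_by_confidence(
    calls: Iterable[CnvCall], caller_id: str, min_conf: float = 5.0
) -> list[CnvCall]:
    """Drop calls from ``caller_id`` whose confidence is below ``min_conf``.

    The comparison is strict (< ``min_conf`` is excluded, == retained); calls
    from other callers, and calls without a confidence value, pass unchanged.
    Input order is preserved.
    """
    kept = []
    for call in calls:
        if (
            call.caller_id == caller_id
            and call.confidence is not None
            and call.confidence < min_conf
        ):
            continue
        kept.append(call)
    return kept


def build_consensus(
    calls: Sequence[CnvCall],
    sample_id: str,
    min_reciprocal: float = 0.4,
    min_callers: int = 2,
) -> list[ConsensusCnv]:
    """Merge one sample's parallel calls into consensus CNVs.

    Builds a graph over same-type calls with an edge wherever the reciprocal
    overlap is >= ``min_reciprocal`` (inclusive), takes connected components
    (single linkage), and keeps components supported by >= ``min_callers``
    distinct callers.  Components with fewer callers — in particular calls
    made by a single algorithm — are discarded.

    Returns consensus CNVs ordered by (chrom, start, end, type).
    """
    for call in calls:
        if call.sample_id != sample_id:
            raise ValueError(
                f"call from sample {call.sample_id!r} passed to consensus "
                f"building for sample {sample_id!r}"
            )
    out: list[ConsensusCnv] = []
    for cnv_type in CNV_TYPES:
        typed = [c for c in calls if c.cnv_type == cnv_type]
        for comp in linkage_components(
            typed, lambda c: c.interval, reciprocal_overlap, min_reciprocal
        ):
            callers = frozenset(c.caller_id for c in comp)
            if len(callers) < min_callers:
                continue
            chrom = comp[0].interval.chrom
            union = GenomicInterval(
                chrom,
                min(c.interval.start_bp for c in comp),
                max(c.interval.end_bp for c in comp),
            )
            core_start = max(c.interval.start_bp for c in comp)
            core_end = min(c.interval.end_bp for c in comp)
            core = (
                GenomicInterval(chrom, core_start, core_end)
                if core_end > core_start
                else None
            )
            out.append(
                ConsensusCnv(
                    sample_id=sample_id,
                    interval=union,
                    cnv_type=cnv_type,
                    supporting_callers=callers,
                    members=tuple(
                        sorted(comp, key=lambda c: (c.interval, c.caller_id))
                    ),
                    intersect_interval=core,
                )
            )
    out.sort(key=lambda c: (c.interval, c.cnv_type))
    return out
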