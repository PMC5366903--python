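"""Cross-sample CNV regions (CNVRs), sharing structure and inheritance.

A CNVR groups same-type consensus CNVs from any number of samples when they
overlap with at least 40% coverage of *at least one* of the two events (the
asymmetric criterion: a small CNV nested in a large one always clusters).
Clustering is single linkage over pairwise edges, and every connected
component — including singletons — is a region, so each consensus CNV belongs
to exactly one CNVR and per-group CNVR pools partition the call set.

Sharing between study groups is defined by co-membership in one CNVR: two
groups share a region when the same component contains consensus CNVs from
samples of both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from ._linkage import linkage_components
from .consensus import CNV_TYPES, ConsensusCnv
from .genome import GenomicInterval, max_fraction_overlap, reciprocal_overlap

__all__ = [
    "GROUPS",
    "TISSUES",
    "ROLES",
    "SampleMeta",
    "Cnvr",
    "SharingSummary",
    "build_cnvrs",
    "sharing_summary",
    "annotate_inheritance",
]

GROUPS = ("rpl_loss", "rpl_livebirth", "control_first_trimester", "control_term")
TISSUES = ("placenta", "blood")
ROLES = ("mother", "father", "placenta")


@dataclass(frozen=True)
class SampleMeta:
    """Study-design metadata for one sample."""

    sample_id: str
    group: str
    tissue: str
    role: str
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class Cnvr:
    """One CNV region: a single-linkage component of same-type consensus CNVs."""

    cnvr_id: str
    cnv_type: str
    span: GenomicInterval
    members: tuple[ConsensusCnv, ...]
    groups_present: frozenset[str] = field(default_factory=frozenset)

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset(m.sample_id for m in self.members)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def build_cnvrs(
    cnvs: Sequence[ConsensusCnv],
    min_max_fraction: float = 0.4,
    meta: Optional[Iterable[SampleMeta]] = None,
    count_singletons: bool = True,
) -> list[Cnvr]:
    """Cluster consensus CNVs (across samples) into CNV regions.

    Edges join same-type CNVs whose :func:`~placnv.genome.max_fraction_overlap`
    is >= ``min_max_fraction``; connected components become regions with a
    union span.  With ``count_singletons=False`` components with a single
    member CNV are dropped (the strict two-CNV reading of the region
    definition); the default keeps them, so regions partition the input.

    When ``meta`` is given, each region records the study groups of its
    member samples.
    """
    group_of = {m.sample_id: m.group for m in meta} if meta is not None else {}
    regions: list[Cnvr] = []
    components: list[list[ConsensusCnv]] = []
    for cnv_type in CNV_TYPES:
        typed = [c for c in cnvs if c.cnv_type == cnv_type]
        components.extend(
            linkage_components(
                typed, lambda c: c.interval, max_fraction_overlap, min_max_fraction
            )
        )
    components.sort(
        key=lambda comp: (
            min(c.interval for c in comp),
            comp[0].cnv_type,
        )
    )
    width = max(4, len(str(len(components))))
    for i, comp in enumerate(components, start=1):
        if not count_singletons and len(comp) < 2:
            continue
        chrom = comp[0].interval.chrom
        span = GenomicInterval(
            chrom,
            min(c.interval.start_bp for c in comp),
            max(c.interval.end_bp for c in comp),
        )
        regions.append(
            Cnvr(
                cnvr_id=f"CNVR_{i:0{width}d}",
                cnv_type=comp[0].cnv_type,
                span=span,
                members=tuple(sorted(comp, key=lambda c: (c.interval, c.sample_id))),
                groups_present=frozenset(
                    group_of[m.sample_id] for m in comp if m.sample_id in group_of
                ),
            )
        )
    return regions


@dataclass(frozen=True)
class SharingSummary:
    """CNVR sharing of one focal study group with a set of other groups."""

    focal_group: str
    pool_size: int  # CNVRs with >= 1 focal-group member
    n_focal_samples: int
    per_sample_rate: float  # pool_size / n_focal_samples
    shared: dict[str, int]  # other group -> co-membership count
    unique_count: int  # focal CNVRs with no member from any listed other group
    unique_fraction: float

    def shared_fraction(self, other_group: str) -> float:
        return self.shared[other_group] / self.pool_size if self.pool_size else 0.0


def sharing_summary(
    cnvrs: Sequence[Cnvr],
    meta: Sequence[SampleMeta],
    focal_group: str,
    other_groups: Sequence[str],
) -> SharingSummary:
    """Summarise how the focal group's CNVR pool is shared with other groups.

    The focal pool is every CNVR containing at least one member from a
    focal-group sample; a region is shared with another group when it also
    contains a member from that group, and unique when no listed other group
    contributes a member.
    """
    group_of = {m.sample_id: m.group for m in meta}
    focal_samples = [m for m in meta if m.group == focal_group]
    if not focal_samples:
        raise ValueError(f"no samples in focal group {focal_group!r}")

    pool = []
    for region in cnvrs:
        member_groups = {
            group_of[s] for s in region.sample_ids if s in group_of
        }
        if focal_group in member_groups:
            pool.append(member_groups)

    shared = {
        g: sum(1 for member_groups in pool if g in member_groups)
        for g in other_groups
    }
    # the focal group trivially co-occurs with itself in every pool region
    if focal_group in other_groups:
        shared[focal_group] = len(pool)
    unique = sum(
        1
        for member_groups in pool
        if not (member_groups - {focal_group}) & set(other_groups)
    )
    return SharingSummary(
        focal_group=focal_group,
        pool_size=len(pool),
        n_focal_samples=len(focal_samples),
        per_sample_rate=len(pool) / len(focal_samples),
        shared=shared,
        unique_count=unique,
        unique_fraction=unique / len(pool) if pool else 0.0,
    )


def annotate_inheritance(
    cnvr_member: ConsensusCnv,
    family: Sequence[SampleMeta],
    parental_cnvs: Sequence[ConsensusCnv],
    min_reciprocal: float = 0.4,
) -> str:
    """Label a placental consensus CNV as inherited or somatic.

    A parental match is a same-type consensus CNV, from a genotyped parent in
    the same family, whose reciprocal overlap with the placental CNV reaches
    ``min_reciprocal`` (the same threshold used for consensus merging).  With
    both parents genotyped the label is ``maternal``, ``paternal`` or
    ``somatic``; when only one parent is available a negative match can only
    yield the disjunctive label (``paternal_or_somatic`` when the father was
    not genotyped, and vice versa).  If the member carries no family link the
    label is ``unknown``.  A CNV matching both parents is labelled maternal
    (maternal precedence).
    """
    fam_by_role = {m.role: m for m in family if m.role in ("mother", "father")}
    if not fam_by_role:
        return "unknown"

    def parent_matches(parent: SampleMeta) -> bool:
        return any(
            c.cnv_type == cnvr_member.cnv_type
            and c.sample_id == parent.sample_id
            and reciprocal_overlap(c.interval, cnvr_member.interval) >= min_reciprocal
            for c in parental_cnvs
        )

    mother = fam_by_role.get("mother")
    father = fam_by_role.get("father")
    if mother is not None and parent_matches(mother):
        return "maternal"
    if father is not None and parent_matches(father):
        return "paternal"
    if mother is not None and father is not None:
        return "somatic"
    if mother is not None:  # father not genotyped, mother negative
        return "paternal_or_somatic"
    return "maternal_or_somatic"
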