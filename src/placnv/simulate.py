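"""Synthetic cohorts: genomes, group-structured CNVs, imperfect callers and
expression matrices.

The generator emulates the study design the analysis expects: placental
samples in four groups (pregnancy-loss, loss couples reaching a live birth,
first-trimester and term controls) with family-linked parental blood
samples, group-specific mean CNV burdens and duplication fractions, a pool
of polymorphic loci shared across groups, three imperfect callers (one of
which reports a log-Bayes-Factor-style confidence), and a count/FPKM
expression matrix with optional dosage effects and an elevated baseline for
deletion-prone genes.

Randomness comes from one global seed; the cohort, caller, gene and
expression stages each draw from their own spawned substream (in that
order), so each stage is reproducible independently of the others.

Within one sample, same-type true CNVs are placed non-overlapping
(rejection sampling).  Real per-sample call sets have the same property,
and it makes noiseless caller emulation round-trip exactly through
consensus merging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cnvr import SampleMeta
from .consensus import DELETION, DUPLICATION, CnvCall
from .expression import ExpressionMatrix, GeneAnnot
from .genome import ChromInfo, GenomicInterval

__all__ = [
    "CallerConfig",
    "GroupConfig",
    "ExpressionConfig",
    "SimConfig",
    "TrueCnv",
    "TruthSet",
    "default_config",
    "default_chromosomes",
    "generate_cohort",
    "emulate_callers",
    "generate_genes",
    "generate_expression",
    "truth_carriers",
]


@dataclass(frozen=True)
class CallerConfig:
    """Behaviour of one emulated CNV-calling algorithm."""

    caller_id: str
    detection_prob: float = 0.85
    jitter_sd_bp: float = 2000.0
    fp_rate: float = 1.0  # false-positive calls per genome (Poisson mean)
    reports_confidence: bool = False
    conf_mean: float = 15.0  # confidence for true calls (log Bayes Factor scale)
    conf_sd: float = 6.0
    fp_conf_mean: float = 8.0  # false positives score systematically lower
    fp_conf_sd: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.jitter_sd_bp < 0 or self.fp_rate < 0:
            raise ValueError("jitter_sd_bp and fp_rate must be >= 0")


@dataclass(frozen=True)
class GroupConfig:
    """Study-design parameters of one sample group."""

    name: str
    n_placentas: int
    parents: str = "none"  # "trio" | "duo" (mother only) | "none"
    father_prob: float = 1.0  # P(father genotyped) within a trio family
    mean_cnvs_placenta: float = 10.0
    mean_cnvs_parent: float = 9.0
    dup_fraction_placenta: float = 0.4
    dup_fraction_parent: float = 0.25
    shared_prob: float = 0.3  # P(a CNV is drawn from the polymorphic pool)
    inherit_prob: float = 0.2  # P(placenta inherits each parental CNV)

    def __post_init__(self) -> None:
        if self.parents not in ("trio", "duo", "none"):
            raise ValueError(f"unknown parent scheme {self.parents!r}")
        for p in (self.father_prob, self.shared_prob, self.inherit_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionConfig:
    """Parameters of the simulated expression matrix."""

    n_genes: int = 2000
    gene_length_median_bp: float = 20_000.0
    gene_length_sigma: float = 0.8
    baseline_median: float = 100.0  # expected raw count of a typical gene
    baseline_sigma: float = 1.2  # log-normal sd of per-gene baselines
    del_prone_fold: float = 3.0  # baseline multiplier for deletion-prone genes
    dosage_effect: bool = True  # 0.5x per deletion, 1.5x per duplication
    dispersion: float = 0.1  # negative-binomial dispersion (1/size)
    library_size_sigma: float = 0.15  # log-normal spread of per-sample depth


def default_chromosomes() -> list[ChromInfo]:
    """A four-autosome toy build with metacentric and acrocentric examples."""
    return [
        ChromInfo("1", 150_000_000, 60_000_000),
        ChromInfo("2", 120_000_000, 50_000_000),
        ChromInfo("3", 80_000_000, 30_000_000),
        ChromInfo("4", 50_000_000, 2_000_000),  # acrocentric: window clips at 0
    ]


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic cohort (one seed -> one cohort)."""

    seed: int
    chromosomes: tuple[ChromInfo, ...]
    groups: tuple[GroupConfig, ...]
    callers: tuple[CallerConfig, ...]
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    cnv_length_median_bp: float = 60_000.0
    cnv_length_sigma: float = 1.0
    min_cnv_length_bp: int = 1_000
    n_shared_loci: int = 40

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        shortest = min(c.length_bp for c in self.chromosomes)
        if self.min_cnv_length_bp > shortest:
            raise ValueError("minimum CNV length exceeds the shortest chromosome")


def default_config(seed: int) -> SimConfig:
    """Cohort configuration emulating the study design.

    Group sizes (10/3/9/8 placentas, trio/duo parent schemes), placental mean
    CNV counts (9/7/15/31), duplication fractions and parental burdens follow
    the cohort the analysis was designed for.
    """
    groups = (
        GroupConfig(
            name="rpl_loss",
            n_placentas=10,
            parents="trio",
            father_prob=0.56,  # fathers were genotyped for ~9 of 16 families
            mean_cnvs_placenta=9.0,
            mean_cnvs_parent=8.8,
            dup_fraction_placenta=0.30,
            dup_fraction_parent=0.25,
        ),
        GroupConfig(
            name="rpl_livebirth",
            n_placentas=3,
            parents="trio",
            mean_cnvs_placenta=7.0,
            mean_cnvs_parent=8.8,
            dup_fraction_placenta=0.43,
            dup_fraction_parent=0.25,
        ),
        GroupConfig(
            name="control_first_trimester",
            n_placentas=9,
            parents="duo",
            mean_cnvs_placenta=15.0,
            mean_cnvs_parent=9.1,
            dup_fraction_placenta=0.53,
            dup_fraction_parent=0.25,
        ),
        GroupConfig(
            name="control_term",
            n_placentas=8,
            parents="trio",
            mean_cnvs_placenta=31.0,
            mean_cnvs_parent=9.1,
            dup_fraction_placenta=0.80,
            dup_fraction_parent=0.25,
        ),
    )
    callers = (
        CallerConfig("caller_A"),
        CallerConfig("caller_B", jitter_sd_bp=3000.0, detection_prob=0.8),
        CallerConfig("caller_C", reports_confidence=True, detection_prob=0.9),
    )
    return SimConfig(
        seed=seed,
        chromosomes=tuple(default_chromosomes()),
        groups=groups,
        callers=callers,
    )


@dataclass(frozen=True)
class TrueCnv:
    """One simulated ground-truth CNV in one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str
    origin: str  # "pool" | "private"
    pool_locus: Optional[int] = None
    inherited_from: Optional[str] = None  # "mother" | "father" | None (somatic/own)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of a simulated cohort."""

    cnvs: tuple[TrueCnv, ...]

    def for_sample(self, sample_id: str) -> list[TrueCnv]:
        return [c for c in self.cnvs if c.sample_id == sample_id]

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cnvs:
            seen.setdefault(c.sample_id, None)
        return list(seen)


def _streams(config: SimConfig) -> list[np.random.SeedSequence]:
    # fixed stage order: cohort, callers, genes, expression
    return np.random.SeedSequence(config.seed).spawn(4)


def _draw_interval(
    rng: np.random.Generator,
    config: SimConfig,
    chrom_weights: np.ndarray,
) -> GenomicInterval:
    chroms = config.chromosomes
    ci = chroms[rng.choice(len(chroms), p=chrom_weights)]
    length = int(
        round(
            rng.lognormal(
                math.log(config.cnv_length_median_bp), config.cnv_length_sigma
            )
        )
    )
    length = max(config.min_cnv_length_bp, min(length, ci.length_bp))
    start = int(rng.integers(0, ci.length_bp - length + 1))
    return GenomicInterval(ci.name, start, start + length)


def _overlaps_same_type(
    iv: GenomicInterval, cnv_type: str, existing: Sequence[TrueCnv]
) -> bool:
    return any(
        c.cnv_type == cnv_type
        and c.interval.chrom == iv.chrom
        and c.interval.start_bp < iv.end_bp
        and iv.start_bp < c.interval.end_bp
        for c in existing
    )


class Cohort(NamedTuple):
    truth: TruthSet
    meta: list[SampleMeta]
    chroms: list[ChromInfo]


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate ground-truth CNVs, sample metadata and the toy genome build.

    Per sample the CNV count is Poisson with the group mean; each event is
    drawn from the shared polymorphic pool (probability ``shared_prob``) or
    placed privately (length log-normal, position uniform, type by the group
    duplication fraction).  Placentas in families first inherit each
    parental CNV with probability ``inherit_prob`` and then add somatic
    events, with the somatic Poisson mean lowered by the expected inherited
    count so the group mean is preserved.
    """
    rng = np.random.default_rng(_streams(config)[0])
    chrom_weights = np.array([c.length_bp for c in config.chromosomes], dtype=float)
    chrom_weights /= chrom_weights.sum()

    # polymorphic pool, shared by all groups
    pool: list[tuple[GenomicInterval, str]] = []
    for _ in range(config.n_shared_loci):
        iv = _draw_interval(rng, config, chrom_weights)
        pool.append((iv, DUPLICATION if rng.random() < 0.5 else DELETION))

    def draw_cnv(
        sample_id: str, group: GroupConfig, dup_fraction: float, existing: list[TrueCnv]
    ) -> Optional[TrueCnv]:
        for _ in range(100):
            if pool and rng.random() < group.shared_prob:
                locus = int(rng.integers(0, len(pool)))
                iv, cnv_type = pool[locus]
                cand = TrueCnv(sample_id, iv, cnv_type, "pool", pool_locus=locus)
            else:
                iv = _draw_interval(rng, config, chrom_weights)
                cnv_type = DUPLICATION if rng.random() < dup_fraction else DELETION
                cand = TrueCnv(sample_id, iv, cnv_type, "private")
            if not _overlaps_same_type(cand.interval, cand.cnv_type, existing):
                return cand
        return None  # genome saturated for this type; skip the event

    meta: list[SampleMeta] = []
    cnvs: list[TrueCnv] = []
    for group in config.groups:
        for i in range(1, group.n_placentas + 1):
            family_id = f"{group.name}_fam{i:02d}"
            parents: list[tuple[str, str]] = []  # (sample_id, role)
            if group.parents in ("trio", "duo"):
                parents.append((f"{family_id}_M", "mother"))
            if group.parents == "trio" and rng.random() < group.father_prob:
                parents.append((f"{family_id}_F", "father"))

            parent_cnvs: list[TrueCnv] = []
            for sample_id, role in parents:
                meta.append(
                    SampleMeta(sample_id, group.name, "blood", role, family_id)
                )
                own: list[TrueCnv] = []
                for _ in range(rng.poisson(group.mean_cnvs_parent)):
                    c = draw_cnv(sample_id, group, group.dup_fraction_parent, own)
                    if c is not None:
                        own.append(c)
                parent_cnvs.extend(own)
                cnvs.extend(own)

            placenta_id = f"{family_id}_P"
            meta.append(
                SampleMeta(placenta_id, group.name, "placenta", "placenta", family_id)
            )
            placental: list[TrueCnv] = []
            role_of = dict(parents)
            for pc in parent_cnvs:
                if rng.random() < group.inherit_prob:
                    cand = TrueCnv(
                        placenta_id,
                        pc.interval,
                        pc.cnv_type,
                        pc.origin,
                        pool_locus=pc.pool_locus,
                        inherited_from=role_of[pc.sample_id],
                    )
                    if not _overlaps_same_type(
                        cand.interval, cand.cnv_type, placental
                    ):
                        placental.append(cand)
            somatic_mean = max(
                0.0,
                group.mean_cnvs_placenta - group.inherit_prob * len(parent_cnvs),
            )
            for _ in range(rng.poisson(somatic_mean)):
                c = draw_cnv(
                    placenta_id, group, group.dup_fraction_placenta, placental
                )
                if c is not None:
                    placental.append(c)
            cnvs.extend(placental)

    return Cohort(TruthSet(tuple(cnvs)), meta, list(config.chromosomes))


def emulate_callers(truth: TruthSet, config: SimConfig) -> list[CnvCall]:
    """Pass the true CNVs through the configured imperfect callers.

    Every caller independently detects each true CNV with its detection
    probability, jitters both breakpoints with rounded Gaussian noise
    (clipped to the chromosome, minimum length re-enforced), and adds
    Poisson false positives at random loci.  The confidence-reporting caller
    attaches a confidence score to every call it makes.
    """
    rng = np.random.default_rng(_streams(config)[1])
    chrom_by_name = {c.name: c for c in config.chromosomes}
    chrom_weights = np.array([c.length_bp for c in config.chromosomes], dtype=float)
    chrom_weights /= chrom_weights.sum()

    def jitter(iv: GenomicInterval, sd: float) -> GenomicInterval:
        length_bp = chrom_by_name[iv.chrom].length_bp
        start = int(round(iv.start_bp + rng.normal(0.0, sd))) if sd > 0 else iv.start_bp
        end = int(round(iv.end_bp + rng.normal(0.0, sd))) if sd > 0 else iv.end_bp
        start = max(0, min(start, length_bp - config.min_cnv_length_bp))
        end = max(start + config.min_cnv_length_bp, min(end, length_bp))
        if end > length_bp:  # interval pinned at the chromosome end
            end = length_bp
            start = length_bp - config.min_cnv_length_bp
        return GenomicInterval(iv.chrom, start, end)

    calls: list[CnvCall] = []
    sample_ids = truth.sample_ids
    for sample_id in sample_ids:
        sample_cnvs = truth.for_sample(sample_id)
        for caller in config.callers:
            for cnv in sample_cnvs:
                if rng.random() >= caller.detection_prob:
                    continue
                conf = (
                    float(rng.normal(caller.conf_mean, caller.conf_sd))
                    if caller.reports_confidence
                    else None
                )
                calls.append(
                    CnvCall(
                        sample_id=sample_id,
                        caller_id=caller.caller_id,
                        interval=jitter(cnv.interval, caller.jitter_sd_bp),
                        cnv_type=cnv.cnv_type,
                        confidence=conf,
                    )
                )
            for _ in range(rng.poisson(caller.fp_rate)):
                iv = _draw_interval(rng, config, chrom_weights)
                conf = (
                    float(rng.normal(caller.fp_conf_mean, caller.fp_conf_sd))
                    if caller.reports_confidence
                    else None
                )
                calls.append(
                    CnvCall(
                        sample_id=sample_id,
                        caller_id=caller.caller_id,
                        interval=iv,
                        cnv_type=DUPLICATION if rng.random() < 0.5 else DELETION,
                        confidence=conf,
                    )
                )
    calls.sort(key=lambda c: (c.sample_id, c.caller_id, c.interval, c.cnv_type))
    return calls


def generate_genes(config: SimConfig) -> list[GeneAnnot]:
    """Place gene intervals on the simulated build (log-normal lengths)."""
    rng = np.random.default_rng(_streams(config)[2])
    expr = config.expression
    chrom_weights = np.array([c.length_bp for c in config.chromosomes], dtype=float)
    chrom_weights /= chrom_weights.sum()
    genes = []
    width = len(str(expr.n_genes))
    for i in range(1, expr.n_genes + 1):
        ci = config.chromosomes[rng.choice(len(config.chromosomes), p=chrom_weights)]
        length = int(
            round(
                rng.lognormal(
                    math.log(expr.gene_length_median_bp), expr.gene_length_sigma
                )
            )
        )
        length = max(200, min(length, ci.length_bp))
        start = int(rng.integers(0, ci.length_bp - length + 1))
        genes.append(
            GeneAnnot(f"G{i:0{width}d}", GenomicInterval(ci.name, start, start + length))
        )
    return genes


def truth_carriers(
    truth: TruthSet, genes: Sequence[GeneAnnot]
) -> dict[str, dict[str, set[str]]]:
    """Map gene_id -> {"del": carrier sample set, "dup": carrier sample set}
    from ground-truth CNV overlap (any overlap >= 1 bp)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for c in truth.cnvs:
        key = (c.interval.chrom, c.cnv_type)
        trees.setdefault(key, IntervalTree()).addi(
            c.interval.start_bp, c.interval.end_bp, c.sample_id
        )
    out: dict[str, dict[str, set[str]]] = {}
    for gene in genes:
        iv = gene.interval
        entry = {}
        for cnv_type in (DELETION, DUPLICATION):
            tree = trees.get((iv.chrom, cnv_type))
            hits = tree.overlap(iv.start_bp, iv.end_bp) if tree else set()
            entry[cnv_type] = {h.data for h in hits}
        out[gene.gene_id] = entry
    return out


class SimulatedExpression(NamedTuple):
    raw_counts: ExpressionMatrix
    fpkm: ExpressionMatrix
    del_prone_genes: set[str]


def generate_expression(
    truth: TruthSet,
    genes: Sequence[GeneAnnot],
    config: SimConfig,
    samples: Optional[Sequence[str]] = None,
) -> SimulatedExpression:
    """Simulate raw counts and FPKM for ``samples`` (default: all in truth).

    Per-gene baselines are log-normal; genes overlapping deletions (and no
    duplication) in the cohort truth are "deletion-prone" and get the
    configured baseline fold.  Counts are negative-binomial around baseline
    x dosage x library size; the FPKM layer is derived from counts, gene
    lengths and per-sample totals.
    """
    rng = np.random.default_rng(_streams(config)[3])
    expr = config.expression
    if samples is None:
        samples = truth.sample_ids
    samples = list(samples)
    carriers = truth_carriers(truth, genes)

    gene_ids = [g.gene_id for g in genes]
    lengths_kb = np.array([g.interval.length_bp / 1e3 for g in genes])
    baselines = rng.lognormal(
        math.log(expr.baseline_median), expr.baseline_sigma, size=len(genes)
    )
    del_prone = {
        g.gene_id
        for g in genes
        if carriers[g.gene_id][DELETION] and not carriers[g.gene_id][DUPLICATION]
    }
    for i, g in enumerate(genes):
        if g.gene_id in del_prone:
            baselines[i] *= expr.del_prone_fold

    lib = np.exp(rng.normal(0.0, expr.library_size_sigma, size=len(samples)))
    dosage = np.ones((len(genes), len(samples)))
    if expr.dosage_effect:
        sample_pos = {s: j for j, s in enumerate(samples)}
        for i, g in enumerate(genes):
            for s in carriers[g.gene_id][DELETION]:
                if s in sample_pos:
                    dosage[i, sample_pos[s]] *= 0.5
            for s in carriers[g.gene_id][DUPLICATION]:
                if s in sample_pos:
                    dosage[i, sample_pos[s]] *= 1.5

    mu = baselines[:, None] * dosage * lib[None, :]
    size = 1.0 / expr.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    index = pd.Index(gene_ids, name="gene_id")
    raw = ExpressionMatrix(
        values=pd.DataFrame(counts, index=index, columns=samples),
        layer="raw_counts",
    )
    totals = counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    fpkm_values = counts / lengths_kb[:, None] / (totals[None, :] / 1e6)
    fpkm = ExpressionMatrix(
        values=pd.DataFrame(fpkm_values, index=index, columns=samples),
        layer="fpkm",
    )
    return SimulatedExpression(raw_counts=raw, fpkm=fpkm, del_prone_genes=del_prone)
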