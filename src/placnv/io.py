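"""Readers, writers, configuration and the end-to-end pipeline.

File dialects
-------------
* chromosome info TSV: ``chrom, length_bp, centromere_center_bp`` (header
  required, one row per autosome);
* raw CNV call TSV: ``sample_id, caller_id, chrom, start, end, type,
  confidence`` with **1-based inclusive** coordinates, ``type`` in
  ``{dup, del}`` and confidence optional (empty allowed);
* sample metadata TSV: ``sample_id, group, tissue, role, family_id``;
* gene BED: ``chrom, start, end, gene_id`` with **0-based half-open**
  coordinates (the BED standard);
* expression TSV: ``gene_id`` column plus one column per sample.

Internally everything is 0-based half-open; conversion happens on read and
write.  Records on sex chromosomes or the mitochondrion are dropped (with a
logged count) since only autosomal CNVs are analysed; any other unknown
chromosome is an error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .burden import (
    BurdenSummary,
    GroupComparison,
    LargeCnvProfile,
    compare_groups,
    fisher_exact_2x2,
    large_cnv_profile,
    summarize_burden,
)
from .cnvr import Cnvr, SampleMeta, SharingSummary, build_cnvrs, sharing_summary
from .consensus import (
    CNV_TYPES,
    CnvCall,
    ConsensusCnv,
    build_consensus,
    filter_by_confidence,
)
from .expression import (
    ExpressionMatrix,
    GeneAnnot,
    classify_genes,
    compare_median_expression,
    normalize_counts,
    zscore_carrier_compare,
)
from .genome import SEX_CHROM_NAMES, ChromInfo, GenomicInterval
from .simulate import TruthSet

logger = logging.getLogger("placnv")

__all__ = [
    "read_chrom_info",
    "read_sample_meta",
    "read_cnv_calls",
    "read_gene_bed",
    "read_expression",
    "write_chrom_info",
    "write_sample_meta",
    "write_cnv_calls",
    "write_gene_bed",
    "write_expression",
    "write_consensus",
    "write_cnvrs",
    "write_truth",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "write_cohort_inputs",
]


def _fail(path, line: int, msg: str):
    raise ValueError(f"{path}:{line}: {msg}")


def read_chrom_info(path) -> list[ChromInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "length_bp", "centromere_center_bp"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    chroms = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.chrom in seen:
            _fail(path, i, f"duplicate chromosome {row.chrom!r}")
        seen.add(row.chrom)
        chroms.append(
            ChromInfo(str(row.chrom), int(row.length_bp), int(row.centromere_center_bp))
        )
    return chroms


def write_chrom_info(path, chroms: Sequence[ChromInfo]) -> None:
    pd.DataFrame(
        [(c.name, c.length_bp, c.centromere_center_bp) for c in chroms],
        columns=["chrom", "length_bp", "centromere_center_bp"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    metas = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.sample_id in seen:
            _fail(path, i, f"duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        family = getattr(row, "family_id", None)
        if pd.isna(family):
            family = None
        try:
            metas.append(
                SampleMeta(row.sample_id, row.group, row.tissue, row.role, family)
            )
        except ValueError as e:
            _fail(path, i, str(e))
    return metas


def write_sample_meta(path, meta: Sequence[SampleMeta]) -> None:
    pd.DataFrame(
        [(m.sample_id, m.group, m.tissue, m.role, m.family_id or "") for m in meta],
        columns=["sample_id", "group", "tissue", "role", "family_id"],
    ).to_csv(path, sep="\t", index=False)


def read_cnv_calls(path, chroms: Sequence[ChromInfo]) -> list[CnvCall]:
    """Read a raw per-caller call table (1-based inclusive coordinates).

    Sex-chromosome/mitochondrial rows are dropped with a logged count;
    unknown autosome labels, bad coordinates and unknown CNV types raise
    with the offending ``file:line``.
    """
    known = {c.name: c for c in chroms}
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "sample_id": str, "caller_id": str},
        float_precision="round_trip",
    )
    calls = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        chrom = str(row.chrom)
        if chrom in SEX_CHROM_NAMES:
            n_dropped += 1
            continue
        if chrom not in known:
            _fail(path, i, f"unknown chromosome {chrom!r}")
        start1, end1 = int(row.start), int(row.end)
        if start1 < 1 or end1 < start1:
            _fail(path, i, f"invalid 1-based inclusive span {start1}-{end1}")
        if end1 > known[chrom].length_bp:
            _fail(path, i, f"end {end1} exceeds length of chromosome {chrom}")
        if row.type not in CNV_TYPES:
            _fail(path, i, f"unknown CNV type {row.type!r}")
        conf = getattr(row, "confidence", None)
        conf = None if conf is None or pd.isna(conf) else float(conf)
        calls.append(
            CnvCall(
                sample_id=row.sample_id,
                caller_id=row.caller_id,
                interval=GenomicInterval(chrom, start1 - 1, end1),
                cnv_type=row.type,
                confidence=conf,
            )
        )
    if n_dropped:
        logger.info("read_cnv_calls: dropped %d non-autosomal records", n_dropped)
    return calls


def write_cnv_calls(path, calls: Sequence[CnvCall]) -> None:
    pd.DataFrame(
        [
            (
                c.sample_id,
                c.caller_id,
                c.interval.chrom,
                c.interval.start_bp + 1,
                c.interval.end_bp,
                c.cnv_type,
                "" if c.confidence is None else c.confidence,
            )
            for c in calls
        ],
        columns=["sample_id", "caller_id", "chrom", "start", "end", "type", "confidence"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_bed(path, chroms: Sequence[ChromInfo]) -> list[GeneAnnot]:
    """Read gene intervals from BED (0-based half-open, no header)."""
    known = {c.name: c for c in chroms}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    genes = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        chrom = str(row.chrom)
        if chrom in SEX_CHROM_NAMES:
            n_dropped += 1
            continue
        if chrom not in known:
            _fail(path, i, f"unknown chromosome {chrom!r}")
        if int(row.end) <= int(row.start):
            _fail(path, i, f"invalid BED span {row.start}-{row.end}")
        genes.append(
            GeneAnnot(row.gene_id, GenomicInterval(chrom, int(row.start), int(row.end)))
        )
    if n_dropped:
        logger.info("read_gene_bed: dropped %d non-autosomal genes", n_dropped)
    return genes


def write_gene_bed(path, genes: Sequence[GeneAnnot]) -> None:
    pd.DataFrame(
        [(g.interval.chrom, g.interval.start_bp, g.interval.end_bp, g.gene_id) for g in genes]
    ).to_csv(path, sep="\t", index=False, header=False)


def read_expression(path, layer: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
    return ExpressionMatrix(values=df, layer=layer)


def write_expression(path, matrix: ExpressionMatrix) -> None:
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t")


def write_consensus(path, cnvs: Sequence[ConsensusCnv]) -> None:
    pd.DataFrame(
        [
            (
                c.sample_id,
                c.interval.chrom,
                c.interval.start_bp + 1,
                c.interval.end_bp,
                c.cnv_type,
                c.length_bp,
                c.n_callers,
                ",".join(sorted(c.supporting_callers)),
            )
            for c in cnvs
        ],
        columns=["sample_id", "chrom", "start", "end", "type", "length_bp", "n_callers", "callers"],
    ).to_csv(path, sep="\t", index=False)


def write_cnvrs(path, cnvrs: Sequence[Cnvr]) -> None:
    pd.DataFrame(
        [
            (
                r.cnvr_id,
                r.span.chrom,
                r.span.start_bp + 1,
                r.span.end_bp,
                r.cnv_type,
                len(r.members),
                r.n_samples,
                ",".join(sorted(r.groups_present)),
                ",".join(sorted(r.sample_ids)),
            )
            for r in cnvrs
        ],
        columns=["cnvr_id", "chrom", "start", "end", "type", "n_members", "n_samples", "groups", "sample_ids"],
    ).to_csv(path, sep="\t", index=False)


def write_truth(path, truth: TruthSet) -> None:
    pd.DataFrame(
        [
            (
                c.sample_id,
                c.interval.chrom,
                c.interval.start_bp + 1,
                c.interval.end_bp,
                c.cnv_type,
                c.origin,
                "" if c.pool_locus is None else c.pool_locus,
                c.inherited_from or "",
            )
            for c in truth.cnvs
        ],
        columns=["sample_id", "chrom", "start", "end", "type", "origin", "pool_locus", "inherited_from"],
    ).to_csv(path, sep="\t", index=False)


def write_cohort_inputs(
    out_dir,
    truth: TruthSet,
    meta: Sequence[SampleMeta],
    chroms: Sequence[ChromInfo],
    calls: Sequence[CnvCall],
    genes: Optional[Sequence[GeneAnnot]] = None,
    raw_counts: Optional[ExpressionMatrix] = None,
    fpkm: Optional[ExpressionMatrix] = None,
) -> dict[str, Path]:
    """Write a simulated cohort as the exact input files the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": out / "calls.tsv",
        "chrom_info": out / "chrom_info.tsv",
        "meta": out / "sample_meta.tsv",
        "truth": out / "truth.tsv",
    }
    write_cnv_calls(paths["calls"], calls)
    write_chrom_info(paths["chrom_info"], chroms)
    write_sample_meta(paths["meta"], meta)
    write_truth(paths["truth"], truth)
    if genes is not None:
        paths["genes"] = out / "genes.bed"
        write_gene_bed(paths["genes"], genes)
    if raw_counts is not None:
        paths["counts"] = out / "expression_counts.tsv"
        write_expression(paths["counts"], raw_counts)
    if fpkm is not None:
        paths["fpkm"] = out / "expression_fpkm.tsv"
        write_expression(paths["fpkm"], fpkm)
    return paths


@dataclass
class PipelineConfig:
    """Paths, thresholds and group definitions for one pipeline run.

    All numeric thresholds default to the analysis constants: 40% reciprocal
    overlap for consensus, 40% coverage-of-one for regions, >= 2 supporting
    callers, confidence floor 5 (applied to ``confidence_caller`` only),
    large-CNV threshold 300 kb, 5% context windows and a 0.05 normality
    gate.
    """

    calls_path: str
    chrom_info_path: str
    meta_path: str
    out_dir: str
    genes_path: Optional[str] = None
    expression_counts_path: Optional[str] = None
    expression_fpkm_path: Optional[str] = None
    min_reciprocal: float = 0.4
    cnvr_min_max_fraction: float = 0.4
    min_callers: int = 2
    confidence_caller: Optional[str] = None
    min_confidence: float = 5.0
    large_cnv_bp: int = 300_000
    window_frac: float = 0.05
    alpha_normality: float = 0.05
    count_singletons: bool = True
    parental_case_groups: tuple[str, ...] = ("rpl_loss", "rpl_livebirth")
    parental_control_groups: tuple[str, ...] = (
        "control_first_trimester",
        "control_term",
    )
    seed: Optional[int] = None  # provenance only

    def __post_init__(self) -> None:
        for name in ("min_reciprocal", "cnvr_min_max_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.window_frac < 0.5:
            raise ValueError("window_frac must be in (0, 0.5)")
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("parental_case_groups", "parental_control_groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["parental_case_groups"] = list(self.parental_case_groups)
        d["parental_control_groups"] = list(self.parental_control_groups)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one pipeline run computed, JSON-serialisable."""

    provenance: dict
    stage_counts: dict
    burden: list[BurdenSummary]
    group_comparisons: list[GroupComparison]
    sharing_placenta: list[SharingSummary]
    sharing_parental: list[SharingSummary]
    sharing_fisher: dict
    large_cnv_profiles: list[LargeCnvProfile]
    expression: Optional[dict] = None

    def to_dict(self) -> dict:
        def comp(c: GroupComparison) -> dict:
            d = asdict(c)
            d["range_a"], d["range_b"] = list(c.range_a), list(c.range_b)
            return d

        def share(s: SharingSummary) -> dict:
            return {
                "focal_group": s.focal_group,
                "pool_size": s.pool_size,
                "n_focal_samples": s.n_focal_samples,
                "per_sample_rate": s.per_sample_rate,
                "shared": dict(s.shared),
                "unique_count": s.unique_count,
                "unique_fraction": s.unique_fraction,
            }

        return {
            "provenance": self.provenance,
            "stage_counts": self.stage_counts,
            "burden": [asdict(b) for b in self.burden],
            "group_comparisons": [comp(c) for c in self.group_comparisons],
            "sharing_placenta": [share(s) for s in self.sharing_placenta],
            "sharing_parental": [share(s) for s in self.sharing_parental],
            "sharing_fisher": self.sharing_fisher,
            "large_cnv_profiles": [asdict(p) for p in self.large_cnv_profiles],
            "expression": self.expression,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _audit(report: RunReport) -> None:
    # every derived percentage must equal recomputation from its own counts
    for p in report.large_cnv_profiles:
        if p.n_all:
            assert abs(p.percent_large - 100.0 * p.n_large / p.n_all) < 1e-9
        assert abs(p.rate_all - p.n_all / p.n_samples) < 1e-9
    for s in report.sharing_placenta + report.sharing_parental:
        assert 0 <= s.unique_count <= s.pool_size
        for count in s.shared.values():
            assert 0 <= count <= s.pool_size


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute filter -> consensus -> CNVR -> burden -> regions -> sharing ->
    (optional) expression and write every table under ``config.out_dir``.

    The run is deterministic for fixed inputs; a stage failure aborts with
    the stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    stage = "read_inputs"
    try:
        chroms = read_chrom_info(config.chrom_info_path)
        meta = read_sample_meta(config.meta_path)
        calls = read_cnv_calls(config.calls_path, chroms)
        counts["raw_calls"] = len(calls)

        stage = "confidence_filter"
        if config.confidence_caller is not None:
            calls = filter_by_confidence(
                calls, config.confidence_caller, config.min_confidence
            )
        counts["filtered_calls"] = len(calls)

        stage = "consensus"
        consensus: list[ConsensusCnv] = []
        calls_by_sample: dict[str, list[CnvCall]] = {}
        for call in calls:
            calls_by_sample.setdefault(call.sample_id, []).append(call)
        for m in meta:
            consensus.extend(
                build_consensus(
                    calls_by_sample.get(m.sample_id, []),
                    m.sample_id,
                    config.min_reciprocal,
                    config.min_callers,
                )
            )
        counts["consensus_cnvs"] = len(consensus)
        write_consensus(out / "consensus.tsv", consensus)

        stage = "cnvr"
        tissue_of = {m.sample_id: m.tissue for m in meta}
        placental = [c for c in consensus if tissue_of[c.sample_id] == "placenta"]
        parental = [c for c in consensus if tissue_of[c.sample_id] == "blood"]
        cnvrs_placenta = build_cnvrs(
            placental, config.cnvr_min_max_fraction, meta, config.count_singletons
        )
        cnvrs_parental = build_cnvrs(
            parental, config.cnvr_min_max_fraction, meta, config.count_singletons
        )
        counts["cnvrs_placenta"] = len(cnvrs_placenta)
        counts["cnvrs_parental"] = len(cnvrs_parental)
        write_cnvrs(out / "cnvr_placenta.tsv", cnvrs_placenta)
        write_cnvrs(out / "cnvr_parental.tsv", cnvrs_parental)

        stage = "burden"
        by_sample: dict[str, list[ConsensusCnv]] = {}
        for c in consensus:
            by_sample.setdefault(c.sample_id, []).append(c)
        burden = [
            summarize_burden(by_sample.get(m.sample_id, []), m.sample_id) for m in meta
        ]
        pd.DataFrame([asdict(b) for b in burden]).to_csv(
            out / "burden.tsv", sep="\t", index=False
        )

        stage = "group_comparisons"
        comparisons: list[GroupComparison] = []
        group_of = {m.sample_id: m.group for m in meta}
        placental_groups = [
            g
            for g in dict.fromkeys(m.group for m in meta)
            if any(m.group == g and m.tissue == "placenta" for m in meta)
        ]

        def burden_values(groups: Sequence[str], tissue: str, metric: str) -> list[float]:
            wanted = {
                m.sample_id
                for m in meta
                if m.group in groups and m.tissue == tissue
            }
            return [getattr(b, metric) for b in burden if b.sample_id in wanted]

        for metric in ("n_all", "n_dup", "n_del", "span_all_mb"):
            for i, ga in enumerate(placental_groups):
                for gb in placental_groups[i + 1 :]:
                    va = burden_values([ga], "placenta", metric)
                    vb = burden_values([gb], "placenta", metric)
                    if len(va) >= 2 and len(vb) >= 2:
                        comparisons.append(
                            compare_groups(
                                va, vb, config.alpha_normality, metric, ga, gb
                            )
                        )
            case_vals = burden_values(config.parental_case_groups, "blood", metric)
            ctrl_vals = burden_values(config.parental_control_groups, "blood", metric)
            if len(case_vals) >= 2 and len(ctrl_vals) >= 2:
                comparisons.append(
                    compare_groups(
                        case_vals,
                        ctrl_vals,
                        config.alpha_normality,
                        metric,
                        "parental_case",
                        "parental_control",
                    )
                )

        stage = "sharing"
        placenta_meta = [m for m in meta if m.tissue == "placenta"]
        blood_meta = [m for m in meta if m.tissue == "blood"]
        sharing_placenta = []
        for g in placental_groups:
            others = [x for x in placental_groups if x != g]
            sharing_placenta.append(
                sharing_summary(cnvrs_placenta, placenta_meta, g, others)
            )
        parental_groups = [
            g
            for g in dict.fromkeys(m.group for m in meta)
            if any(m.group == g and m.tissue == "blood" for m in meta)
        ]
        sharing_parental = []
        for g in parental_groups:
            others = [x for x in parental_groups if x != g]
            sharing_parental.append(
                sharing_summary(cnvrs_parental, blood_meta, g, others)
            )

        sharing_fisher: dict = {}
        focal = "control_first_trimester"
        summary = next(
            (s for s in sharing_placenta if s.focal_group == focal), None
        )
        if summary is not None and summary.pool_size > 0:
            a = summary.shared.get("control_term", 0)
            b = summary.shared.get("rpl_loss", 0)
            table = [
                [a, summary.pool_size - a],
                [b, summary.pool_size - b],
            ]
            sharing_fisher = {
                "focal_group": focal,
                "groups": ["control_term", "rpl_loss"],
                "table": table,
                "p_value": fisher_exact_2x2(table),
            }

        stage = "large_cnv_profile"
        profiles = []
        for label, groups in (
            ("parental_rpl", config.parental_case_groups),
            ("parental_control", config.parental_control_groups),
        ):
            if any(m.group in groups and m.tissue == "blood" for m in meta):
                profiles.append(
                    large_cnv_profile(
                        consensus,
                        meta,
                        chroms,
                        groups,
                        tissue="blood",
                        size_threshold_bp=config.large_cnv_bp,
                        window_frac=config.window_frac,
                        label=label,
                    )
                )
        if profiles:
            pd.DataFrame([asdict(p) for p in profiles]).to_csv(
                out / "large_cnv_profile.tsv", sep="\t", index=False
            )

        stage = "expression"
        expression_block = None
        if config.genes_path is not None and (
            config.expression_fpkm_path is not None
            or config.expression_counts_path is not None
        ):
            expression_block = _expression_stage(
                config, chroms, meta, placental, cnvrs_placenta, out
            )
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    report = RunReport(
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
        stage_counts=counts,
        burden=burden,
        group_comparisons=comparisons,
        sharing_placenta=sharing_placenta,
        sharing_parental=sharing_parental,
        sharing_fisher=sharing_fisher,
        large_cnv_profiles=profiles,
        expression=expression_block,
    )
    _audit(report)
    report.to_json(out / "report.json")
    return report


def _expression_stage(
    config: PipelineConfig,
    chroms: Sequence[ChromInfo],
    meta: Sequence[SampleMeta],
    placental_cnvs: Sequence[ConsensusCnv],
    cnvrs_placenta: Sequence[Cnvr],
    out: Path,
) -> dict:
    from collections import Counter

    from intervaltree import IntervalTree

    genes = read_gene_bed(config.genes_path, chroms)
    classes = classify_genes(genes, cnvrs_placenta)
    class_of = {c.gene_id: c.cnv_class for c in classes}
    class_counts = Counter(c.cnv_class for c in classes)
    pd.DataFrame(
        [(c.gene_id, c.cnv_class) for c in classes], columns=["gene_id", "cnv_class"]
    ).to_csv(out / "gene_classes.tsv", sep="\t", index=False)

    block: dict = {"gene_class_counts": dict(class_counts)}

    if config.expression_fpkm_path is not None:
        fpkm = read_expression(config.expression_fpkm_path, "fpkm")
        medians = fpkm.gene_medians()
        by_class: dict[str, list[float]] = {}
        for gene_id, med in medians.items():
            if gene_id in class_of:
                by_class.setdefault(class_of[gene_id], []).append(float(med))
        comparisons = {}
        non_cnv = by_class.get("non_cnv", [])
        cnv_all = (
            by_class.get("del_only", [])
            + by_class.get("dup_only", [])
            + by_class.get("both", [])
        )
        for name, vals in (
            ("cnv_vs_non_cnv", cnv_all),
            ("del_only_vs_non_cnv", by_class.get("del_only", [])),
            ("dup_only_vs_non_cnv", by_class.get("dup_only", [])),
        ):
            if vals and non_cnv:
                r = compare_median_expression(vals, non_cnv)
                comparisons[name] = {
                    "median_cnv_class": r.median_a,
                    "median_non_cnv": r.median_b,
                    "fold": r.fold,
                    "p_value": r.p_value,
                }
        block["median_fpkm_comparisons"] = comparisons

    if config.expression_counts_path is not None:
        raw = read_expression(config.expression_counts_path, "raw_counts")
        normalized = normalize_counts(raw)
        # carrier map from placental consensus CNVs overlapping each gene
        trees: dict[tuple[str, str], IntervalTree] = {}
        for c in placental_cnvs:
            key = (c.interval.chrom, c.cnv_type)
            trees.setdefault(key, IntervalTree()).addi(
                c.interval.start_bp, c.interval.end_bp, c.sample_id
            )
        matrix_samples = set(normalized.sample_ids)
        zstats = {"del": [], "dup": []}
        skipped: Counter = Counter()
        for gene in genes:
            if class_of.get(gene.gene_id) == "non_cnv":
                continue
            if gene.gene_id not in normalized.gene_ids:
                continue
            iv = gene.interval
            carrier_sets = {}
            for type_key, cnv_type in (("del", "del"), ("dup", "dup")):
                tree = trees.get((iv.chrom, cnv_type))
                hits = tree.overlap(iv.start_bp, iv.end_bp) if tree else set()
                carrier_sets[type_key] = {h.data for h in hits} & matrix_samples
            no_cnv = matrix_samples - carrier_sets["del"] - carrier_sets["dup"]
            for type_key in ("del", "dup"):
                carriers = carrier_sets[type_key]
                res = zscore_carrier_compare(normalized, gene.gene_id, carriers, no_cnv)
                if res.skip_reason is not None:
                    skipped[f"{type_key}:{res.skip_reason}"] += 1
                else:
                    zstats[type_key].append(
                        (gene.gene_id, res.carrier_mean_z, res.p_value)
                    )
        block["zscore_carrier"] = {
            type_key: {
                "n_genes_tested": len(rows),
                "n_significant_p05": sum(1 for _, _, p in rows if p < 0.05),
                "mean_carrier_z": (
                    float(pd.Series([z for _, z, _ in rows]).mean()) if rows else None
                ),
            }
            for type_key, rows in zstats.items()
        } | {"skipped": dict(skipped)}

    return block
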