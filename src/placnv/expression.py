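"""Linking CNV regions to gene expression.

Genes are classified by which CNVR types they overlap (any overlap >= 1 bp):
``non_cnv``, ``del_only``, ``dup_only`` or ``both``; the small ``both`` class
is kept in the partition but excluded from del/dup subgroup comparisons.
Gene-group expression contrasts compare per-gene median FPKM between classes
with a two-sided rank-sum test.  For individual-level dosage analysis, raw
counts are normalised with median-of-ratios size factors, transformed per
gene to z-scores, and carriers of a CNV over the gene are compared to
non-carriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .burden import rank_sum_test
from .cnvr import Cnvr
from .consensus import DELETION, DUPLICATION
from .genome import GenomicInterval

__all__ = [
    "GeneAnnot",
    "GeneCnvClass",
    "ExpressionMatrix",
    "MedianComparison",
    "CarrierCompareResult",
    "classify_genes",
    "compare_median_expression",
    "size_factors",
    "normalize_counts",
    "zscore_carrier_compare",
    "zscore_carrier_scan",
    "bcv_bandwidth",
    "plot_expression_density",
]


@dataclass(frozen=True)
class GeneAnnot:
    """A gene with a stable identifier and its genomic interval."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class GeneCnvClass:
    """CNV-overlap class of one gene."""

    gene_id: str
    cnv_class: str  # non_cnv | del_only | dup_only | both


def classify_genes(
    genes: Sequence[GeneAnnot], cnvrs: Sequence[Cnvr]
) -> list[GeneCnvClass]:
    """Assign each gene to exactly one CNV-overlap class.

    Overlap is tested against CNVR spans (>= 1 bp, strand-free).  The four
    classes partition the gene list; counts per class are available from the
    result with ``collections.Counter``.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for region in cnvrs:
        key = (region.span.chrom, region.cnv_type)
        trees.setdefault(key, IntervalTree()).addi(
            region.span.start_bp, region.span.end_bp
        )
    out = []
    for gene in genes:
        iv = gene.interval
        hits_del = bool(
            trees.get((iv.chrom, DELETION), IntervalTree()).overlap(
                iv.start_bp, iv.end_bp
            )
        )
        hits_dup = bool(
            trees.get((iv.chrom, DUPLICATION), IntervalTree()).overlap(
                iv.start_bp, iv.end_bp
            )
        )
        if hits_del and hits_dup:
            cls = "both"
        elif hits_del:
            cls = "del_only"
        elif hits_dup:
            cls = "dup_only"
        else:
            cls = "non_cnv"
        out.append(GeneCnvClass(gene_id=gene.gene_id, cnv_class=cls))
    return out


@dataclass
class ExpressionMatrix:
    """A gene x sample expression grid with a named layer.

    ``values`` is a pandas DataFrame indexed by gene_id with sample_id
    columns; ``layer`` is one of ``fpkm``, ``raw_counts`` or
    ``normalized_counts``.
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in ("fpkm", "raw_counts", "normalized_counts"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def gene_medians(self, samples: Optional[Sequence[str]] = None) -> pd.Series:
        """Per-gene median over all samples or a declared sample subset."""
        df = self.values if samples is None else self.values[list(samples)]
        return df.median(axis=1)


@dataclass(frozen=True)
class MedianComparison:
    median_a: float
    median_b: float
    fold: Optional[float]  # median_a / median_b; None when median_b == 0
    p_value: float


def compare_median_expression(
    medians_a: Sequence[float], medians_b: Sequence[float]
) -> MedianComparison:
    """Compare two gene classes on their per-gene median expression values.

    Returns the group medians (median over genes of the per-gene medians),
    their ratio, and the two-sided rank-sum p for the full distributions.
    """
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both gene classes must be non-empty")
    med_a = float(np.median(a))
    med_b = float(np.median(b))
    fold = med_a / med_b if med_b > 0 else None
    return MedianComparison(
        median_a=med_a, median_b=med_b, fold=fold, p_value=rank_sum_test(a, b)
    )


def size_factors(raw_counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors for a raw-count matrix.

    For every gene with nonzero counts in all samples, each sample's count is
    divided by the gene's geometric mean across samples; the sample's size
    factor is the median of those ratios.  Factors are not rescaled to a unit
    product.
    """
    if raw_counts.layer != "raw_counts":
        raise ValueError("size factors are defined on the raw_counts layer")
    counts = raw_counts.values
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    usable = counts[(counts > 0).all(axis=1)]
    if usable.empty:
        raise ValueError("no gene has nonzero counts in all samples")
    logc = np.log(usable.to_numpy(dtype=float))
    log_gm = logc.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logc - log_gm, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(raw_counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample's raw counts by its median-of-ratios size factor."""
    sf = size_factors(raw_counts)
    return ExpressionMatrix(values=raw_counts.values / sf, layer="normalized_counts")


@dataclass(frozen=True)
class CarrierCompareResult:
    """Per-gene z-score contrast of CNV carriers vs non-carriers."""

    gene_id: str
    z: Optional[pd.Series]  # z-score per included sample; None when skipped
    carrier_mean_z: Optional[float]
    p_value: Optional[float]
    skip_reason: Optional[str] = None


def zscore_carrier_compare(
    normalized: ExpressionMatrix,
    gene_id: str,
    carriers: Iterable[str],
    noncarriers: Iterable[str],
) -> CarrierCompareResult:
    """Compare one gene's z-scored expression between carriers and non-carriers.

    z-scores are computed over the union of the two sample sets
    ((value - mean) / sd); genes with zero variance are skipped with reason
    ``"zero_variance"``, and a group with no samples skips with
    ``"no_carriers"`` / ``"no_noncarriers"``.
    """
    carriers = sorted(set(carriers))
    noncarriers = sorted(set(noncarriers))
    if not carriers:
        return CarrierCompareResult(gene_id, None, None, None, "no_carriers")
    if not noncarriers:
        return CarrierCompareResult(gene_id, None, None, None, "no_noncarriers")
    values = normalized.values.loc[gene_id, carriers + noncarriers].astype(float)
    sd = values.std(ddof=0)
    if sd == 0 or math.isnan(sd):
        return CarrierCompareResult(gene_id, None, None, None, "zero_variance")
    z = (values - values.mean()) / sd
    p = rank_sum_test(z[carriers].to_numpy(), z[noncarriers].to_numpy())
    return CarrierCompareResult(
        gene_id=gene_id,
        z=z,
        carrier_mean_z=float(z[carriers].mean()),
        p_value=p,
    )


def zscore_carrier_scan(
    normalized: ExpressionMatrix,
    carriers_by_gene: Mapping[str, set[str]],
    mode: str = "per_gene",
) -> dict:
    """Run the carrier contrast over many genes.

    ``carriers_by_gene`` maps gene_id to the set of carrier sample_ids;
    non-carriers are the remaining samples of the matrix.  ``per_gene`` mode
    returns one :class:`CarrierCompareResult` per gene plus skip counts;
    ``pooled`` mode concatenates carrier and non-carrier z-scores across all
    usable genes into a single rank-sum test (more power when most CNVs are
    singletons).
    """
    if mode not in ("per_gene", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    all_samples = set(normalized.sample_ids)
    results = []
    pooled_carrier: list[float] = []
    pooled_noncarrier: list[float] = []
    skipped: dict[str, int] = {}
    for gene_id, carriers in carriers_by_gene.items():
        res = zscore_carrier_compare(
            normalized, gene_id, carriers, all_samples - set(carriers)
        )
        if res.skip_reason is not None:
            skipped[res.skip_reason] = skipped.get(res.skip_reason, 0) + 1
            continue
        results.append(res)
        if mode == "pooled":
            carr = sorted(set(carriers))
            pooled_carrier.extend(res.z[carr].tolist())
            pooled_noncarrier.extend(res.z.drop(labels=carr).tolist())
    out: dict = {"n_tested": len(results), "skipped": skipped}
    if mode == "per_gene":
        out["results"] = results
    else:
        out["pooled_p"] = (
            rank_sum_test(pooled_carrier, pooled_noncarrier)
            if pooled_carrier and pooled_noncarrier
            else None
        )
        out["pooled_carrier_mean_z"] = (
            float(np.mean(pooled_carrier)) if pooled_carrier else None
        )
    return out


def bcv_bandwidth(x: Sequence[float]) -> float:
    """Gaussian-kernel bandwidth by biased cross-validation.

    Minimises the BCV estimate of the asymptotic mean integrated squared
    error over a bracket around the normal-reference rule; falls back to
    Silverman's rule when the data are degenerate or the minimisation does
    not move off the bracket edges.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25])) if n > 1 else 0.0
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    silverman = 0.9 * sigma * n ** (-1 / 5) if sigma > 0 else 1.0
    if n < 5 or sigma == 0:
        return silverman
    if n > 2000:  # the criterion is quadratic in n; a fixed subsample suffices
        x = x[np.linspace(0, n - 1, 2000).astype(int)]
        n = len(x)

    diffs = (x[:, None] - x[None, :])[np.triu_indices(n, k=1)]

    def bcv(h: float) -> float:
        # BCV2 criterion (Scott & Terrell): leave-out estimate of AMISE
        d = diffs / h
        phi4 = (d**4 - 6 * d**2 + 3) * np.exp(-0.25 * d**2)
        s = phi4.sum() / (64 * math.sqrt(math.pi))
        return 1 / (2 * n * h * math.sqrt(math.pi)) + s / (n**2 * h)

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        bcv, bounds=(silverman / 10, silverman * 10), method="bounded"
    )
    h = float(res.x)
    at_edge = h < silverman / 9 or h > silverman * 9
    if not res.success or at_edge or not np.isfinite(h) or h <= 0:
        return silverman
    return h


def plot_expression_density(
    medians_by_class: Mapping[str, Sequence[float]],
    path: str,
    log10: bool = True,
    pseudocount: float = 1e-3,
) -> None:
    """Diagnostic density plot of per-gene median expression by gene class.

    Gaussian kernel with BCV-selected bandwidth per class; expression values
    are log10-transformed (with a pseudocount) by default.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, vals in medians_by_class.items():
        v = np.asarray(vals, dtype=float)
        if log10:
            v = np.log10(v + pseudocount)
        if len(v) < 5 or np.ptp(v) == 0:
            continue
        h = bcv_bandwidth(v)
        grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, 400)
        dens = np.exp(-0.5 * ((grid[:, None] - v[None, :]) / h) ** 2).sum(axis=1)
        dens /= len(v) * h * math.sqrt(2 * math.pi)
        ax.plot(grid, dens, label=f"{name} (n={len(v)})")
    ax.set_xlabel("log10 median expression" if log10 else "median expression")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
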