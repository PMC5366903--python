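"""Per-sample CNV burden summaries and group-level comparison statistics.

Burden is counted per sample (events and cumulative Mb span, split by
duplication/deletion).  Group comparisons follow a normality gate: both
groups are tested with Shapiro–Wilk, and only when both pass does a Welch
two-sample t-test run; otherwise the two-sided Wilcoxon rank-sum test is
used (exact null distribution when both groups have <= 25 observations and
no ties, else the normal approximation with tie and continuity correction).
Group sharing contrasts use Fisher's exact test.  No multiple-testing
correction is applied; reported p-values are unadjusted.

The large-CNV profile counts events above a size threshold (300 kb default)
and locates them with respect to pericentromeric/subtelomeric windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cnvr import SampleMeta
from .consensus import DELETION, DUPLICATION, ConsensusCnv
from .genome import ChromInfo, classify_region

__all__ = [
    "BurdenSummary",
    "GroupComparison",
    "LargeCnvProfile",
    "summarize_burden",
    "percent_change",
    "compare_groups",
    "rank_sum_test",
    "fisher_exact_2x2",
    "large_cnv_profile",
]

BP_PER_MB = 1e6


@dataclass(frozen=True)
class BurdenSummary:
    """CNV counts and cumulative spans (Mb) for one sample."""

    sample_id: str
    n_all: int
    n_dup: int
    n_del: int
    span_all_mb: float
    span_dup_mb: float
    span_del_mb: float


def summarize_burden(cnvs: Sequence[ConsensusCnv], sample_id: str) -> BurdenSummary:
    """Count events and sum union-span lengths for one sample's consensus CNVs."""
    for c in cnvs:
        if c.sample_id != sample_id:
            raise ValueError(
                f"CNV from sample {c.sample_id!r} in burden summary for {sample_id!r}"
            )
    dups = [c for c in cnvs if c.cnv_type == DUPLICATION]
    dels = [c for c in cnvs if c.cnv_type == DELETION]
    span_dup = sum(c.length_bp for c in dups) / BP_PER_MB
    span_del = sum(c.length_bp for c in dels) / BP_PER_MB
    return BurdenSummary(
        sample_id=sample_id,
        n_all=len(dups) + len(dels),
        n_dup=len(dups),
        n_del=len(dels),
        span_all_mb=span_dup + span_del,
        span_dup_mb=span_dup,
        span_del_mb=span_del,
    )


def percent_change(reference_median: float, comparison_median: float) -> float:
    """Percent reduction of ``comparison`` relative to ``reference``.

    ``100 * (reference - comparison) / reference``; positive when the
    comparison group is lower.  Rounding to whole percent is left to report
    formatting.
    """
    if reference_median <= 0:
        raise ValueError("reference median must be > 0")
    return 100.0 * (reference_median - comparison_median) / reference_median


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a gated two-group location comparison."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    shapiro_p_a: Optional[float]
    shapiro_p_b: Optional[float]
    test_used: str  # "welch_t" | "wilcoxon_rank_sum"
    p_value: float


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null distribution when both samples have <= 25 observations and the
    pooled data contain no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(a) <= 25 and len(b) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def _shapiro_p(values: np.ndarray) -> Optional[float]:
    # Shapiro-Wilk needs n >= 3 and non-constant data
    if len(values) < 3 or np.ptp(values) == 0:
        return None
    return float(stats.shapiro(values).pvalue)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha_normality: float = 0.05,
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Compare two groups with the Shapiro-gated Welch/rank-sum procedure.

    Each group needs >= 2 values.  Groups too small or too degenerate for
    the Shapiro–Wilk test (n < 3, constant values) fail the gate and fall
    through to the rank-sum test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    sp_a = _shapiro_p(a)
    sp_b = _shapiro_p(b)
    normal = (
        sp_a is not None
        and sp_b is not None
        and sp_a > alpha_normality
        and sp_b > alpha_normality
    )
    if normal:
        test_used = "welch_t"
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        test_used = "wilcoxon_rank_sum"
        p = rank_sum_test(a, b)
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        range_a=(float(a.min()), float(a.max())),
        range_b=(float(b.min()), float(b.max())),
        shapiro_p_a=sp_a,
        shapiro_p_b=sp_b,
        test_used=test_used,
        p_value=p,
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of nonnegative counts.

    Uses the point-probability rule: the p-value sums the hypergeometric
    probabilities (margins fixed) of every table at most as probable as the
    observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("table entries must be nonnegative")
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class LargeCnvProfile:
    """Context profile of large CNVs (> size threshold) for one sample set."""

    group: str
    n_samples: int
    n_all: int
    n_large: int
    n_pericentromeric_large: int
    n_subtelomeric_large: int
    rate_all: float  # CNVs per genome
    rate_large: float
    rate_pericentromeric_large: float
    rate_subtelomeric_large: float
    percent_large: float  # 100 * n_large / n_all

    @property
    def percent_peri_subtelo_of_large(self) -> float:
        if self.n_large == 0:
            return 0.0
        return (
            100.0
            * (self.n_pericentromeric_large + self.n_subtelomeric_large)
            / self.n_large
        )


def large_cnv_profile(
    cnvs: Sequence[ConsensusCnv],
    meta: Sequence[SampleMeta],
    chroms: Sequence[ChromInfo],
    groups: Sequence[str],
    tissue: str = "blood",
    size_threshold_bp: int = 300_000,
    window_frac: float = 0.05,
    label: Optional[str] = None,
) -> LargeCnvProfile:
    """Profile large CNVs for the pooled samples of ``groups`` (one tissue).

    Large means strictly longer than ``size_threshold_bp``.  Each large CNV
    is counted once by its primary region label (pericentromeric takes
    precedence over subtelomeric).  Rates divide by the number of selected
    samples ("per genome").
    """
    chrom_by_name = {c.name: c for c in chroms}
    samples = {
        m.sample_id for m in meta if m.group in groups and m.tissue == tissue
    }
    if not samples:
        raise ValueError(f"no {tissue} samples in groups {list(groups)}")
    selected = [c for c in cnvs if c.sample_id in samples]
    large = [c for c in selected if c.length_bp > size_threshold_bp]
    n_peri = n_subtelo = 0
    for c in large:
        rc = classify_region(c.interval, chrom_by_name[c.interval.chrom], window_frac)
        if rc.primary_label == "pericentromeric":
            n_peri += 1
        elif rc.primary_label == "subtelomeric":
            n_subtelo += 1
    n = len(samples)
    return LargeCnvProfile(
        group=label or "+".join(groups),
        n_samples=n,
        n_all=len(selected),
        n_large=len(large),
        n_pericentromeric_large=n_peri,
        n_subtelomeric_large=n_subtelo,
        rate_all=len(selected) / n,
        rate_large=len(large) / n,
        rate_pericentromeric_large=n_peri / n,
        rate_subtelomeric_large=n_subtelo / n,
        percent_large=100.0 * len(large) / len(selected) if selected else 0.0,
    )
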