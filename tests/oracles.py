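"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's sweep/linkage code paths: pairwise
fractions are computed with dense numpy all-pairs arithmetic, components
with a minimal edge-list union-find, Fisher p-values with full
hypergeometric-support enumeration, and region flags with per-base-pair
membership scans.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def all_pairs_components(
    starts: np.ndarray,
    ends: np.ndarray,
    chrom_codes: np.ndarray,
    type_codes: np.ndarray,
    threshold: float,
    mode: str,
) -> list[frozenset[int]]:
    """Single-linkage components over all pairs, dense enumeration.

    ``mode`` is ``"reciprocal"`` (min of mutual fractions) or ``"max"``
    (coverage of at least one).  Returns the partition as a list of
    frozensets of item indices.
    """
    n = len(starts)
    lengths = ends - starts
    ov = np.minimum(ends[:, None], ends[None, :]) - np.maximum(
        starts[:, None], starts[None, :]
    )
    ov = np.clip(ov, 0, None).astype(float)
    fr_i = ov / lengths[:, None]
    fr_j = ov / lengths[None, :]
    frac = np.minimum(fr_i, fr_j) if mode == "reciprocal" else np.maximum(fr_i, fr_j)
    adj = (
        (chrom_codes[:, None] == chrom_codes[None, :])
        & (type_codes[:, None] == type_codes[None, :])
        & (frac >= threshold)
    )
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def components_from_objects(items, threshold: float, mode: str) -> set[frozenset[int]]:
    """Partition arbitrary objects carrying ``.interval`` and ``.cnv_type``."""
    chroms = sorted({it.interval.chrom for it in items})
    types = sorted({it.cnv_type for it in items})
    starts = np.array([it.interval.start_bp for it in items])
    ends = np.array([it.interval.end_bp for it in items])
    cc = np.array([chroms.index(it.interval.chrom) for it in items])
    tc = np.array([types.index(it.cnv_type) for it in items])
    if len(items) == 0:
        return set()
    return set(all_pairs_components(starts, ends, cc, tc, threshold, mode))


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities
    at most as large as the observed table's (margins fixed)."""
    n_total = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, c1 - (n_total - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n_total, r1, c1)
    p_obs = hypergeom.pmf(a, n_total, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-10)].sum())


def region_flags_per_bp(
    start: int, end: int, length: int, centromere: int, window_frac: float
) -> tuple[bool, bool]:
    """(pericentromeric, subtelomeric) by scanning every base pair."""
    w = round(window_frac * length)
    peri_bp = set(range(max(0, centromere - w), min(length, centromere + w)))
    sub_bp = set(range(0, w)) | set(range(length - w, length))
    iv = set(range(start, end))
    return bool(iv & peri_bp), bool(iv & sub_bp)


def welch_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Hand-computed Welch two-sample t-test p (Welch-Satterthwaite df)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    tstat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(2 * tdist.sf(abs(tstat), df))
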