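"""Single-linkage clustering of genomic intervals under an overlap criterion.

Shared machinery for per-sample consensus merging (reciprocal overlap) and
cross-sample CNV-region clustering (coverage of at least one interval).
Items are partitioned by chromosome before edge enumeration; the caller is
responsible for any further partitioning (CNV type, sample).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Callable, Sequence, TypeVar

from .genome import GenomicInterval

T = TypeVar("T")


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]

    def components(self) -> list[list[int]]:
        groups: dict[int, list[int]] = defaultdict(list)
        for i in range(len(self.parent)):
            groups[self.find(i)].append(i)
        return sorted(groups.values(), key=lambda g: g[0])


def linkage_components(
    items: Sequence[T],
    get_interval: Callable[[T], GenomicInterval],
    edge_fraction: Callable[[GenomicInterval, GenomicInterval], float],
    min_fraction: float,
) -> list[list[T]]:
    """Connected components of the graph with edges where the overlap
    fraction is >= ``min_fraction``.

    Singletons are returned as one-element components.  A plane sweep over
    start-sorted intervals keeps the pair enumeration near-linear for
    non-pathological data; components are returned ordered by their leftmost
    member (chrom, start, end).
    """
    n = len(items)
    uf = UnionFind(n)
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, item in enumerate(items):
        by_chrom[get_interval(items[i]).chrom].append(i)

    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: (get_interval(items[i]).start_bp, get_interval(items[i]).end_bp))
        active: list[int] = []
        for i in idxs:
            iv = get_interval(items[i])
            still = []
            for j in active:
                jv = get_interval(items[j])
                if jv.end_bp <= iv.start_bp:
                    continue  # starts are sorted, so j cannot overlap any later item
                still.append(j)
                if edge_fraction(iv, jv) >= min_fraction:
                    uf.union(i, j)
            active = still + [i]

    def comp_key(comp: list[int]) -> tuple:
        ivs = sorted(
            (get_interval(items[i]).chrom, get_interval(items[i]).start_bp, get_interval(items[i]).end_bp)
            for i in comp
        )
        return ivs[0]

    comps = sorted(uf.components(), key=comp_key)
    return [[items[i] for i in comp] for comp in comps]
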