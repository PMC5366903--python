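"""Genomic coordinate conventions, interval algebra and chromosome-context windows.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
Tab-separated inputs and outputs use the 1-based inclusive dialect common in
CNV reports; conversion happens at I/O time (:mod:`placnv.io`), never here.

Chromosome context is defined relative to a :class:`ChromInfo` table:
*subtelomeric* windows cover a fixed fraction of the chromosome length at each
end, and the *pericentromeric* window extends the same fraction to both sides
of the centromere centre.  An interval overlapping either window by at least
one base pair carries the corresponding flag.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ChromInfo",
    "GenomicInterval",
    "RegionClass",
    "overlap_bp",
    "reciprocal_overlap",
    "max_fraction_overlap",
    "classify_region",
]


@dataclass(frozen=True)
class ChromInfo:
    """One autosome of the active genome build.

    Parameters
    ----------
    name:
        Chromosome label (e.g. ``"1"``).
    length_bp:
        Chromosome length in base pairs, > 0.
    centromere_center_bp:
        Midpoint of the centromere, within ``[0, length_bp]``.  Acrocentric
        chromosomes simply have a centre close to 0; the pericentromeric
        window is clipped at the chromosome boundary.
    """

    name: str
    length_bp: int
    centromere_center_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name!r}: length_bp must be > 0")
        if not 0 <= self.centromere_center_bp <= self.length_bp:
            raise ValueError(
                f"chromosome {self.name!r}: centromere centre "
                f"{self.centromere_center_bp} outside [0, {self.length_bp}]"
            )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start_bp, end_bp)`` on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 0:
            raise ValueError(f"start_bp must be >= 0, got {self.start_bp}")
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"empty or inverted interval [{self.start_bp}, {self.end_bp}) "
                f"on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class RegionClass:
    """Chromosome-context flags for one interval.

    ``primary_label`` resolves multi-window overlaps with pericentromeric >
    subtelomeric > interstitial precedence, so each CNV is counted once in
    context tables.
    """

    pericentromeric: bool
    subtelomeric: bool

    @property
    def primary_label(self) -> str:
        if self.pericentromeric:
            return "pericentromeric"
        if self.subtelomeric:
            return "subtelomeric"
        return "interstitial"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 if disjoint or trans)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end_bp, b.end_bp) - max(a.start_bp, b.start_bp))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: ``min(ov/len(a), ov/len(b))``.

    This is the symmetric criterion used to decide that two calls on the same
    sample identify the same event; both intervals must individually be
    covered to the threshold fraction.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length_bp, ov / b.length_bp)


def max_fraction_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Coverage of *at least one* interval: ``max(ov/len(a), ov/len(b))``.

    The asymmetric criterion used for cross-sample CNV-region clustering: a
    small CNV fully contained in a large one scores 1.0 even when it covers
    only a sliver of the larger event.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return max(ov / a.length_bp, ov / b.length_bp)


def classify_region(
    iv: GenomicInterval, chrom: ChromInfo, window_frac: float = 0.05
) -> RegionClass:
    """Flag an interval as pericentromeric and/or subtelomeric.

    The window width is ``w = round(window_frac * length)``.  Subtelomeric
    windows are ``[0, w)`` and ``[L - w, L)``; the pericentromeric window is
    ``[c - w, c + w)`` clipped to the chromosome, with ``c`` the centromere
    centre.  Membership is any-overlap (>= 1 bp).
    """
    if iv.chrom != chrom.name:
        raise ValueError(f"interval on {iv.chrom!r}, chromosome is {chrom.name!r}")
    if iv.end_bp > chrom.length_bp:
        raise ValueError(
            f"interval [{iv.start_bp}, {iv.end_bp}) exceeds length of "
            f"{chrom.name} ({chrom.length_bp})"
        )
    if not 0.0 < window_frac < 0.5:
        raise ValueError(f"window_frac must be in (0, 0.5), got {window_frac}")

    length = chrom.length_bp
    w = round(window_frac * length)
    c = chrom.centromere_center_bp

    def hits(lo: int, hi: int) -> bool:
        return min(iv.end_bp, hi) - max(iv.start_bp, lo) >= 1

    subtelo = (w > 0) and (hits(0, w) or hits(length - w, length))
    peri = hits(max(0, c - w), min(length, c + w))
    return RegionClass(pericentromeric=peri, subtelomeric=subtelo)


SEX_CHROM_NAMES = frozenset(
    {"X", "Y", "XY", "MT", "M", "chrX", "chrY", "chrM", "chrMT"}
)
"""Labels recognised as non-autosomal; records on these are dropped at I/O."""
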