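import numpy as np
import pytest

from placnv.genome import ChromInfo, GenomicInterval


@pytest.fixture
def toy_chrom() -> ChromInfo:
    """100 Mb metacentric chromosome with the centromere at 40 Mb."""
    return ChromInfo("1", 100_000_000, 40_000_000)


@pytest.fixture
def toy_build() -> list[ChromInfo]:
    return [
        ChromInfo("1", 100_000_000, 40_000_000),
        ChromInfo("2", 60_000_000, 25_000_000),
        ChromInfo("4", 50_000_000, 2_000_000),  # acrocentric
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def iv(start: int, end: int, chrom: str = "1") -> GenomicInterval:
    return GenomicInterval(chrom, start, end)
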