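import numpy as np
import pytest

from tadpersist import GenomeLayout, GenomicInterval, IntervalSet


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout((("chrA", 2_000_000), ("chrB", 1_000_000)), bin_size=40_000)


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chrA", "chrB"),
    max_pos: int = 1_000_000,
    max_len: int = 50_000,
) -> IntervalSet:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out)
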