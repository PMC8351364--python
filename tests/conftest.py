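import numpy as np
import pytest

from epihet.io import EpiRead
from epihet.loci import EpialleleLocus, PatternCounts
from epihet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_locus():
    return EpialleleLocus("chr1", (100, 110, 120, 130))


def make_counts(counts_by_pattern: dict[int, int], locus=None) -> PatternCounts:
    arr = np.zeros(16, dtype=np.int64)
    for pattern, n in counts_by_pattern.items():
        arr[pattern] = n
    if locus is None:
        locus = EpialleleLocus("chr1", (100, 110, 120, 130))
    return PatternCounts(locus, arr)


def reads_for_pattern(
    pattern: int, n: int, chrom="chr1", positions=(100, 110, 120, 130), tag="r"
) -> list[EpiRead]:
    bits = [(pattern >> s) & 1 for s in (3, 2, 1, 0)]
    return [
        EpiRead(chrom, f"{tag}{pattern}_{i}", np.array(positions), np.array(bits, dtype=np.int8))
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A compact deterministic cohort shared by read-only tests."""
    return simulate_cohort(
        SimulationConfig(seed=11, n_loci=60, n_genes=20, depth_mean=80.0)
    )
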