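import numpy as np
import pytest

from gnmfclust import (
    CopyNumberMatrix,
    Segment,
    default_benchmark_designs,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """2 segments x 3 samples, hand-written values."""
    segments = [Segment("chr1", 0, 1000, 120), Segment("chr1", 1000, 2500, 150)]
    values = np.array([[2.0, 3.1, 1.4], [2.1, 2.0, 1.5]])
    return CopyNumberMatrix(values, segments, ["s1", "s2", "s3"],
                            ["tumor", "tumor", "tumor"])


@pytest.fixture(scope="session")
def separable3():
    """The anchor fixture: 3 well-separated planted clusters, 60 samples."""
    design = default_benchmark_designs(seed=42)["separable-3"]
    matrix, truth, contaminated = simulate_cohort(design)
    return matrix, truth


@pytest.fixture(scope="session")
def contaminated_cohort():
    design = default_benchmark_designs(seed=7)["contaminated"]
    return simulate_cohort(design)


def make_grid(n, chrom="chr1", size=1000):
    return [Segment(chrom, i * size, (i + 1) * size, 100) for i in range(n)]
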