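import numpy as np
import pytest

from cpgdecon.genome_io import CoverageMatrix, CpGIndex, ReadInterval, segment_regions

#: the worked example: 5 CpG sites, 6 reads covering
#: {1}, {1,2}, {1,2,3}, {3,4}, {3,4,5}, {5}
FIG1_SPANS = np.array([(0, 0), (0, 1), (0, 2), (2, 3), (2, 4), (4, 4)])
FIG1_POSITIONS = np.array([100, 130, 160, 190, 220])


@pytest.fixture
def fig1_cm() -> CoverageMatrix:
    return CoverageMatrix(
        region_id=0,
        chrom="chr1",
        site_positions=FIG1_POSITIONS.copy(),
        spans=FIG1_SPANS.copy(),
    )


@pytest.fixture
def fig1_index() -> CpGIndex:
    return segment_regions(CpGIndex("chr1", FIG1_POSITIONS.copy()), link_dist=50)


@pytest.fixture
def fig1_reads() -> list[ReadInterval]:
    """Reads whose covered spans reproduce the worked-example matrix."""
    intervals = [
        (90, 110),  # site 1 only
        (95, 140),  # sites 1-2
        (95, 170),  # sites 1-3
        (155, 200),  # sites 3-4
        (155, 230),  # sites 3-5
        (215, 230),  # site 5 only
    ]
    return [ReadInterval("chr1", s, e) for s, e in intervals]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240807)


def random_instance(rng, g_max=4, n_max=8, identifiable=False):
    """A random small coverage matrix (every site covered by >=1 read).

    With ``identifiable=True`` every site gets a singleton-span read, which
    makes the observed-data likelihood strictly concave with a unique
    maximizer (per-coordinate oracle comparisons are only meaningful then —
    ambiguous-only designs have maximizer ridges).
    """
    g = int(rng.integers(2, g_max + 1))
    n = int(rng.integers(g, n_max + 1))
    spans = [(j, j) for j in range(g)] if identifiable else []
    while len(spans) < n:
        k = int(rng.integers(0, g))
        l = int(rng.integers(k, g))
        spans.append((k, l))
    # ensure every site is covered so the MLE is interior-ish
    for j in range(g):
        if not any(k <= j <= l for k, l in spans):
            spans[int(rng.integers(0, n))] = (j, j)
    positions = np.cumsum(rng.integers(20, 40, size=g)) + 100
    return CoverageMatrix(0, "chr1", positions, np.array(spans))
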