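import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bedperturb as bp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# independent oracles


def pairwise_overlap_oracle(a, b) -> int:
    """O(n*m) nested-loop count of >=1 bp overlapping pairs."""
    return sum(1 for ra in a for rb in b if ra.overlaps(rb))


def bitmap_coverage_oracle(reference, query, chrom_len=10_000):
    """Per-base bitmap coverage of each query region by the reference union."""
    masks = {}
    for r in reference:
        mask = masks.setdefault(r.chrom, np.zeros(chrom_len, dtype=bool))
        mask[r.start : r.end] = True
    out = []
    for q in query:
        mask = masks.get(q.chrom)
        covered = 0 if mask is None else int(mask[q.start : q.end].sum())
        out.append(covered / q.length)
    return np.asarray(out)


def random_region_set(rng, n, chrom_len=10_000, chroms=("chr1", "chr2")):
    regions = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(start + 500, chrom_len) + 1))
        regions.append(bp.GenomicRegion(chrom, start, end))
    return bp.RegionSet(regions)


# ---------------------------------------------------------------------------
# shared fixtures


@pytest.fixture(scope="session")
def study_inputs():
    """1,000-region non-self-overlapping original + superset universe."""
    return bp.default_study_inputs(seed=11)


@pytest.fixture(scope="session")
def study_table(study_inputs):
    """The full 36-cell x 10-replicate study score table."""
    original, universe, sizes, _ = study_inputs
    return bp.run_study(
        original, bp.build_grid(), 10, universe, sizes, add_pool=universe, seed=11
    )


@pytest.fixture
def toy_set():
    """3 mutually non-overlapping 100 bp regions."""
    return bp.RegionSet(
        [
            bp.GenomicRegion("chr1", 0, 100),
            bp.GenomicRegion("chr1", 150, 250),
            bp.GenomicRegion("chr1", 300, 400),
        ]
    )


@pytest.fixture
def chrom_sizes():
    return bp.ChromSizes({"chr1": 1_000_000, "chr2": 1_000_000})
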