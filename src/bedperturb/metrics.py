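"""Four similarity scores between two region sets.

Two overlap-based scores:

* **Jaccard** — overlapping-pair count divided by the union count
  ``|A| + |B| - |A n B|``, where ``|A n B|`` is the number of region pairs
  (one from each set) sharing at least 1 bp.
* **Coverage** — the mean, over every region in both files, of the fraction of
  that region's bases covered by the other file, averaged across the two
  directions.

Two vector-based scores, computed on binary presence/absence vectors cast
against a universe (one bit per universe region, set when any query region
overlaps it by >=1 bp):

* **Euclidean similarity** — ``1 - ||u - v|| / sqrt(d)`` where ``d`` is the
  universe size (the distance between an all-zeros and an all-ones vector),
  so the score lies in [0, 1].
* **Cosine similarity** — the plain cosine of the angle between the two
  vectors (1 for identical non-empty vectors).

All four scores are symmetric and equal 1 for identical non-empty inputs.
Empty inputs raise rather than returning a sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _intervals
from .regions import RegionSet, ValidationError

METRIC_NAMES = ("jaccard", "coverage", "euclidean", "cosine")


def count_overlap_pairs(a: RegionSet, b: RegionSet) -> int:
    """Number of (region in a, region in b) pairs sharing at least 1 bp."""
    return _intervals.total_overlap_pairs(
        _intervals.by_chrom(a), _intervals.by_chrom(b)
    )


def jaccard_score(a: RegionSet, b: RegionSet) -> float:
    """Region-count Jaccard: overlapping pairs over ``|A| + |B| - pairs``."""
    if len(a) == 0 and len(b) == 0:
        raise ValidationError("Jaccard undefined for two empty region sets")
    inter = count_overlap_pairs(a, b)
    union = len(a) + len(b) - inter
    if union <= 0:
        raise ValidationError(
            f"degenerate union count {union} (|A|={len(a)}, |B|={len(b)}, "
            f"pairs={inter}): heavy multi-overlap inflates the pair count "
            "beyond the region totals"
        )
    return inter / union


def per_region_coverage(reference: RegionSet, query: RegionSet) -> np.ndarray:
    """For each region in ``query``, the fraction of its bases covered by the
    union of ``reference`` regions. Returned in query order."""
    if len(query) == 0:
        return np.zeros(0, dtype=float)
    ref = _intervals.by_chrom(reference)
    fractions = np.empty(len(query), dtype=float)
    # compute per chromosome, then scatter back to query order
    positions: dict[str, list[int]] = {}
    for i, r in enumerate(query):
        positions.setdefault(r.chrom, []).append(i)
    q = _intervals.by_chrom(query)
    frac = _intervals.covered_fractions(q, ref)
    for chrom, idx in positions.items():
        fractions[idx] = frac[chrom]
    return fractions


def coverage_score(a: RegionSet, b: RegionSet) -> float:
    """Bidirectional mean coverage: average of the two directional means."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("coverage score undefined for an empty region set")
    cov_a = per_region_coverage(b, a)  # a's regions covered by b
    cov_b = per_region_coverage(a, b)  # b's regions covered by a
    return float((cov_a.mean() + cov_b.mean()) / 2.0)


@dataclass(frozen=True)
class BinaryVector:
    """Presence/absence of a region set cast against an ordered universe."""

    universe: RegionSet
    bits: np.ndarray  # uint8 of length |universe|

    def __post_init__(self) -> None:
        if len(self.bits) != len(self.universe):
            raise ValidationError(
                f"bit vector length {len(self.bits)} != universe size "
                f"{len(self.universe)}"
            )

    def same_universe(self, other: "BinaryVector") -> bool:
        if self.universe is other.universe:
            return True
        return self.universe.regions == other.universe.regions


def vectorize(rs: RegionSet, universe: RegionSet) -> BinaryVector:
    """Cast ``rs`` against ``universe``: bit i is 1 iff any region of ``rs``
    overlaps universe region i by >=1 bp."""
    if len(universe) == 0:
        raise ValidationError("cannot vectorize against an empty universe")
    counts = _intervals.overlap_counts(
        _intervals.by_chrom(universe), _intervals.by_chrom(rs)
    )
    positions: dict[str, list[int]] = {}
    for i, r in enumerate(universe):
        positions.setdefault(r.chrom, []).append(i)
    bits = np.zeros(len(universe), dtype=np.uint8)
    for chrom, idx in positions.items():
        bits[idx] = (counts[chrom] > 0).astype(np.uint8)
    return BinaryVector(universe, bits)


def euclidean_similarity(u: BinaryVector, v: BinaryVector) -> float:
    """1 minus the Euclidean distance normalized by the maximum possible
    distance in this universe (all-zeros vs all-ones, i.e. sqrt(d))."""
    if not u.same_universe(v):
        raise ValidationError("vectors were built against different universes")
    d = len(u.universe)
    dist = float(np.sqrt(np.sum((u.bits.astype(float) - v.bits.astype(float)) ** 2)))
    return 1.0 - dist / float(np.sqrt(d))


def cosine_similarity(u: BinaryVector, v: BinaryVector) -> float:
    """Cosine of the angle between the two presence/absence vectors."""
    if not u.same_universe(v):
        raise ValidationError("vectors were built against different universes")
    nu = float(np.linalg.norm(u.bits.astype(float)))
    nv = float(np.linalg.norm(v.bits.astype(float)))
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("cosine similarity undefined for an all-zero vector")
    return float(np.dot(u.bits.astype(float), v.bits.astype(float)) / (nu * nv))


def all_scores(a: RegionSet, b: RegionSet, universe: RegionSet) -> dict[str, float]:
    """All four similarity scores between ``a`` and ``b`` under ``universe``."""
    ua = vectorize(a, universe)
    ub = vectorize(b, universe)
    return {
        "jaccard": jaccard_score(a, b),
        "coverage": coverage_score(a, b),
        "euclidean": euclidean_similarity(ua, ub),
        "cosine": cosine_similarity(ua, ub),
    }
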