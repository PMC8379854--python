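"""Synthetic fixtures: region sets, universes, and chromosome-size tables.

The generator lays regions left-to-right with fixed gaps, which guarantees a
mutually non-overlapping set — the regime in which the Jaccard drop law is
exact. Defaults echo a typical transcription-factor ChIP-seq peak file:
300 bp regions on a small multi-chromosome toy genome.

Universes come in two flavours:

* *full*: one universe region overlapping each base region, plus ``extra``
  additional regions disjoint from the base set — a catalog that fully
  encapsulates the query, the well-behaved regime for vector metrics.
* *subset* (``subset_fraction``): only a stated fraction of the
  base-overlapping regions is retained (extras are kept), emulating a
  reference catalog that poorly encapsulates the file being perturbed. This
  reproduces the universe-dependence of the vector metrics: the fewer
  universe regions the query actually hits, the larger the proportion of
  vector components that change under a given perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .regions import ChromSizes, GenomicRegion, RegionSet, ValidationError

#: Default toy genome: two 1 Mb chromosomes.
DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1", 1_000_000),
    ("chr2", 1_000_000),
)

LengthSpec = Union[int, Tuple[float, float]]  # fixed, or (mean, stdev)


@dataclass
class SynthSpec:
    """Layout parameters for a synthetic region set."""

    n_regions: int = 1000
    region_length: LengthSpec = 300
    gap_length: int = 100
    chromosomes: Sequence[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_CHROMOSOMES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 0:
            raise ValidationError(f"n_regions must be >= 0, got {self.n_regions}")
        if self.gap_length < 1:
            raise ValidationError(
                f"gap_length must be >= 1 to guarantee disjoint regions, "
                f"got {self.gap_length}"
            )

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(dict(self.chromosomes))


def _draw_length(spec: SynthSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.region_length, int):
        return spec.region_length
    mean, stdev = spec.region_length
    return max(1, int(np.rint(rng.normal(mean, stdev))))


def _layout(
    lengths: list[int],
    gap: int,
    chromosomes: Sequence[tuple[str, int]],
    cursors: Optional[dict[str, int]] = None,
) -> list[GenomicRegion]:
    """Place regions left-to-right across chromosomes, ``gap`` bases apart."""
    cursors = dict(cursors or {})
    regions: list[GenomicRegion] = []
    chrom_iter = iter(chromosomes)
    chrom, limit = next(chrom_iter)
    pos = cursors.get(chrom, 0)
    for length in lengths:
        while pos + length > limit:
            nxt = next(chrom_iter, None)
            if nxt is None:
                required = sum(lengths) + gap * len(lengths)
                available = sum(c[1] for c in chromosomes)
                raise ValidationError(
                    f"regions do not fit: need roughly {required} bases "
                    f"(plus gaps), only {available} available"
                )
            chrom, limit = nxt
            pos = cursors.get(chrom, 0)
        regions.append(GenomicRegion(chrom, pos, pos + length))
        pos += length + gap
    return regions


def make_regions(spec: SynthSpec) -> RegionSet:
    """Generate ``spec.n_regions`` mutually non-overlapping regions.

    Deterministic given the spec (lengths drawn from the seeded generator when
    ``region_length`` is a (mean, stdev) pair).
    """
    rng = np.random.default_rng(spec.seed)
    lengths = [_draw_length(spec, rng) for _ in range(spec.n_regions)]
    return RegionSet(_layout(lengths, spec.gap_length, spec.chromosomes))


def make_universe(
    base: RegionSet,
    extra: int,
    spec: SynthSpec,
    subset_fraction: Optional[float] = None,
) -> RegionSet:
    """Build a universe around ``base``.

    Full mode (``subset_fraction`` None): one universe region per base region
    (identical coordinates, hence overlapping) plus ``extra`` regions laid out
    beyond the base regions, disjoint from them and from each other.

    Subset mode: keep a uniformly chosen fraction of the base-overlapping
    regions while retaining all extras — a universe that only partially
    encapsulates the query.
    """
    if extra < 0:
        raise ValidationError(f"extra must be >= 0, got {extra}")
    base_part = list(base)
    if subset_fraction is not None:
        if not 0.0 < subset_fraction <= 1.0:
            raise ValidationError(
                f"subset_fraction must be in (0, 1], got {subset_fraction}"
            )
        # independent stream so the extras are identical across fractions,
        # keeping the subset universes nested around the same extra regions
        sub_rng = np.random.default_rng(spec.seed + 2)
        keep = max(1, int(round(subset_fraction * len(base_part))))
        idx = np.sort(sub_rng.choice(len(base_part), size=keep, replace=False))
        base_part = [base_part[int(i)] for i in idx]
    rng = np.random.default_rng(spec.seed + 1)
    extras: list[GenomicRegion] = []
    if extra > 0:
        # resume layout after the last base region on each chromosome
        cursors: dict[str, int] = {}
        for r in base:
            cursors[r.chrom] = max(cursors.get(r.chrom, 0), r.end + spec.gap_length)
        lengths = [_draw_length(spec, rng) for _ in range(extra)]
        extras = _layout(lengths, spec.gap_length, spec.chromosomes, cursors)
    return RegionSet(base_part + extras)
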