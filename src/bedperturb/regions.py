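"""Core domain types for genomic interval sets.

Coordinates are 0-based, half-open (BED convention): a region covers bases
``start .. end-1`` and two regions overlap iff ``max(starts) < min(ends)``.
Zero- and negative-length regions are rejected everywhere.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union


class ValidationError(ValueError):
    """Raised when a region, plan, or input file violates an invariant."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A single genomic interval: chromosome, start, end (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValidationError(f"invalid chromosome name {self.chrom!r}")
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValidationError(
                f"coordinates must be integers, got {self.start!r}, {self.end!r}"
            )
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"zero- or negative-length region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        """True iff the two regions share at least one base."""
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )

    def shifted(self, distance: int) -> "GenomicRegion":
        """Translate both endpoints by ``distance`` bases (length preserved)."""
        return GenomicRegion(self.chrom, self.start + distance, self.end + distance)

    def to_line(self) -> str:
        return f"{self.chrom}\t{self.start}\t{self.end}"


class RegionSet:
    """An ordered collection of regions with a snapshot of its original state.

    The snapshot taken at construction time is immutable; :meth:`reset`
    restores it, which is the contract perturbation pipelines rely on when
    generating many replicates from the same starting file.
    """

    __slots__ = ("regions", "_original", "source")

    def __init__(
        self,
        regions: Iterable[GenomicRegion],
        original: Optional[Iterable[GenomicRegion]] = None,
        source: Optional[Path] = None,
    ) -> None:
        self.regions: list[GenomicRegion] = list(regions)
        self._original: tuple[GenomicRegion, ...] = (
            tuple(self.regions) if original is None else tuple(original)
        )
        self.source = Path(source) if source is not None else None

    @property
    def original(self) -> tuple[GenomicRegion, ...]:
        return self._original

    def reset(self) -> "RegionSet":
        """Restore the region list to the original snapshot, in place."""
        self.regions = list(self._original)
        return self

    def derive(self, regions: Iterable[GenomicRegion]) -> "RegionSet":
        """New RegionSet with different regions but the same original snapshot."""
        return RegionSet(regions, original=self._original, source=self.source)

    def original_set(self) -> "RegionSet":
        """A fresh RegionSet holding the original snapshot."""
        return RegionSet(self._original, original=self._original, source=self.source)

    def sorted_regions(self) -> list[GenomicRegion]:
        return sorted(self.regions)

    def lengths(self) -> list[int]:
        return [r.length for r in self.regions]

    def total_bases(self) -> int:
        """Sum of region lengths (overlapping bases counted per region)."""
        return sum(r.length for r in self.regions)

    def validate_against(self, chrom_sizes: "ChromSizes") -> None:
        for r in self.regions:
            if r.chrom not in chrom_sizes:
                raise ValidationError(f"chromosome {r.chrom} missing from sizes table")
            if r.end > chrom_sizes[r.chrom]:
                raise ValidationError(
                    f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome "
                    f"length {chrom_sizes[r.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet({len(self.regions)} regions)"


class ChromSizes(Mapping):
    """Mapping from chromosome name to its length in bases (all > 0)."""

    def __init__(self, lengths: Mapping[str, int]) -> None:
        self._lengths: dict[str, int] = {}
        for name, length in lengths.items():
            if not isinstance(length, int) or length <= 0:
                raise ValidationError(
                    f"chromosome {name!r} has non-positive length {length!r}"
                )
            if name in self._lengths:
                raise ValidationError(f"duplicate chromosome {name!r}")
            self._lengths[name] = length

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __repr__(self) -> str:
        return f"ChromSizes({self._lengths!r})"


PathLike = Union[str, Path]
#: Selector slots accept either a BED path (loaded lazily) or a RegionSet.
Selector = Union[PathLike, RegionSet, None]


@dataclass
class PerturbationPlan:
    """Rates, distribution parameters, and selector files for one perturbation run.

    Rates are proportions of the *current* region count at the moment each
    operation executes. Distances and added-region lengths are drawn from
    normal distributions; defaults N(0, 150) for shift and N(320, 20) for add.
    """

    shift_rate: float = 0.0
    add_rate: float = 0.0
    cut_rate: float = 0.0
    merge_rate: float = 0.0
    drop_rate: float = 0.0
    shift_mean: float = 0.0
    shift_stdev: float = 150.0
    add_mean: float = 320.0
    add_stdev: float = 20.0
    add_file: Selector = None
    drop_file: Selector = None
    shift_file: Selector = None
    valid_regions: Selector = None
    seed: Optional[int] = None
    repeat: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("shift_rate", "add_rate", "cut_rate", "merge_rate", "drop_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name}={rate} outside [0, 1]")
        if self.shift_stdev <= 0:
            raise ValidationError(f"shift_stdev must be > 0, got {self.shift_stdev}")
        if self.add_stdev < 0:
            raise ValidationError(f"add_stdev must be >= 0, got {self.add_stdev}")
        if self.add_mean <= 0:
            raise ValidationError(f"add_mean must be > 0, got {self.add_mean}")
        if self.repeat < 1:
            raise ValidationError(f"repeat must be >= 1, got {self.repeat}")
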