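"""The five stochastic perturbation operators and the combined runner.

Each operation perturbs ``k = round(rate * n)`` regions (half-away-from-zero
rounding, floored at 0), where ``n`` is the region count *at the moment the
operation runs*. Selection is always uniform without replacement. The combined
runner applies the operations in the fixed order

    shift -> add -> cut -> merge -> drop

each acting on the result of the previous one. A single seed drives one random
stream consumed in that order, so a whole plan is reproducible from one
integer: identical (input, plan, seed) triples produce byte-identical output
files.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree

from .io import default_output_path, read_bed, write_bed
from .regions import (
    ChromSizes,
    GenomicRegion,
    PerturbationPlan,
    RegionSet,
    Selector,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Attempts at redrawing a shift distance / add start before giving up.
MAX_REDRAWS = 100

RandomSource = np.random.Generator


def ensure_rng(rng: Union[None, int, RandomSource]) -> RandomSource:
    """Coerce a seed (or None, or an existing Generator) into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def perturbed_count(rate: float, n: int) -> int:
    """k = round(rate * n), half away from zero, floored at 0."""
    if n < 0:
        raise ValidationError(f"negative region count {n}")
    return max(0, int(np.floor(rate * n + 0.5)))


def _resolve_selector(selector: Selector) -> Optional[RegionSet]:
    if selector is None or isinstance(selector, RegionSet):
        return selector
    return read_bed(selector)


def select_from_file(rs: RegionSet, selector: RegionSet) -> list[int]:
    """Indices of regions in ``rs`` overlapping (>=1 bp) any selector region.

    Used by drop-from-file and shift-from-file to restrict the candidate pool
    before uniform sampling.
    """
    trees: dict[str, IntervalTree] = {}
    for r in selector:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return [
        i
        for i, r in enumerate(rs)
        if r.chrom in trees and trees[r.chrom].overlaps(r.start, r.end)
    ]


def shift_regions(
    rs: RegionSet,
    rate: float,
    mean: float,
    stdev: float,
    chrom_sizes: ChromSizes,
    rng: Union[None, int, RandomSource] = None,
    candidates: Optional[RegionSet] = None,
) -> RegionSet:
    """Translate k randomly chosen regions by a common per-region distance.

    Each selected region's start and end move by the same integer distance
    drawn from Normal(mean, stdev) and rounded to the nearest integer, so
    region length is preserved exactly. A draw that would push the region past
    either chromosome end is redrawn (up to ``MAX_REDRAWS`` times, after which
    the region is left unshifted with a warning). With ``candidates`` given,
    only regions intersecting the candidate file are eligible.
    """
    if stdev <= 0:
        raise ValidationError(f"shift stdev must be > 0, got {stdev}")
    rng = ensure_rng(rng)
    n = len(rs)
    k = perturbed_count(rate, n)
    if k == 0:
        return rs.derive(rs.regions)
    for r in rs:
        if r.chrom not in chrom_sizes:
            raise ValidationError(
                f"chromosome {r.chrom} absent from the sizes table; "
                "shift requires a length for every chromosome in the set"
            )
    pool = list(range(n)) if candidates is None else select_from_file(rs, candidates)
    if k > len(pool):
        raise ValidationError(
            f"cannot shift {k} regions: only {len(pool)} candidates available"
        )
    chosen = rng.choice(len(pool), size=k, replace=False)
    regions = list(rs.regions)
    for ci in chosen:
        i = pool[int(ci)]
        region = regions[i]
        limit = chrom_sizes[region.chrom]
        for _ in range(MAX_REDRAWS):
            dist = int(np.rint(rng.normal(mean, stdev)))
            if region.start + dist >= 0 and region.end + dist <= limit:
                regions[i] = region.shifted(dist)
                break
        else:
            warnings.warn(
                f"region {region.chrom}:{region.start}-{region.end} left "
                f"unshifted after {MAX_REDRAWS} out-of-bounds draws",
                stacklevel=2,
            )
    return rs.derive(regions)


def _draw_position(
    length: int,
    chrom_sizes: ChromSizes,
    rng: RandomSource,
    valid: Optional[list[GenomicRegion]],
    chrom_probs: Optional[np.ndarray],
    chrom_names: list[str],
) -> GenomicRegion:
    """Place one new region of ``length`` bases, redrawing the start (not
    truncating the length) when it would cross the chromosome end."""
    for _ in range(MAX_REDRAWS):
        if valid is None:
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
            limit = chrom_sizes[chrom]
            start = int(rng.integers(0, limit))
        else:
            weights = np.array([v.length for v in valid], dtype=float)
            iv = valid[int(rng.choice(len(valid), p=weights / weights.sum()))]
            chrom = iv.chrom
            if chrom not in chrom_sizes:
                raise ValidationError(
                    f"valid-regions chromosome {chrom} absent from sizes table"
                )
            limit = chrom_sizes[chrom]
            start = int(rng.integers(iv.start, iv.end))
        if start + length <= limit:
            return GenomicRegion(chrom, start, start + length)
    raise ValidationError(
        f"could not place a {length} bp region after {MAX_REDRAWS} attempts; "
        "region length likely exceeds the available chromosomes"
    )


def add_regions(
    rs: RegionSet,
    rate: float,
    mean: float,
    stdev: float,
    chrom_sizes: ChromSizes,
    rng: Union[None, int, RandomSource] = None,
    valid_regions: Optional[RegionSet] = None,
) -> RegionSet:
    """Append k randomly generated regions.

    Per region: a chromosome is sampled with probability proportional to its
    length, a start uniform along it, and a length from Normal(mean, stdev)
    rounded and floored at 1 bp. With ``valid_regions``, sampling is restricted
    to those intervals (interval chosen proportional to its length, then a
    start within it); the region stays within its chromosome.
    """
    rng = ensure_rng(rng)
    k = perturbed_count(rate, len(rs))
    if k == 0:
        return rs.derive(rs.regions)
    if len(chrom_sizes) == 0:
        raise ValidationError("add requires a non-empty chromosome sizes table")
    valid: Optional[list[GenomicRegion]] = None
    if valid_regions is not None:
        valid = list(valid_regions)
        if not valid:
            raise ValidationError("valid-regions file is empty but k > 0")
    names = list(chrom_sizes)
    lens = np.array([chrom_sizes[c] for c in names], dtype=float)
    probs = lens / lens.sum()
    regions = list(rs.regions)
    for _ in range(k):
        length = max(1, int(np.rint(rng.normal(mean, stdev))))
        regions.append(_draw_position(length, chrom_sizes, rng, valid, probs, names))
    return rs.derive(regions)


def add_from_file(
    rs: RegionSet,
    rate: float,
    add_pool: RegionSet,
    rng: Union[None, int, RandomSource] = None,
) -> RegionSet:
    """Append k regions sampled uniformly without replacement from a pool."""
    rng = ensure_rng(rng)
    k = perturbed_count(rate, len(rs))
    if k == 0:
        return rs.derive(rs.regions)
    if len(add_pool) == 0:
        raise ValidationError("add pool is empty")
    if k > len(add_pool):
        raise ValidationError(
            f"cannot add {k} regions without replacement from a pool of "
            f"{len(add_pool)}"
        )
    chosen = rng.choice(len(add_pool), size=k, replace=False)
    regions = list(rs.regions) + [add_pool[int(i)] for i in chosen]
    return rs.derive(regions)


def cut_regions(
    rs: RegionSet,
    rate: float,
    rng: Union[None, int, RandomSource] = None,
) -> RegionSet:
    """Split k regions at their midpoint (floor division) into two halves.

    Only regions of length >= 2 are eligible (a 1 bp region cannot be cut);
    if fewer than k are eligible an error reports the eligible count. Total
    covered bases are conserved.
    """
    rng = ensure_rng(rng)
    k = perturbed_count(rate, len(rs))
    if k == 0:
        return rs.derive(rs.regions)
    eligible = [i for i, r in enumerate(rs) if r.length >= 2]
    if k > len(eligible):
        raise ValidationError(
            f"cannot cut {k} regions: only {len(eligible)} have length >= 2"
        )
    chosen = set(
        int(eligible[int(i)]) for i in rng.choice(len(eligible), size=k, replace=False)
    )
    regions: list[GenomicRegion] = []
    for i, r in enumerate(rs):
        if i in chosen:
            mid = (r.start + r.end) // 2
            regions.append(GenomicRegion(r.chrom, r.start, mid))
            regions.append(GenomicRegion(r.chrom, mid, r.end))
        else:
            regions.append(r)
    return rs.derive(regions)


def merge_regions(
    rs: RegionSet,
    rate: float,
    rng: Union[None, int, RandomSource] = None,
) -> RegionSet:
    """Merge k regions with their next same-chromosome neighbour.

    The set is viewed sorted by (chrom, start); a selected region and its
    successor are replaced by one region spanning from the first's start to
    the second's end. A region already consumed by a merge in the same pass
    is not selected again (no chained merges). If fewer eligible positions
    than k exist, as many merges as possible are performed and the shortfall
    is logged. The result is returned in sorted order.
    """
    rng = ensure_rng(rng)
    n = len(rs)
    k = perturbed_count(rate, n)
    if k == 0 or n < 2:
        return rs.derive(rs.regions)
    ordered = rs.sorted_regions()
    eligible = [
        i for i in range(n - 1) if ordered[i].chrom == ordered[i + 1].chrom
    ]
    order = rng.permutation(len(eligible))
    consumed: set[int] = set()
    merge_at: list[int] = []
    for oi in order:
        if len(merge_at) == k:
            break
        i = eligible[int(oi)]
        if i in consumed or i + 1 in consumed:
            continue
        merge_at.append(i)
        consumed.update((i, i + 1))
    if len(merge_at) < k:
        logger.warning(
            "merge: only %d of %d requested merges possible", len(merge_at), k
        )
    starts_merge = set(merge_at)
    skip = {i + 1 for i in merge_at}
    regions: list[GenomicRegion] = []
    for i, r in enumerate(ordered):
        if i in skip:
            continue
        if i in starts_merge:
            nxt = ordered[i + 1]
            regions.append(GenomicRegion(r.chrom, r.start, max(r.end, nxt.end)))
        else:
            regions.append(r)
    return rs.derive(regions)


def drop_regions(
    rs: RegionSet,
    rate: float,
    rng: Union[None, int, RandomSource] = None,
    candidates: Optional[RegionSet] = None,
) -> RegionSet:
    """Remove k regions chosen uniformly without replacement.

    With ``candidates`` given, only regions intersecting the candidate file
    are considered for dropping (k still computed from the full count).
    """
    rng = ensure_rng(rng)
    n = len(rs)
    k = perturbed_count(rate, n)
    if k == 0:
        return rs.derive(rs.regions)
    pool = list(range(n)) if candidates is None else select_from_file(rs, candidates)
    if k > len(pool):
        raise ValidationError(
            f"cannot drop {k} regions: only {len(pool)} candidates available"
        )
    chosen = set(pool[int(i)] for i in rng.choice(len(pool), size=k, replace=False))
    regions = [r for i, r in enumerate(rs) if i not in chosen]
    return rs.derive(regions)


def all_perturbations(
    rs: RegionSet,
    plan: PerturbationPlan,
    chrom_sizes: Optional[ChromSizes] = None,
    rng: Union[None, int, RandomSource] = None,
) -> tuple[RegionSet, dict[str, int]]:
    """Apply the full plan in the fixed order shift -> add -> cut -> merge -> drop.

    Each operation's k is computed from the region count at the moment it
    runs, since each perturbation operates on the result of the previous one.
    Returns the final RegionSet and a log of per-operation counts.
    """
    plan.validate()
    if rng is None:
        rng = ensure_rng(plan.seed)
    else:
        rng = ensure_rng(rng)
    needs_sizes = plan.shift_rate > 0 or (plan.add_rate > 0 and plan.add_file is None)
    if needs_sizes and chrom_sizes is None:
        raise ValidationError(
            "shift and random add require a chromosome sizes table"
        )
    log: dict[str, int] = {}
    current = rs.derive(rs.regions)
    if plan.shift_rate > 0:
        log["shift"] = perturbed_count(plan.shift_rate, len(current))
        current = shift_regions(
            current,
            plan.shift_rate,
            plan.shift_mean,
            plan.shift_stdev,
            chrom_sizes,
            rng,
            candidates=_resolve_selector(plan.shift_file),
        )
    if plan.add_rate > 0:
        log["add"] = perturbed_count(plan.add_rate, len(current))
        add_pool = _resolve_selector(plan.add_file)
        if add_pool is not None:
            current = add_from_file(current, plan.add_rate, add_pool, rng)
        else:
            current = add_regions(
                current,
                plan.add_rate,
                plan.add_mean,
                plan.add_stdev,
                chrom_sizes,
                rng,
                valid_regions=_resolve_selector(plan.valid_regions),
            )
    if plan.cut_rate > 0:
        log["cut"] = perturbed_count(plan.cut_rate, len(current))
        current = cut_regions(current, plan.cut_rate, rng)
    if plan.merge_rate > 0:
        before = len(current)
        current = merge_regions(current, plan.merge_rate, rng)
        log["merge"] = before - len(current)
    if plan.drop_rate > 0:
        log["drop"] = perturbed_count(plan.drop_rate, len(current))
        current = drop_regions(
            current,
            plan.drop_rate,
            rng,
            candidates=_resolve_selector(plan.drop_file),
        )
    return current, log


def apply_config(
    rs: RegionSet,
    operations: Sequence[tuple[str, dict]],
    chrom_sizes: Optional[ChromSizes] = None,
    rng: Union[None, int, RandomSource] = None,
) -> tuple[RegionSet, dict[str, int]]:
    """Run an ordered list of (operation, params) entries from a YAML config.

    The listed order is executed exactly, overriding the default fixed order.
    An empty list is a no-op.
    """
    rng = ensure_rng(rng)
    current = rs.derive(rs.regions)
    log: dict[str, int] = {}
    for op, params in operations:
        rate = float(params.get("rate", 0.0))
        if op == "shift":
            if chrom_sizes is None:
                raise ValidationError("shift requires a chromosome sizes table")
            log[f"shift[{len(log)}]"] = perturbed_count(rate, len(current))
            current = shift_regions(
                current,
                rate,
                float(params.get("mean", 0.0)),
                float(params.get("stdev", 150.0)),
                chrom_sizes,
                rng,
                candidates=_resolve_selector(params.get("file")),
            )
        elif op == "add":
            log[f"add[{len(log)}]"] = perturbed_count(rate, len(current))
            pool = _resolve_selector(params.get("file"))
            if pool is not None:
                current = add_from_file(current, rate, pool, rng)
            else:
                if chrom_sizes is None:
                    raise ValidationError("random add requires a chromosome sizes table")
                current = add_regions(
                    current,
                    rate,
                    float(params.get("mean", 320.0)),
                    float(params.get("stdev", 20.0)),
                    chrom_sizes,
                    rng,
                    valid_regions=_resolve_selector(params.get("valid_regions")),
                )
        elif op == "cut":
            log[f"cut[{len(log)}]"] = perturbed_count(rate, len(current))
            current = cut_regions(current, rate, rng)
        elif op == "merge":
            before = len(current)
            current = merge_regions(current, rate, rng)
            log[f"merge[{len(log)}]"] = before - len(current)
        elif op == "drop":
            log[f"drop[{len(log)}]"] = perturbed_count(rate, len(current))
            current = drop_regions(
                current, rate, rng, candidates=_resolve_selector(params.get("file"))
            )
        else:
            raise ValidationError(f"unknown operation {op!r}")
    return current, log


def run_replicates(
    rs: RegionSet,
    plan: PerturbationPlan,
    n: int,
    chrom_sizes: Optional[ChromSizes] = None,
    outdir: Union[str, Path] = ".",
    stem: Optional[str] = None,
) -> list[Path]:
    """Write n independently perturbed files, each starting from the original
    snapshot. With ``plan.seed`` set, replicate i is reproducible across runs
    (its stream derives from (seed, i)). Filenames carry a 1-based replicate
    index."""
    if n < 1:
        raise ValidationError(f"replicate count must be >= 1, got {n}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = default_output_path(rs.source).stem if rs.source else "perturbed_regions"
    paths: list[Path] = []
    for i in range(n):
        if plan.seed is not None:
            rng = np.random.default_rng([plan.seed, i])
        else:
            rng = np.random.default_rng()
        perturbed, _ = all_perturbations(rs.original_set(), plan, chrom_sizes, rng)
        path = outdir / f"{stem}_rep{i + 1}.bed"
        write_bed(perturbed, path)
        paths.append(path)
    return paths
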