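"""Reading and writing BED files, chrom.sizes tables, and YAML run configs.

Only the first three BED columns (chrom, start, end) are retained: perturbation
creates regions with no source metadata, so extra columns are dropped loudly on
read rather than half-preserved. Track/browser/comment lines are skipped and
not written back.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .regions import ChromSizes, GenomicRegion, RegionSet, ValidationError

#: Prefix used for default output names when no explicit path is given.
DEFAULT_PREFIX = "perturbed_"

#: Operation names accepted in YAML configs, mapped to their rate semantics.
KNOWN_OPERATIONS = ("shift", "add", "cut", "merge", "drop")


class BedParseError(ValidationError):
    """A malformed line in a BED or chrom.sizes file, with its line number."""


def _is_header(line: str) -> bool:
    return line.startswith(("track", "browser", "#"))


def read_bed(path: Union[str, Path]) -> RegionSet:
    """Read a BED file into a :class:`RegionSet` (first three columns only).

    Header lines beginning with ``track``, ``browser`` or ``#`` are skipped.
    Raises :class:`BedParseError` naming the offending line for non-integer
    coordinates, missing columns, or zero/negative-length regions.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or _is_header(line):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}, {end_s!r}"
                ) from None
            try:
                regions.append(GenomicRegion(chrom, start, end))
            except ValidationError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
    return RegionSet(regions, source=path)


def default_output_path(input_path: Union[str, Path], outdir: Optional[Union[str, Path]] = None) -> Path:
    """Default output name: input basename prefixed with ``perturbed_``."""
    input_path = Path(input_path)
    directory = Path(outdir) if outdir is not None else input_path.parent
    return directory / (DEFAULT_PREFIX + input_path.name)


def write_bed(rs: RegionSet, path: Union[str, Path]) -> Path:
    """Write a RegionSet as three tab-separated columns, one region per line."""
    path = Path(path)
    with open(path, "w") as fh:
        for region in rs:
            fh.write(region.to_line() + "\n")
    return path


def _read_fasta_lengths(path: Path) -> ChromSizes:
    from Bio import SeqIO

    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise ValidationError(f"duplicate sequence {record.id!r} in {path}")
        lengths[record.id] = len(record.seq)
    return ChromSizes(lengths)


def read_chrom_sizes(path: Union[str, Path]) -> ChromSizes:
    """Read chromosome lengths from a two-column chrom.sizes table or a FASTA.

    FASTA input (detected by a leading ``>``) is accepted by computing
    sequence lengths. Duplicate names and non-positive lengths are errors.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(">"):
            return _read_fasta_lengths(path)
        lengths: dict[str, int] = {}
        for lineno, raw in enumerate([first] + fh.readlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
            if name in lengths:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            if length <= 0:
                raise ValidationError(
                    f"{path}:{lineno}: non-positive length {length} for {name!r}"
                )
            lengths[name] = length
    return ChromSizes(lengths)


def read_config(path: Union[str, Path]) -> list[tuple[str, dict[str, Any]]]:
    """Read an ordered YAML perturbation config.

    The file holds a sequence of entries, each with an ``operation`` (one of
    shift/add/cut/merge/drop), a ``rate``, and optional parameters
    (mean/stdev/file/valid_regions). The listed order is preserved exactly —
    this is the one entry point that overrides the default fixed order.

    Accepted layouts::

        - operation: drop
          rate: 0.1
        - operation: add
          rate: 0.2

    or the same list nested under a top-level ``perturbations:`` key.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return []
    if isinstance(doc, dict) and "perturbations" in doc:
        doc = doc["perturbations"]
    if doc is None:
        return []
    if not isinstance(doc, list):
        raise ValidationError(f"{path}: expected a list of perturbation entries")
    plan: list[tuple[str, dict[str, Any]]] = []
    for i, entry in enumerate(doc):
        if not isinstance(entry, dict) or "operation" not in entry:
            raise ValidationError(f"{path}: entry {i} lacks an 'operation' key")
        op = entry["operation"]
        if op not in KNOWN_OPERATIONS:
            raise ValidationError(
                f"{path}: unknown operation {op!r} (expected one of {KNOWN_OPERATIONS})"
            )
        params = {k: v for k, v in entry.items() if k != "operation"}
        rate = params.get("rate", 0.0)
        if not isinstance(rate, (int, float)) or not 0.0 <= float(rate) <= 1.0:
            raise ValidationError(f"{path}: entry {i} rate {rate!r} outside [0, 1]")
        plan.append((op, params))
    return plan
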