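"""Desk-scale simulation study: parameter grid, replicates, and sensitivity.

The study perturbs one original region set under 36 parameter combinations of
shift, add, and drop (9 single-perturbation sets — 3 types at 3 levels — plus
27 pairwise combinations at 3 x 3 levels), with a fixed number of replicates
per combination, and scores every perturbed set against the original with the
four similarity metrics. Cut and merge are held at 0 for the study.

Sensitivity ("similarity score change") for a metric and a varying
perturbation is the replicate-mean score at the lowest level minus the mean at
the highest level. When a second perturbation is held constant, the difference
is computed at each of its three levels and the three differences averaged.

Adds are drawn from the universe file by default (the add pool), so the
vector metrics stay meaningful; fully random adds are available but are not
the study default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, all_scores
from .perturb import all_perturbations
from .regions import ChromSizes, PerturbationPlan, RegionSet, ValidationError
from .synth import SynthSpec, make_regions, make_universe

#: Study levels per perturbation type (low / moderate / high).
LEVELS: dict[str, tuple[float, ...]] = {
    "shift": (0.2, 0.5, 0.8),
    "add": (0.1, 0.2, 0.3),
    "drop": (0.1, 0.2, 0.3),
}

PERTURBATION_TYPES = ("shift", "add", "drop")

#: Default desk-scale study fixture sizes.
DEFAULT_N_REGIONS = 1000
DEFAULT_EXTRA_UNIVERSE = 15_000
DEFAULT_REPLICATES = 10
STUDY_CHROMOSOMES = (("chr1", 10_000_000), ("chr2", 10_000_000))


@dataclass(frozen=True)
class ParameterSet:
    """One grid cell: a label and shift/add/drop rates."""

    label: str
    shift_rate: float = 0.0
    add_rate: float = 0.0
    drop_rate: float = 0.0

    def rate(self, ptype: str) -> float:
        return getattr(self, f"{ptype}_rate")

    def to_plan(self, add_pool: Optional[RegionSet]) -> PerturbationPlan:
        return PerturbationPlan(
            shift_rate=self.shift_rate,
            add_rate=self.add_rate,
            drop_rate=self.drop_rate,
            add_file=add_pool if self.add_rate > 0 else None,
        )


def _label(parts: dict[str, float]) -> str:
    return "_".join(f"{p}{parts[p]:g}" for p in PERTURBATION_TYPES if p in parts)


def build_grid() -> list[ParameterSet]:
    """The 36-cell grid: 9 single-perturbation sets + 27 pairwise sets."""
    grid: list[ParameterSet] = []
    for ptype in PERTURBATION_TYPES:
        for level in LEVELS[ptype]:
            grid.append(
                ParameterSet(_label({ptype: level}), **{f"{ptype}_rate": level})
            )
    pairs = [("shift", "add"), ("shift", "drop"), ("add", "drop")]
    for p1, p2 in pairs:
        for l1 in LEVELS[p1]:
            for l2 in LEVELS[p2]:
                grid.append(
                    ParameterSet(
                        _label({p1: l1, p2: l2}),
                        **{f"{p1}_rate": l1, f"{p2}_rate": l2},
                    )
                )
    return grid


def read_grid_csv(path: Union[str, Path]) -> list[ParameterSet]:
    """Read a parameter grid from a CSV with columns
    sample_name, shift, add, drop."""
    df = pd.read_csv(path)
    required = {"sample_name", "shift", "add", "drop"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"grid CSV missing columns: {sorted(missing)}")
    return [
        ParameterSet(
            str(row.sample_name),
            shift_rate=float(row.shift),
            add_rate=float(row.add),
            drop_rate=float(row.drop),
        )
        for row in df.itertuples()
    ]


def default_study_inputs(
    seed: int = 0,
    n_regions: int = DEFAULT_N_REGIONS,
    extra_universe: int = DEFAULT_EXTRA_UNIVERSE,
) -> tuple[RegionSet, RegionSet, ChromSizes, SynthSpec]:
    """Synthetic study fixture: a non-self-overlapping original of 300 bp
    regions and a universe that is a strict superset of it.

    The universe deliberately dwarfs the query (16:1 by default), mirroring
    the relationship between a genome-wide regulatory-element catalog and a
    single experiment's peak file; vector-metric behaviour depends on this
    ratio (see docs)."""
    spec = SynthSpec(
        n_regions=n_regions,
        region_length=300,
        gap_length=700,
        chromosomes=list(STUDY_CHROMOSOMES),
        seed=seed,
    )
    original = make_regions(spec)
    universe = make_universe(original, extra=extra_universe, spec=spec)
    return original, universe, spec.chrom_sizes(), spec


def run_study(
    original: RegionSet,
    grid: Sequence[ParameterSet],
    replicates: int,
    universe: RegionSet,
    chrom_sizes: ChromSizes,
    add_pool: Optional[RegionSet] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Perturb ``original`` for every grid cell x replicate and score it.

    Returns a tidy table with one row per (parameter set, replicate, metric):
    columns label, shift, add, drop, replicate, metric, score. Each replicate
    starts from the original snapshot; its random stream derives from
    (seed, parameter-set index, replicate index), so any cell is reproducible
    in isolation. ``add_pool`` defaults to the universe.
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates}")
    if add_pool is None:
        add_pool = universe
    rows: list[dict] = []
    for ps_index, ps in enumerate(grid):
        plan = ps.to_plan(add_pool)
        for rep in range(replicates):
            rng = np.random.default_rng([seed, ps_index, rep])
            perturbed, _ = all_perturbations(
                original.original_set(), plan, chrom_sizes, rng
            )
            scores = all_scores(original, perturbed, universe)
            for metric, score in scores.items():
                rows.append(
                    {
                        "label": ps.label,
                        "shift": ps.shift_rate,
                        "add": ps.add_rate,
                        "drop": ps.drop_rate,
                        "replicate": rep,
                        "metric": metric,
                        "score": score,
                    }
                )
    return pd.DataFrame(rows)


def _mean_score(
    table: pd.DataFrame, metric: str, rates: dict[str, float]
) -> float:
    mask = table["metric"] == metric
    for ptype in PERTURBATION_TYPES:
        mask &= table[ptype] == rates.get(ptype, 0.0)
    sub = table[mask]
    if sub.empty:
        raise ValidationError(
            f"no rows for metric={metric} at rates {rates}; grid incomplete"
        )
    return float(sub["score"].mean())


def score_change(
    table: pd.DataFrame,
    metric: str,
    varying: str,
    held: Optional[str] = None,
) -> float:
    """Similarity score change: replicate-mean score at the lowest level of
    ``varying`` minus the mean at its highest level.

    With ``held`` given, the difference is computed at each of the held
    perturbation's three levels and the three differences are averaged.
    """
    if varying not in LEVELS:
        raise ValidationError(f"unknown perturbation type {varying!r}")
    lo, _, hi = LEVELS[varying]
    if held is None:
        return _mean_score(table, metric, {varying: lo}) - _mean_score(
            table, metric, {varying: hi}
        )
    if held not in LEVELS or held == varying:
        raise ValidationError(f"invalid held perturbation {held!r}")
    diffs = []
    for h in LEVELS[held]:
        diffs.append(
            _mean_score(table, metric, {varying: lo, held: h})
            - _mean_score(table, metric, {varying: hi, held: h})
        )
    return float(np.mean(diffs))


def sensitivity_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """4 x 3 matrix of score changes: metrics as rows, perturbations as columns.

    Each entry averages the varying-alone scenario with the two held-constant
    scenarios for that perturbation, condensing the nine study scenarios.
    """
    data = {}
    for ptype in PERTURBATION_TYPES:
        others = [p for p in PERTURBATION_TYPES if p != ptype]
        col = []
        for metric in METRIC_NAMES:
            changes = [score_change(table, metric, ptype)]
            changes += [score_change(table, metric, ptype, held=o) for o in others]
            col.append(float(np.mean(changes)))
        data[ptype] = col
    return pd.DataFrame(data, index=list(METRIC_NAMES))


def universe_sensitivity(
    original: RegionSet,
    universes: dict[str, RegionSet],
    chrom_sizes: ChromSizes,
    add_pool: RegionSet,
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Score the *same* perturbed sets against several universes.

    Add-only perturbations at the study levels are generated once (drawn from
    ``add_pool``), then every universe rescored against the identical files.
    Returns a tidy table with a ``universe`` column. Jaccard and coverage do
    not involve the universe, so their rows are bit-identical across
    universes by construction; only the vector metrics can differ.
    """
    rows: list[dict] = []
    for li, level in enumerate(LEVELS["add"]):
        plan = PerturbationPlan(add_rate=level, add_file=add_pool)
        for rep in range(replicates):
            rng = np.random.default_rng([seed, li, rep])
            perturbed, _ = all_perturbations(
                original.original_set(), plan, chrom_sizes, rng
            )
            for name, universe in universes.items():
                scores = all_scores(original, perturbed, universe)
                for metric, score in scores.items():
                    rows.append(
                        {
                            "universe": name,
                            "shift": 0.0,
                            "add": level,
                            "drop": 0.0,
                            "replicate": rep,
                            "metric": metric,
                            "score": score,
                        }
                    )
    return pd.DataFrame(rows)


def write_study_outputs(
    table: pd.DataFrame, outdir: Union[str, Path]
) -> tuple[Path, Path]:
    """Write scores.tsv (tidy score table) and sensitivity.tsv (4x3 matrix)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores_path = outdir / "scores.tsv"
    table.to_csv(scores_path, sep="\t", index=False)
    matrix = sensitivity_matrix(table)
    matrix_path = outdir / "sensitivity.tsv"
    matrix.to_csv(matrix_path, sep="\t", index_label="metric")
    return scores_path, matrix_path
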