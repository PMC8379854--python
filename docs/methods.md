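# Methods

## Coordinate model

All intervals are 0-based, half-open (`[start, end)`), the BED convention:
two regions overlap iff `max(starts) < min(ends)`, and book-ended regions
(`[0,10)`, `[10,20)`) share no base. Zero- and negative-length regions are
rejected on read and never produced by any operation. Only the first three
BED columns are kept; perturbation creates regions with no source metadata,
so extra columns are dropped on read rather than half-preserved, and
track/browser/comment lines are skipped and not written back. Chromosome
lengths come from a two-column `chrom.sizes` table (a FASTA is also accepted;
sequence lengths are computed).

## Perturbation operators

Every operation perturbs `k = round(rate * n)` regions — half-away-from-zero
rounding, floored at 0 — where `n` is the region count *at the moment the
operation runs*. The combined runner applies shift → add → cut → merge → drop
in that fixed order, each on the result of the previous, so e.g. add 0.2 then
drop 0.1 on a 1,000-region file drops `round(0.1 × 1200) = 120` regions. A
YAML config is the one entry point that overrides this order. Selection is
always uniform without replacement.

- **shift** (`mean = 0`, `sd = 150` bp by default): both endpoints of a
  selected region move by the same integer distance, drawn from
  `N(mean, sd)` and rounded to nearest — length is preserved exactly. A draw
  that would cross a chromosome end is redrawn (up to 100 times, then the
  region is left unshifted with a warning); redrawing, rather than clamping,
  keeps the realized distance distribution close to the nominal one.
- **add** (`mean = 320`, `sd = 20` bp): chromosome sampled with probability
  proportional to its length, start uniform along it, length rounded with a
  1 bp floor. If the region would cross the chromosome end the *start* is
  redrawn, not the length truncated, preserving the length distribution.
  With a candidate file, `k` regions are instead sampled without replacement
  from the file and appended verbatim; with a valid-regions mask, placement
  samples an interval proportional to its length and a start within it.
- **cut**: the split point is the midpoint, `floor((start+end)/2)`; only
  regions of length ≥ 2 are eligible. Cut conserves total covered bases.
- **merge**: on a (chrom, start)-sorted view, a selected region fuses with
  its next same-chromosome neighbour into `[first.start, second.end)`
  (the max of the two ends, in case the successor is nested). A pair
  consumed by one merge is excluded for the rest of the pass — no chained
  merges in one call. If fewer eligible positions than `k` exist, as many
  merges as possible are performed and the shortfall logged.
- **drop**: `k` regions removed. With a selector file, only regions
  intersecting it (≥ 1 bp) are candidates; requesting more than the
  candidate pool is an error rather than a silent partial drop.

Selector-file semantics are always ≥ 1 bp intersection, never exact match.

**Seeding.** One integer seed initializes a single PCG64 stream consumed in
operation order, so a whole plan is reproducible from one number:
`(input, plan, seed)` → byte-identical output files. Replicate `i` of a
repeated run derives its stream from `(seed, i)`; study cell `(p, r)` from
`(seed, p, r)` — any single replicate can be regenerated in isolation.

## Similarity metrics

- **Jaccard (region-count form).** `|A∩B|` is the number of region *pairs*
  (one from each set) sharing ≥ 1 bp, and `|A∪B| = |A| + |B| − |A∩B|`. This
  pair-count reading is what makes the metric an exact ruler for dropping:
  on an input with no intra-set overlaps, dropping `k` of `N` regions gives
  exactly `(N−k)/N`, independent of which regions were dropped. Heavily
  self-overlapping inputs can inflate the pair count past the region totals
  and drive the union non-positive; that degenerate case raises an error
  with a diagnostic rather than returning a junk score.
- **Coverage.** For each region in each file, the fraction of its bases
  covered by the *union* of the other file's regions; the two directional
  means are averaged. Computed natively with interval arithmetic
  (merge + prefix sums), verified against a per-base bitmap oracle.
- **Vector metrics.** Each set is cast against a universe (reference
  catalog) as a 0/1 vector, one bit per universe region, set on ≥ 1 bp
  overlap. Euclidean similarity is `1 − ‖a−b‖/√d` with `d` the universe
  size — √d is the distance between an all-zeros and an all-ones vector, so
  the normalizer adapts to whatever universe is supplied instead of
  hard-coding one catalog's constant. Cosine is the plain cosine, 1 for
  identical non-empty vectors; both raise on empty/zero inputs.

Overlap counting uses sorted-coordinate binary searches (the identity
`#overlaps = #(starts < e) − #(ends ≤ s)` for a half-open query `[s, e)`);
any correct counter is equivalent, and equivalence with an O(n·m)
nested-loop oracle is asserted over randomized instances in the tests.

## The sensitivity study

The grid holds 36 parameter sets: shift ∈ {0.2, 0.5, 0.8} and
add, drop ∈ {0.1, 0.2, 0.3}, as 9 single-perturbation sets (3 types × 3
levels) and 27 pairwise sets (3 type-pairs × 3 × 3 levels); cut and merge
stay at 0. Each set is replicated 10 times from the original snapshot and
scored against the original with all four metrics (1,440 scores). Study adds
are drawn from the universe file so the vector metrics remain meaningful;
fully random adds are available but not the study default.

*Sensitivity* (similarity score change) of a metric to a varying
perturbation is the replicate-mean score at its lowest level minus the mean
at its highest level; when a second perturbation is held constant the
difference is computed at each of its three levels and the three differences
averaged. The 4 × 3 sensitivity matrix entry for (metric, perturbation)
averages the varying-alone scenario with the two held-constant scenarios.

## Synthetic fixtures

The generator lays `n` regions left-to-right with fixed gaps, which makes
the set mutually non-overlapping by construction — the regime in which the
Jaccard drop law is exact. The study default is 1,000 regions of 300 bp
(typical of transcription-factor ChIP-seq peaks) with 700 bp gaps on a
two-chromosome toy genome; unit fixtures default to 1 Mb chromosomes, the
study uses 10 Mb ones to leave room for the universe.

The default universe is a strict superset of the query: one universe region
per query region plus 15,000 extra disjoint regions (16,000 total, 16:1
universe:query). The ratio is deliberate, mirroring a genome-wide
regulatory-element catalog against a single experiment's peak file. It is
also what the Euclidean metric's behaviour hinges on: its sensitivity scales
as √(changed bits)/√d, so a universe that dwarfs the query makes Euclidean
the least sensitive metric overall, as observed on real catalogs; with a
small universe (a few times the query) that ordering inverts against cosine.
Subset universes keep a stated fraction of the query-overlapping regions
while retaining the extras — a catalog that only partially encapsulates the
query.

**What the fixture does and does not emulate.** Regular spacing, constant
region length and disjointness are idealizations: real peak files have
length dispersion, clustering, and occasional self-overlap. Passing tests
therefore demonstrate the metrics' behaviour under controlled divergence,
not their values on any real dataset; on real data the drop law holds only
as exactly as the input is free of intra-set overlap, and shift sensitivity
scales inversely with region length (smaller regions lose overlap sooner
for the same shift distances).

**Universe dependence of the vector metrics.** On these fully nested
synthetic subsets, cosine is exactly scale-free under drop and shift: both
vectors thin proportionally, so the score is unchanged by universe size
(cosine ignores dimensions that are zero in both vectors, which is also why
it is stable where Euclidean distance is not when universes diverge from the
data). The universe effect therefore expresses through the *add* channel:
added regions light up a fixed number of extra universe bits while the
query-overlapping base shrinks, so the proportion of changing components —
and with it both Euclidean and cosine sensitivity — grows strictly as the
universe's coverage of the query falls. The universe-comparison experiment
accordingly measures add-varying sensitivity on identical perturbed files
rescored under each universe; Jaccard and coverage never touch the universe
and are bit-identical across them by construction.

## Numerical and design choices

- `k = round(rate × n)` half away from zero: a fixed convention so count
  contracts are exact and testable.
- Rates bind to the current count, not the original; the two readings agree
  on the canonical shift-then-add example, and the sequential-state reading
  is the one consistent with each operation acting on its predecessor's
  output.
- Midpoint cut uses floor division; odd-length regions split into
  `ceil`/`floor` halves deterministically.
- Empty-set conventions: every metric raises on empty input rather than
  returning a sentinel; `read_bed` of an empty file is a valid empty set.
- Default output naming: input basename prefixed with `perturbed_` when no
  output path is given.
- Desk-scale defaults (1,000 regions, 16,000-region universe, 10
  replicates) keep the full study in the tens of seconds while preserving
  every qualitative ordering.

## Known limitations

- Strand is ignored entirely (columns beyond the third are dropped), so
  strand-aware perturbations and metrics are out of reach.
- Merge can create very large regions by bridging distant same-chromosome
  neighbours; this is inherent to the operation's definition.
- The pair-count Jaccard is not the base-level Jaccard computed by some
  interval toolkits; the two disagree whenever overlaps are partial.
- Shift iterates per selected region (redraw loop); it is the slowest
  operation at very large n, though irrelevant at desk scale.
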