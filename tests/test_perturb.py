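import hashlib

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bedperturb as bp
from tests.conftest import random_region_set


def merged_coverage(rs):
    """Union of covered bases, for merge monotonicity checks."""
    from bedperturb._intervals import by_chrom, merge_intervals

    return sum(
        int((m[:, 1] - m[:, 0]).sum())
        for m in (merge_intervals(a) for a in by_chrom(rs).values())
    )


@pytest.fixture
def big_set(chrom_sizes):
    spec = bp.SynthSpec(n_regions=1000, region_length=300, gap_length=700, seed=3)
    return bp.make_regions(spec)


class TestCounts:
    @given(st.floats(0, 1), st.integers(0, 5000))
    def test_rounding_half_away_from_zero(self, rate, n):
        k = bp.perturbed_count(rate, n)
        assert 0 <= k <= n + 1
        assert abs(k - rate * n) <= 0.5 + 1e-9

    @pytest.mark.parametrize(
        "rate,n,expected", [(0.4, 1000, 400), (0.1, 1005, 101), (0.0, 10, 0), (1.0, 7, 7)]
    )
    def test_exact_counts(self, rate, n, expected):
        assert bp.perturbed_count(rate, n) == expected


class TestShift:
    def test_moves_exactly_k_leaving_rest_untouched(self, big_set, chrom_sizes):
        out = bp.shift_regions(big_set, 0.4, 50, 10, chrom_sizes, rng=1)
        assert len(out) == len(big_set)
        moved = sum(a != b for a, b in zip(big_set, out))
        # mean 50 sd 10: a zero-distance draw is ~a 6-sigma event, so all
        # 400 selected regions actually move
        assert moved == 400

    def test_rate_zero_is_identity(self, big_set, chrom_sizes):
        assert bp.shift_regions(big_set, 0.0, 0, 150, chrom_sizes, rng=1) == big_set

    def test_preserves_length_multiset(self, big_set, chrom_sizes):
        out = bp.shift_regions(big_set, 0.7, 0, 150, chrom_sizes, rng=2)
        assert sorted(out.lengths()) == sorted(big_set.lengths())

    def test_respects_chromosome_bounds(self, chrom_sizes):
        edge = bp.RegionSet(
            [bp.GenomicRegion("chr1", 0, 50), bp.GenomicRegion("chr1", 999_950, 1_000_000)]
        )
        for seed in range(20):
            out = bp.shift_regions(edge, 1.0, 0, 100_000, chrom_sizes, rng=seed)
            for r in out:
                assert 0 <= r.start < r.end <= chrom_sizes[r.chrom]

    def test_missing_chromosome_is_an_error(self, big_set):
        with pytest.raises(bp.ValidationError, match="chr"):
            bp.shift_regions(big_set, 0.1, 0, 150, bp.ChromSizes({"chrX": 100}), rng=1)

    def test_candidates_restrict_selection(self, big_set, chrom_sizes):
        selector = bp.RegionSet(list(big_set)[:500])
        out = bp.shift_regions(
            big_set, 0.2, 5000, 100, chrom_sizes, rng=4, candidates=selector
        )
        for orig, new in zip(list(big_set)[500:], list(out)[500:]):
            assert orig == new


class TestAdd:
    def test_appends_exactly_k(self, big_set, chrom_sizes):
        out = bp.add_regions(big_set, 0.2, 320, 20, chrom_sizes, rng=1)
        assert len(out) == 1200
        assert list(out)[:1000] == list(big_set)

    def test_rate_zero_is_identity(self, big_set, chrom_sizes):
        assert bp.add_regions(big_set, 0.0, 320, 20, chrom_sizes, rng=1) == big_set

    def test_chromosome_odds_proportional_to_length(self):
        sizes = bp.ChromSizes({"chr1": 900_000, "chr2": 100_000})
        seedling = bp.RegionSet([bp.GenomicRegion("chr1", 0, 10)] * 10)
        out = bp.add_regions(seedling, 1000.0, 300, 10, sizes, rng=7)
        added = list(out)[10:]
        frac = sum(r.chrom == "chr1" for r in added) / len(added)
        se = np.sqrt(0.9 * 0.1 / len(added))
        assert abs(frac - 0.9) <= 3 * se

    def test_valid_regions_confine_placement(self, chrom_sizes):
        valid = bp.RegionSet([bp.GenomicRegion("chr2", 10_000, 20_000)])
        seedling = bp.RegionSet([bp.GenomicRegion("chr1", 0, 10)] * 10)
        out = bp.add_regions(
            seedling, 5.0, 100, 5, chrom_sizes, rng=3, valid_regions=valid
        )
        for r in list(out)[10:]:
            assert r.chrom == "chr2"
            assert 10_000 <= r.start < 20_000

    def test_empty_valid_regions_is_an_error(self, big_set, chrom_sizes):
        with pytest.raises(bp.ValidationError, match="empty"):
            bp.add_regions(
                big_set, 0.1, 320, 20, chrom_sizes, rng=1,
                valid_regions=bp.RegionSet([]),
            )


class TestAddFromFile:
    def test_added_rows_come_verbatim_from_pool(self, toy_set):
        pool = bp.RegionSet(
            [bp.GenomicRegion("chr2", i * 1000, i * 1000 + 100) for i in range(5)]
        )
        out = bp.add_from_file(toy_set, 2 / 3, pool, rng=1)
        assert len(out) == 5
        for r in list(out)[3:]:
            assert r in list(pool)

    def test_whole_pool_appended_when_k_equals_pool(self, toy_set):
        pool = bp.RegionSet([bp.GenomicRegion("chr2", 0, 10), bp.GenomicRegion("chr2", 20, 30)])
        out = bp.add_from_file(toy_set, 2 / 3, pool, rng=5)
        assert sorted(list(out)[3:]) == sorted(pool)

    def test_oversampling_pool_is_an_error(self, toy_set):
        pool = bp.RegionSet([bp.GenomicRegion("chr2", 0, 10)])
        with pytest.raises(bp.ValidationError, match="without replacement"):
            bp.add_from_file(toy_set, 1.0, pool, rng=1)


class TestCut:
    def test_midpoint_cut(self):
        rs = bp.RegionSet([bp.GenomicRegion("chr1", 0, 100)])
        out = bp.cut_regions(rs, 1.0, rng=1)
        assert out.regions == [
            bp.GenomicRegion("chr1", 0, 50),
            bp.GenomicRegion("chr1", 50, 100),
        ]

    def test_odd_length_uses_floor_midpoint(self):
        out = bp.cut_regions(bp.RegionSet([bp.GenomicRegion("chr1", 10, 15)]), 1.0, rng=1)
        assert out.regions == [
            bp.GenomicRegion("chr1", 10, 12),
            bp.GenomicRegion("chr1", 12, 15),
        ]

    def test_conserves_covered_bases_and_adds_k_regions(self, big_set):
        out = bp.cut_regions(big_set, 0.3, rng=2)
        assert len(out) == len(big_set) + 300
        assert out.total_bases() == big_set.total_bases()

    def test_one_bp_regions_are_ineligible(self):
        rs = bp.RegionSet(
            [bp.GenomicRegion("chr1", 0, 1), bp.GenomicRegion("chr1", 5, 6)]
        )
        with pytest.raises(bp.ValidationError, match="only 0"):
            bp.cut_regions(rs, 1.0, rng=1)


class TestMerge:
    def test_merges_with_next_same_chromosome_region(self):
        rs = bp.RegionSet(
            [bp.GenomicRegion("chr1", 0, 10), bp.GenomicRegion("chr1", 20, 30)]
        )
        out = bp.merge_regions(rs, 1.0, rng=1)
        assert out.regions == [bp.GenomicRegion("chr1", 0, 30)]

    def test_single_region_cannot_merge(self):
        rs = bp.RegionSet([bp.GenomicRegion("chr1", 0, 10)])
        assert bp.merge_regions(rs, 1.0, rng=1) == rs

    def test_cross_chromosome_pairs_never_merge(self):
        rs = bp.RegionSet(
            [bp.GenomicRegion("chr1", 0, 10), bp.GenomicRegion("chr2", 0, 10)]
        )
        assert len(bp.merge_regions(rs, 1.0, rng=1)) == 2

    def test_never_decreases_covered_bases(self, big_set):
        out = bp.merge_regions(big_set, 0.4, rng=3)
        assert merged_coverage(out) >= merged_coverage(big_set)
        assert len(out) == len(big_set) - 400

    def test_no_chained_merges_in_one_pass(self):
        # 4 regions, rate 1.0 -> at most 2 disjoint merges, never a chain
        rs = bp.RegionSet(
            [bp.GenomicRegion("chr1", i * 20, i * 20 + 10) for i in range(4)]
        )
        out = bp.merge_regions(rs, 1.0, rng=0)
        assert len(out) == 2
        assert all(r.length == 30 for r in out)


class TestDrop:
    def test_survivors_are_verbatim_subset(self, big_set):
        out = bp.drop_regions(big_set, 0.1, rng=1)
        assert len(out) == 900
        originals = set(big_set)
        assert all(r in originals for r in out)

    def test_rate_one_empties_the_set(self, toy_set):
        assert len(bp.drop_regions(toy_set, 1.0, rng=1)) == 0

    def test_drop_law_jaccard(self, big_set):
        out = bp.drop_regions(big_set, 0.3, rng=8)
        assert bp.jaccard_score(big_set, out) == pytest.approx(0.70, abs=1e-12)

    def test_dropfile_restricts_candidates(self, big_set):
        selector = bp.RegionSet(list(big_set)[:300])
        out = bp.drop_regions(big_set, 0.2, rng=2, candidates=selector)
        survivors = set(out)
        # every region outside the selector must survive
        assert all(r in survivors for r in list(big_set)[300:])


class TestSelectFromFile:
    def test_identical_selector_selects_all(self, toy_set):
        assert bp.select_from_file(toy_set, toy_set) == [0, 1, 2]

    def test_disjoint_selector_selects_none(self, toy_set):
        sel = bp.RegionSet([bp.GenomicRegion("chr2", 0, 10)])
        assert bp.select_from_file(toy_set, sel) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rs = random_region_set(rng, 40)
        sel = random_region_set(rng, 15)
        expected = [
            i for i, r in enumerate(rs) if any(r.overlaps(s) for s in sel)
        ]
        assert bp.select_from_file(rs, sel) == expected


class TestAllPerturbations:
    def test_shift_and_add_counts(self, big_set, chrom_sizes):
        plan = bp.PerturbationPlan(shift_rate=0.4, add_rate=0.2, seed=1)
        out, log = bp.all_perturbations(big_set, plan, chrom_sizes)
        assert log == {"shift": 400, "add": 200}
        assert len(out) == 1200

    def test_all_zero_rates_is_identity(self, big_set, chrom_sizes):
        plan = bp.PerturbationPlan(seed=1)
        out, log = bp.all_perturbations(big_set, plan, chrom_sizes)
        assert out == big_set and log == {}

    def test_rates_apply_to_current_count(self, big_set, chrom_sizes):
        # add 0.2 (k=200 on 1000), then drop 0.1 computed on 1200 -> 120
        plan = bp.PerturbationPlan(add_rate=0.2, drop_rate=0.1, seed=1)
        out, log = bp.all_perturbations(big_set, plan, chrom_sizes)
        assert log["add"] == 200 and log["drop"] == 120
        assert len(out) == 1080

    def test_shift_without_sizes_is_an_error(self, big_set):
        plan = bp.PerturbationPlan(shift_rate=0.4, seed=1)
        with pytest.raises(bp.ValidationError, match="sizes"):
            bp.all_perturbations(big_set, plan, None)

    def test_yaml_order_overrides_default(self, big_set, chrom_sizes):
        # drop first (k=100 on 1000), then add 0.2 on 900 -> 180
        out, log = bp.apply_config(
            big_set,
            [("drop", {"rate": 0.1}), ("add", {"rate": 0.2})],
            chrom_sizes,
            rng=1,
        )
        assert len(out) == 1080
        assert list(log.values()) == [100, 180]

    def test_bounds_respected_end_to_end(self, big_set, chrom_sizes):
        plan = bp.PerturbationPlan(
            shift_rate=0.5, add_rate=0.3, cut_rate=0.2, merge_rate=0.1,
            drop_rate=0.1, seed=5,
        )
        out, _ = bp.all_perturbations(big_set, plan, chrom_sizes)
        for r in out:
            assert 0 <= r.start < r.end <= chrom_sizes[r.chrom]


class TestReproducibility:
    def _digest(self, paths):
        h = hashlib.sha256()
        for p in sorted(paths):
            h.update(p.read_bytes())
        return h.hexdigest()

    def test_same_seed_gives_byte_identical_replicates(self, big_set, chrom_sizes, tmp_path):
        plan = bp.PerturbationPlan(
            shift_rate=0.3, add_rate=0.2, drop_rate=0.1, seed=42
        )
        a = bp.run_replicates(big_set, plan, 3, chrom_sizes, tmp_path / "a", stem="x")
        b = bp.run_replicates(big_set, plan, 3, chrom_sizes, tmp_path / "b", stem="x")
        assert self._digest(a) == self._digest(b)

    def test_replicates_start_from_original_snapshot(self, big_set, chrom_sizes, tmp_path):
        plan = bp.PerturbationPlan(drop_rate=0.1, seed=1)
        paths = bp.run_replicates(big_set, plan, 10, chrom_sizes, tmp_path, stem="r")
        assert len(paths) == 10
        for p in paths:
            assert len(bp.read_bed(p)) == 900

    def test_different_replicates_differ(self, big_set, chrom_sizes, tmp_path):
        plan = bp.PerturbationPlan(drop_rate=0.1, seed=1)
        paths = bp.run_replicates(big_set, plan, 2, chrom_sizes, tmp_path, stem="d")
        assert paths[0].read_bytes() != paths[1].read_bytes()


class TestPlanValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"shift_rate": -0.1},
            {"drop_rate": 1.5},
            {"shift_stdev": 0},
            {"add_mean": -5},
            {"repeat": 0},
        ],
    )
    def test_invalid_plans_rejected(self, kwargs):
        with pytest.raises(bp.ValidationError):
            bp.PerturbationPlan(**kwargs)


@given(st.integers(0, 2**31 - 1))
def test_seeded_perturbation_is_deterministic(seed):
    spec = bp.SynthSpec(n_regions=50, region_length=100, gap_length=50, seed=0)
    rs = bp.make_regions(spec)
    sizes = spec.chrom_sizes()
    plan = bp.PerturbationPlan(shift_rate=0.4, add_rate=0.2, drop_rate=0.2, seed=seed)
    a, _ = bp.all_perturbations(rs, plan, sizes)
    b, _ = bp.all_perturbations(rs, plan, sizes)
    assert a.regions == b.regions


@given(st.floats(0, 1), st.integers(1, 60))
def test_cut_conserves_bases_for_any_rate(rate, n):
    spec = bp.SynthSpec(n_regions=n, region_length=(80, 30), gap_length=10, seed=4)
    rs = bp.make_regions(spec)
    eligible = sum(r.length >= 2 for r in rs)
    k = bp.perturbed_count(rate, n)
    if k > eligible:
        return
    out = bp.cut_regions(rs, rate, rng=1)
    assert out.total_bases() == rs.total_bases()
    assert len(out) == n + k
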