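from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from bsmethy.dmr import (
    DMRParams,
    _JoinedCalls,
    CandidateRegion,
    SeedRegion,
    call_dmrs,
    chi_square_region,
    classify_unchanged,
    dmrs_to_frame,
    extend_and_merge,
    find_next_seed,
    mann_whitney_u,
    merge_adjacent,
    valid_cpgs,
)

from conftest import cpg_grid_calls


def enumeration_p(xs, ys):
    """Brute-force two-sided permutation p with midranks (independent oracle)."""
    from scipy.stats import rankdata

    vals = list(xs) + list(ys)
    ranks = rankdata(vals)
    n, m = len(xs), len(ys)
    mean = n * m / 2
    obs = ranks[:n].sum() - n * (n + 1) / 2
    count = total = 0
    for idx in combinations(range(n + m), n):
        u = sum(ranks[i] for i in idx) - n * (n + 1) / 2
        total += 1
        count += abs(u - mean) >= abs(obs - mean) - 1e-9
    return count / total


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([0] * 5, [100] * 5)
        assert u == 0.0
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_constant_groups(self):
        _, p = mann_whitney_u([50] * 5, [50] * 5)
        assert p == 1.0

    @pytest.mark.parametrize(
        "xs,ys",
        [
            ([10, 20, 30], [15, 25, 35]),
            ([0, 0, 50, 100], [50, 100, 100]),
            ([1, 2, 3, 4, 5], [3, 4, 5, 6, 7]),
        ],
    )
    def test_small_samples_match_enumeration_oracle(self, xs, ys):
        _, p = mann_whitney_u(xs, ys)
        assert p == pytest.approx(enumeration_p(xs, ys), abs=1e-12)

    def test_large_samples_use_corrected_normal(self):
        rng = np.random.default_rng(2)
        xs = rng.integers(0, 100, 15).tolist()
        ys = rng.integers(20, 120, 15).tolist()
        from scipy import stats

        _, p = mann_whitney_u(xs, ys)
        ref = stats.mannwhitneyu(xs, ys, alternative="two-sided", use_continuity=True).pvalue
        assert p == pytest.approx(float(ref))


class TestChiSquare:
    def test_hand_computed_statistic(self):
        chi2, p = chi_square_region((90, 10), (10, 90))
        assert chi2 == pytest.approx(128.0)
        assert p < 1e-20

    def test_identical_proportions(self):
        assert chi_square_region((50, 50), (50, 50)) == (0.0, 1.0)

    def test_zero_marginal_guard(self):
        assert chi_square_region((0, 0), (5, 5))[1] == 1.0
        assert chi_square_region((5, 5), (0, 0))[1] == 1.0
        assert chi_square_region((5, 0), (5, 0))[1] == 1.0


class TestValidCpgs:
    def test_depth_threshold_in_both_samples(self):
        a = cpg_grid_calls([100, 200, 300], [5, 2, 5], depth=5)
        b = pd.concat(
            [
                cpg_grid_calls([100, 200], [50, 50], depth=100),
                cpg_grid_calls([300], [2], depth=4),
            ]
        )
        out = valid_cpgs(a, b, ("chr1", 1, 1000), n=5)
        # 100: depth (5,100) ok; 200: ok; 300: depth 4 in b -> excluded
        assert list(out["pos"]) == [100, 200]

    def test_empty_interval(self):
        a = cpg_grid_calls([100], [5])
        out = valid_cpgs(a, a, ("chr1", 500, 600), n=5)
        assert len(out) == 0

    def test_increasing_n_never_adds_sites(self):
        rng = np.random.default_rng(3)
        pos = np.arange(50, 2000, 40)
        a = cpg_grid_calls(pos, rng.integers(0, 10, len(pos)), depth=12)
        b = cpg_grid_calls(pos, rng.integers(0, 8, len(pos)), depth=9)
        counts = [len(valid_cpgs(a, b, ("chr1", 1, 2000), n=n)) for n in range(1, 12)]
        assert counts == sorted(counts, reverse=True)


def two_sample_fixture(
    positions, mds_a, mds_b, depth=10, chrom_len=None
):
    """Call tables with exact per-site MDs (depth divides the MD)."""
    c_a = [round(md / 100 * depth) for md in mds_a]
    c_b = [round(md / 100 * depth) for md in mds_b]
    return (
        cpg_grid_calls(positions, c_a, depth=depth),
        cpg_grid_calls(positions, c_b, depth=depth),
    )


class TestSeedSearch:
    def test_slides_until_enough_valid_cpgs(self):
        # window [1,500] holds 4 CpGs; [101,600] holds 5
        positions = [150, 250, 350, 450, 550]
        a, b = two_sample_fixture(positions, [100] * 5, [0] * 5)
        params = DMRParams()
        joined = _JoinedCalls(a, b, params)
        seed = find_next_seed(joined, "chr1", 1, 2000, params)
        assert seed.start == 101 and seed.end == 600

    def test_first_window_valid_returned_unmoved(self):
        positions = [50, 150, 250, 350, 450]
        a, b = two_sample_fixture(positions, [100] * 5, [0] * 5)
        params = DMRParams()
        joined = _JoinedCalls(a, b, params)
        seed = find_next_seed(joined, "chr1", 1, 2000, params)
        assert seed.start == 1

    def test_no_cpgs_returns_none(self):
        a, b = two_sample_fixture([50], [100], [0])
        params = DMRParams()
        joined = _JoinedCalls(a, b, params)
        assert find_next_seed(joined, "chr2", 1, 5000, params) is None


class TestExtension:
    def test_extension_stops_after_length_exceeds_k(self):
        # four consecutive qualifying 500-bp windows; extension is tested
        # only while the region is <= k=1000, so the result spans 1500
        positions = list(range(50, 2000, 80))
        a, b = two_sample_fixture(positions, [100] * len(positions), [0] * len(positions))
        params = DMRParams()
        joined = _JoinedCalls(a, b, params)
        seed = find_next_seed(joined, "chr1", 1, 2500, params)
        cand = extend_and_merge(seed, joined, 2500, params)
        assert (cand.start, cand.end) == (1, 1500)
        assert cand.direction == "hypo"  # sample 2 lower than sample 1

    def test_non_significant_next_window_stops_extension(self):
        positions = list(range(50, 1000, 80))
        mds_a = [100 if p <= 500 else 50 for p in positions]
        mds_b = [0 if p <= 500 else 50 for p in positions]
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        params = DMRParams()
        joined = _JoinedCalls(a, b, params)
        seed = find_next_seed(joined, "chr1", 1, 2000, params)
        cand = extend_and_merge(seed, joined, 2000, params)
        assert (cand.start, cand.end) == (1, 500)

    def test_opposite_direction_stops_extension(self):
        positions = list(range(50, 1000, 80))
        mds_a = [100 if p <= 500 else 0 for p in positions]
        mds_b = [0 if p <= 500 else 100 for p in positions]
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        params = DMRParams()
        joined = _JoinedCalls(a, b, params)
        seed = find_next_seed(joined, "chr1", 1, 2000, params)
        cand = extend_and_merge(seed, joined, 2000, params)
        assert (cand.start, cand.end) == (1, 500)


class TestMerging:
    def _joined(self, positions, mds_a, mds_b):
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        return _JoinedCalls(a, b, DMRParams())

    def test_nearby_similar_regions_merge(self):
        positions = list(range(50, 500, 80)) + list(range(1350, 1800, 80))
        n1 = sum(1 for p in positions if p < 500)
        mds_a = [100] * len(positions)
        mds_b = [0] * len(positions)
        joined = self._joined(positions, mds_a, mds_b)
        regions = [
            CandidateRegion("chr1", 1, 500, "hypo", 0.005),
            CandidateRegion("chr1", 1301, 1800, "hypo", 0.007),  # gap 800
        ]
        merged = merge_adjacent(regions, joined, DMRParams())
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (1, 1800)

    def test_gap_over_limit_not_merged(self):
        positions = list(range(50, 500, 80)) + list(range(1750, 2200, 80))
        joined = self._joined(positions, [100] * len(positions), [0] * len(positions))
        regions = [
            CandidateRegion("chr1", 1, 500, "hypo", 0.005),
            CandidateRegion("chr1", 1701, 2200, "hypo", 0.007),  # gap 1200
        ]
        assert len(merge_adjacent(regions, joined, DMRParams())) == 2

    def test_md_difference_blocks_merge(self):
        positions = list(range(50, 500, 80)) + list(range(1050, 1500, 80))
        n1 = sum(1 for p in positions if p < 500)
        n2 = len(positions) - n1
        # sample A: 100% in region 1 vs 80% in region 2 (diff 20 >= 10)
        mds_a = [100] * n1 + [80] * n2
        mds_b = [0] * len(positions)
        joined = self._joined(positions, mds_a, mds_b)
        regions = [
            CandidateRegion("chr1", 1, 500, "hypo", 0.005),
            CandidateRegion("chr1", 1001, 1500, "hypo", 0.007),  # gap 500
        ]
        assert len(merge_adjacent(regions, joined, DMRParams())) == 2

    def test_opposite_directions_not_merged(self):
        positions = list(range(50, 500, 80)) + list(range(1050, 1500, 80))
        joined = self._joined(positions, [100] * len(positions), [0] * len(positions))
        regions = [
            CandidateRegion("chr1", 1, 500, "hypo", 0.005),
            CandidateRegion("chr1", 1001, 1500, "hyper", 0.007),
        ]
        assert len(merge_adjacent(regions, joined, DMRParams())) == 2


class TestCallDmrs:
    def test_single_planted_block_found_exactly(self):
        # 1-kb block at [2001, 3000] where sample B is ~0% vs sample A ~100%,
        # 1 CpG per 50 bp, depth 10; background identical in both samples
        positions = list(range(25, 5000, 50))
        mds_a = [100.0] * len(positions)
        mds_b = [0.0 if 2001 <= p <= 3000 else 100.0 for p in positions]
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        dmrs = call_dmrs(a, b, DMRParams(), chrom_lengths={"chr1": 5000})
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hypo"
        # the call overlaps the block substantially; boundaries may be off
        # by up to one window because seeds live on the 100-bp slide grid
        overlap = min(d.end, 3000) - max(d.start, 2001) + 1
        assert overlap >= 800
        assert d.end - d.start + 1 <= 2000
        assert d.chi2_p <= 0.01
        assert d.md1 > d.md2

    def test_identical_samples_give_no_dmrs(self):
        positions = list(range(25, 3000, 50))
        a, b = two_sample_fixture(positions, [70.0] * len(positions), [70.0] * len(positions))
        assert call_dmrs(a, b, DMRParams()) == []

    def test_too_few_cpgs_per_window_gives_no_dmrs(self):
        # 4 CpGs per 500-bp window < m=5
        positions = list(range(60, 3000, 125))
        mds_a = [100.0] * len(positions)
        mds_b = [0.0] * len(positions)
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        assert call_dmrs(a, b, DMRParams()) == []

    def test_sample_swap_symmetry(self):
        rng = np.random.default_rng(17)
        positions = list(range(40, 8000, 70))
        mds_a = [100.0] * len(positions)
        mds_b = [50.0 if 3001 <= p <= 4000 else 100.0 for p in positions]
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        fwd = call_dmrs(a, b, DMRParams(), chrom_lengths={"chr1": 8000})
        rev = call_dmrs(b, a, DMRParams(), chrom_lengths={"chr1": 8000})
        assert len(fwd) == len(rev) >= 1
        flip = {"hyper": "hypo", "hypo": "hyper"}
        for df, dr in zip(fwd, rev):
            assert (df.start, df.end) == (dr.start, dr.end)
            assert dr.direction == flip[df.direction]
            assert df.chi2_p == pytest.approx(dr.chi2_p)
            assert (df.md1, df.md2) == (dr.md2, dr.md1)

    def test_emitted_dmr_invariants(self):
        positions = list(range(30, 6000, 60))
        mds_a = [90.0] * len(positions)
        mds_b = [10.0 if 2001 <= p <= 3200 else 90.0 for p in positions]
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        params = DMRParams()
        for d in call_dmrs(a, b, params, chrom_lengths={"chr1": 6000}):
            assert d.end - d.start + 1 >= params.w
            assert d.chi2_p <= params.p_region
            assert (d.direction == "hyper") == (d.md2 > d.md1)

    def test_dmrs_to_frame_columns(self):
        positions = list(range(25, 3000, 50))
        mds_a = [100.0] * len(positions)
        mds_b = [0.0] * len(positions)
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        frame = dmrs_to_frame(call_dmrs(a, b, DMRParams()))
        assert list(frame.columns) == [
            "chrom", "start", "end", "direction", "md1", "md2",
            "C1", "T1", "C2", "T2", "mw_p", "chi2", "chi2_p",
        ]
        assert len(frame) >= 1


class TestClassifyUnchanged:
    def test_identical_vectors_unchanged(self):
        positions = [100, 200, 300, 400, 480]
        a, b = two_sample_fixture(positions, [70] * 5, [70] * 5)
        assert classify_unchanged(("chr1", 1, 500), a, b) is True

    def test_fully_separated_not_unchanged(self):
        positions = [100, 200, 300, 400, 480]
        a, b = two_sample_fixture(positions, [100] * 5, [0] * 5)
        assert classify_unchanged(("chr1", 1, 500), a, b) is False

    def test_midgrade_overlap_neither_unchanged_nor_dmr(self):
        positions = [100, 200, 300, 400, 480]
        mds_a = [40, 60, 80, 90, 100]
        mds_b = [10, 30, 50, 70, 90]
        p = enumeration_p(mds_a, mds_b)
        assert 0.01 < p < 0.25  # fixture sits between the two thresholds
        a, b = two_sample_fixture(positions, mds_a, mds_b)
        assert classify_unchanged(("chr1", 1, 500), a, b) is False

    def test_too_few_valid_cpgs_rejected(self):
        a, b = two_sample_fixture([100, 200], [50, 50], [50, 50])
        with pytest.raises(ValueError):
            classify_unchanged(("chr1", 1, 500), a, b)
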