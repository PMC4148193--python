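"""Hi-C aggregation profiles, pair selection, overlap counts, rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import insulator_bridge as ib
from insulator_bridge import hic
from insulator_bridge.errors import ConfigError, InputError


def make_table(records, bin_size=500, genome=None):
    df = pd.DataFrame(records, columns=["chrom", "bin_i", "bin_j", "count"])
    return ib.ContactTable(bin_size=bin_size, df=df,
                           genome=genome or {"chr1": 1_000_000})


class TestPeakSet:
    def test_sorted_and_validated(self):
        ps = ib.PeakSet("x", [("chr2", 50, 60), ("chr1", 10, 20), ("chr1", 0, 5)])
        assert ps.intervals == [("chr1", 0, 5), ("chr1", 10, 20), ("chr2", 50, 60)]

    @pytest.mark.parametrize("iv", [("chr1", 10, 10), ("chr1", 20, 10), ("chr1", -5, 10)])
    def test_bad_intervals_rejected(self, iv):
        with pytest.raises(InputError):
            ib.PeakSet("x", [iv])


class TestContactTable:
    def test_canonical_ordering_enforced(self):
        t = make_table([("chr1", 2000, 1000, 3)])
        assert t.df.loc[0, "bin_i"] == 1000 and t.df.loc[0, "bin_j"] == 2000

    def test_misaligned_bins_rejected(self):
        with pytest.raises(InputError):
            make_table([("chr1", 1250, 2000, 1)])

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            make_table([("chr1", 1000, 2000, -1)])


class TestSiteAssignment:
    def test_midpoint_rule(self):
        t = make_table([])
        ps = ib.PeakSet("p", [("chr1", 1200, 1300)])  # midpoint 1250
        mapping, skipped = ib.assign_sites_to_bins(ps, t)
        assert mapping[("chr1", 1250)] == 1000
        assert skipped == 0

    def test_boundary_spanning_peak_gets_single_bin(self):
        t = make_table([])
        ps = ib.PeakSet("p", [("chr1", 900, 1200)])  # midpoint 1050 -> bin 1000
        mapping, _ = ib.assign_sites_to_bins(ps, t)
        assert list(mapping.values()) == [1000]

    def test_out_of_genome_peaks_skipped_with_warning(self):
        t = make_table([], genome={"chr1": 10_000})
        ps = ib.PeakSet("p", [("chr1", 500, 600), ("chr1", 20_000, 20_100), ("chrX", 0, 10)])
        with pytest.warns(UserWarning, match="outside the genome"):
            mapping, skipped = ib.assign_sites_to_bins(ps, t)
        assert skipped == 2 and len(mapping) == 1

    def test_random_sites_match_per_base_bruteforce(self):
        rng = np.random.default_rng(0)
        t = make_table([], genome={"chr1": 100_000})
        ivs = []
        for _ in range(100):
            s = int(rng.integers(0, 99_000))
            ivs.append(("chr1", s, s + int(rng.integers(1, 900))))
        ps = ib.PeakSet("p", ivs)
        mapping, _ = ib.assign_sites_to_bins(ps, t)
        assert len(mapping) == len(set(ps.midpoints()))
        for (chrom, mid), b in mapping.items():
            # brute force: the bin whose base range contains the midpoint
            assert b <= mid < b + 500
            assert b % 500 == 0


class TestPairSelection:
    def test_inclusion_and_exclusion_by_distance(self):
        anchors = ib.PeakSet("a", [("chr1", 99_950, 100_050)])
        targets = ib.PeakSet("t", [("chr1", 129_950, 130_050), ("chr1", 109_950, 110_050)])
        pairs = ib.select_anchor_target_pairs(anchors, targets, 15_000, 60_000)
        assert [(p.anchor_mid, p.target_mid) for p in pairs] == [(100_000, 130_000)]

    def test_both_orientations_kept(self):
        anchors = ib.PeakSet("a", [("chr1", 99_950, 100_050)])
        targets = ib.PeakSet("t", [("chr1", 69_950, 70_050), ("chr1", 129_950, 130_050)])
        pairs = ib.select_anchor_target_pairs(anchors, targets)
        assert len(pairs) == 2

    def test_matches_bruteforce_all_pairs_filter(self):
        rng = np.random.default_rng(1)
        a_ivs = [("chr1", int(x), int(x) + 100) for x in rng.integers(0, 500_000, 50)]
        t_ivs = [("chr1", int(x), int(x) + 100) for x in rng.integers(0, 500_000, 80)]
        t_ivs += [("chr2", 1000, 1100)]
        anchors, targets = ib.PeakSet("a", a_ivs), ib.PeakSet("t", t_ivs)
        got = set(ib.select_anchor_target_pairs(anchors, targets, 15_000, 60_000))
        expected = {
            ib.AnchorTargetPair(ca, ma, mt)
            for (ca, ma), (ct, mt) in itertools.product(anchors.midpoints(), targets.midpoints())
            if ca == ct and 15_000 <= abs(mt - ma) <= 60_000
        }
        assert got == expected


class TestAggregation:
    def test_single_pair_single_contact(self):
        # anchor bin 100000, target bin 130000, contact count 4 at offset 0
        t = make_table([("chr1", 100_000, 130_000, 4)])
        pairs = [ib.AnchorTargetPair("chr1", 100_250, 130_250)]
        prof = ib.aggregate_profile(pairs, t)
        i0 = int(np.where(prof.offsets == 0)[0][0])
        assert prof.signal[i0] == 4.0
        assert prof.n_pairs == 1
        assert prof.offsets.size == 20

    def test_uniform_contacts_give_flat_profile(self):
        records = [("chr1", 100_000, 130_000 + off, 2)
                   for off in range(-5000, 5000, 500)]
        t = make_table(records)
        pairs = [ib.AnchorTargetPair("chr1", 100_250, 130_250)]
        prof = ib.aggregate_profile(pairs, t)
        np.testing.assert_allclose(prof.signal, 2.0)

    def test_permutation_invariance_and_count_scaling(self):
        rng = np.random.default_rng(2)
        records = [("chr1", int(i) * 500, int(j) * 500, int(c))
                   for i, j, c in zip(rng.integers(150, 250, 40),
                                      rng.integers(250, 350, 40),
                                      rng.integers(1, 10, 40))]
        t = make_table(records)
        pairs = [ib.AnchorTargetPair("chr1", 100_250, 140_250),
                 ib.AnchorTargetPair("chr1", 110_250, 150_250),
                 ib.AnchorTargetPair("chr1", 90_250, 130_250)]
        prof = ib.aggregate_profile(pairs, t)
        prof_rev = ib.aggregate_profile(pairs[::-1], t)
        np.testing.assert_allclose(prof.signal, prof_rev.signal)
        t3 = make_table([(c, i, j, 3 * n) for c, i, j, n in records])
        prof3 = ib.aggregate_profile(pairs, t3)
        np.testing.assert_allclose(prof3.signal, 3 * prof.signal)

    def test_aggregated_sums_are_conserved(self):
        rng = np.random.default_rng(3)
        records = [("chr1", int(i) * 500, int(j) * 500, int(c))
                   for i, j, c in zip(rng.integers(190, 210, 30),
                                      rng.integers(250, 270, 30),
                                      rng.integers(1, 5, 30))]
        t = make_table(records)
        pairs = [ib.AnchorTargetPair("chr1", 100_250, 130_250)]
        prof = ib.aggregate_profile(pairs, t)
        # single pair, all offsets in bounds: per-offset sums == direct lookup sum
        lookup = {(i, j): c for _, i, j, c in t.df.itertuples(index=False, name=None)}
        expected = sum(
            lookup.get((min(100_000, 130_000 + off), max(100_000, 130_000 + off)), 0)
            for off in prof.offsets
        )
        assert prof.signal.sum() == expected

    def test_window_not_multiple_of_bin_rejected(self):
        t = make_table([])
        with pytest.raises(ConfigError):
            ib.aggregate_profile([ib.AnchorTargetPair("chr1", 100_250, 130_250)],
                                 t, window=5300)

    def test_empty_pairs_yield_nan_profile_with_warning(self):
        t = make_table([])
        with pytest.warns(UserWarning, match="no anchor/target pairs"):
            prof = ib.aggregate_profile([], t)
        assert np.all(np.isnan(prof.signal)) and prof.n_pairs == 0

    def test_empty_control_set_yields_nan_control(self):
        t = make_table([])
        anchors = ib.PeakSet("a", [("chr1", 99_950, 100_050)])
        empty = ib.PeakSet("ff", [])
        with pytest.warns(UserWarning, match="no anchor/target pairs"):
            ctrl = ib.control_profile(anchors, empty, t)
        assert np.all(np.isnan(ctrl.signal))


class TestWilcoxon:
    def test_identical_groups_give_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            assert ib.compare_profiles([1.0] * 5, [1.0] * 5) == 1.0

    def test_small_groups_match_exact_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = ib.compare_profiles(x, y)
        assert p == pytest.approx(_exact_two_sided_p(x, y), rel=1e-12)
        assert p == pytest.approx(0.1, rel=1e-12)

    @pytest.mark.parametrize("nx, ny, seed", [(3, 3, 0), (4, 5, 1), (6, 8, 2), (8, 8, 3)])
    def test_exact_distribution_oracle(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.5, 1, ny)
        assert ib.compare_profiles(x, y) == pytest.approx(
            _exact_two_sided_p(x, y), rel=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(InputError):
            ib.compare_profiles([1.0, 2.0], [3.0, 4.0, 5.0])


def _exact_two_sided_p(x, y):
    """Enumerate the exact two-sided Mann-Whitney p-value (no ties)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_hi = max(u_obs, n * m - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        if u >= u_hi or u <= n * m - u_hi:
            count += 1
        total += 1
    return count / total


class TestPeakOverlap:
    def test_simple_overlap_both_ways(self):
        a = ib.PeakSet("A", [("chr1", 0, 100)])
        b = ib.PeakSet("B", [("chr1", 50, 150)])
        res = ib.peak_overlap(a, b)
        assert res["pairwise"]["A_in_B"] == 1
        assert res["pairwise"]["B_in_A"] == 1
        assert res["venn"]["A"] == {"A&B": 1}

    def test_half_open_abutting_intervals_do_not_overlap(self):
        a = ib.PeakSet("A", [("chr1", 0, 100)])
        b = ib.PeakSet("B", [("chr1", 100, 200)])
        res = ib.peak_overlap(a, b)
        assert res["pairwise"]["A_in_B"] == 0
        assert res["venn"]["A"] == {"A": 1}

    def test_three_way_venn_regions(self):
        a = ib.PeakSet("A", [("chr1", 0, 100), ("chr1", 1000, 1100), ("chr1", 5000, 5100)])
        b = ib.PeakSet("B", [("chr1", 50, 150), ("chr1", 1050, 1150)])
        c = ib.PeakSet("C", [("chr1", 1090, 1200)])
        res = ib.peak_overlap(a, b, c)
        assert res["venn"]["A"] == {"A&B": 1, "A&B&C": 1, "A": 1}
        assert res["venn"]["C"] == {"C&A&B": 1}

    def test_duplicate_names_rejected(self):
        a = ib.PeakSet("A", [("chr1", 0, 100)])
        with pytest.raises(InputError):
            ib.peak_overlap(a, a)

    def test_filter_overlapping_and_inverse_partition(self):
        a = ib.PeakSet("A", [("chr1", 0, 100), ("chr1", 300, 400)])
        b = ib.PeakSet("B", [("chr1", 50, 80)])
        hit = ib.filter_overlapping(a, b)
        miss = ib.filter_overlapping(a, b, invert=True)
        assert hit.intervals == [("chr1", 0, 100)]
        assert miss.intervals == [("chr1", 300, 400)]


class TestBinLevelFactorSites:
    def test_cobound_bins_require_all_factors(self):
        t = make_table([], genome={"chr1": 10_000})
        a = ib.PeakSet("A", [("chr1", 1100, 1300), ("chr1", 4100, 4300)])
        b = ib.PeakSet("B", [("chr1", 1350, 1450)])  # midpoint 1400: same bin as A's 1200
        both = ib.factor_bound_sites(t, [a, b], mode="all")
        assert [c for c, s, e in both.intervals] == ["chr1"]
        assert both.intervals[0][1] // 500 * 500 == 1000
        any_ = ib.factor_bound_sites(t, [a, b], mode="any")
        assert len(any_) == 2

    def test_feature_free_sites_exclude_peak_bins(self):
        t = make_table([], genome={"chr1": 5_000})
        peaks = ib.PeakSet("A", [("chr1", 1100, 1300)])
        ff = ib.feature_free_sites(t, [peaks])
        bins = {s // 500 * 500 for _, s, e in ff.intervals}
        assert 1000 not in bins
        assert len(ff) == 9  # 10 bins minus the bound one
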