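"""Scanning statistic, segmentation, and the four-rule merge."""

import numpy as np
import pytest

from refpanelqc.misassembly_scan import (
    FlaggedRegion,
    ScanParams,
    Segment,
    cbs_segment,
    merge_and_flag,
    scan_statistic,
)

from oracles import naive_best_arc, naive_best_arc_definitional, naive_cbs


class TestScanStatistic:
    def test_transform_values(self):
        y = scan_statistic([0, 12, 2], [0, 0, 1])
        assert y[0] == pytest.approx(1.0)           # log2(2)
        assert y[1] == pytest.approx(np.log2(14))   # 12 het samples
        assert y[2] == pytest.approx(np.log2(5))

    def test_twelve_sample_range(self):
        het = np.arange(13)
        y = scan_statistic(het, np.zeros(13))
        assert y.min() == pytest.approx(1.0)
        assert y.max() == pytest.approx(np.log2(14))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            scan_statistic([-1], [0])


def positions(n, step=100):
    return np.arange(1, n + 1) * step


class TestSegmentation:
    def test_constant_series_single_segment(self):
        segs = cbs_segment(np.full(100, 1.0), positions(100), ScanParams())
        assert len(segs) == 1
        assert (segs[0].first, segs[0].last) == (0, 99)

    def test_clean_step_found_exactly(self):
        y = np.r_[np.full(50, 1.0), np.full(50, 3.5)]
        segs = cbs_segment(y, positions(100), ScanParams(seed=1))
        assert [(s.first, s.last) for s in segs] == [(0, 49), (50, 99)]
        assert segs[0].mean == pytest.approx(1.0)
        assert segs[1].mean == pytest.approx(3.5)

    def test_noisy_shift_boundary_recovered(self):
        # 4-sigma mean shift at index 14; boundary within +/-1 in >= 95% of
        # seeded replicates
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            y = rng.normal(0, 1, 30)
            y[14:] += 4.0
            segs = cbs_segment(y, positions(30), ScanParams(seed=rep))
            bounds = [s.first for s in segs[1:]]
            if any(abs(b - 14) <= 1 for b in bounds):
                hits += 1
        assert hits >= 95

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            cbs_segment(np.ones(10), np.array([5, 4, 3, 2, 1, 6, 7, 8, 9, 10]),
                        ScanParams())

    def test_min_width_respected(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, 60)
        y[20:40] += 5
        segs = cbs_segment(y, positions(60), ScanParams(seed=7))
        assert all(s.n_sites >= 5 for s in segs)

    def test_oracle_self_check(self):
        # the fast prefix-sum oracle agrees with the definitional statistic
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 26))
            y = rng.normal(0, 1, n)
            fast = naive_best_arc(y, 5)
            slow = naive_best_arc_definitional(y, 5)
            assert fast[1:] == slow[1:]
            assert fast[0] == pytest.approx(slow[0])

    def test_matches_exhaustive_oracle_small_series(self):
        params = ScanParams(seed=11)
        rng = np.random.default_rng(0)
        for rep in range(25):
            n = int(rng.integers(10, 26))
            y = rng.normal(0, 1, n)
            if rep % 2:
                k = int(rng.integers(5, n - 4))
                y[k:] += 6.0
            pos = positions(n)
            got = [(s.first, s.last + 1) for s in
                   cbs_segment(y, pos, params)]
            expected = naive_cbs(y, pos, params.min_width, params.alpha,
                                 params.permutations, params.seed)
            assert got == expected


def seg(mean, n_sites, bp, chrom="c", first=0):
    """Segment helper; genomic length bp, site-index span n_sites."""
    return Segment(chrom=chrom, first=first, last=first + n_sites - 1,
                   start_bp=0, end_bp=bp, mean=mean, n_sites=n_sites)


def chain_segments(specs, chrom="c"):
    """Build a partition from (mean, n_sites, bp_length) triples."""
    out, first, bp = [], 0, 0
    for mean, n, length in specs:
        out.append(Segment(chrom=chrom, first=first, last=first + n - 1,
                           start_bp=bp, end_bp=bp + length, mean=mean,
                           n_sites=n))
        first += n
        bp += length
    return out


class TestMerge:
    def test_two_segments_opposite_states_untouched(self):
        segs = chain_segments([(1.0, 10, 10_000), (2.0, 10, 10_000)])
        merged, flags = merge_and_flag(segs, ScanParams())
        assert len(merged) == 2
        assert len(flags) == 1
        assert flags[0].start == 10_000

    def test_positive_flicker_cascades_to_single_high(self):
        segs = chain_segments([(2.0, 20, 10_000), (1.0, 6, 3_000),
                               (2.2, 16, 8_000)])
        merged, flags = merge_and_flag(segs, ScanParams())
        assert len(merged) == 1
        expected = (20 * 2.0 + 6 * 1.0 + 16 * 2.2) / 42
        assert merged[0].mean == pytest.approx(expected)
        assert merged[0].end_bp - merged[0].start_bp == 21_000
        assert len(flags) == 1

    def test_negative_flicker_absorbed(self):
        segs = chain_segments([(1.0, 20, 10_000), (2.0, 6, 3_000),
                               (1.1, 16, 8_000)])
        merged, flags = merge_and_flag(segs, ScanParams())
        assert len(merged) == 1
        assert flags == []

    def test_wide_middle_not_a_flicker(self):
        segs = chain_segments([(2.0, 20, 10_000), (1.0, 12, 6_000),
                               (2.2, 16, 8_000)])
        merged, _ = merge_and_flag(segs, ScanParams())
        assert len(merged) == 3

    def test_all_low_collapses_with_no_flags(self):
        segs = chain_segments([(1.1, 10, 5_000), (1.2, 10, 5_000),
                               (1.3, 10, 5_000)])
        merged, flags = merge_and_flag(segs, ScanParams())
        assert len(merged) == 1 and flags == []

    def test_mean_equal_threshold_is_low(self):
        segs = chain_segments([(1.5, 10, 5_000), (1.5, 10, 5_000)])
        merged, flags = merge_and_flag(segs, ScanParams())
        assert len(merged) == 1 and flags == []

    def test_back_transform_of_flagged_mean(self):
        segs = chain_segments([(3.0, 10, 5_000)])
        _, flags = merge_and_flag(segs, ScanParams())
        assert flags[0].mean_het_na == pytest.approx(2 ** 3 - 2)

    def _random_partition(self, rng):
        n_seg = int(rng.integers(1, 12))
        specs = [(float(rng.uniform(0.8, 3.0)), int(rng.integers(5, 30)),
                  int(rng.integers(500, 20_000))) for _ in range(n_seg)]
        return chain_segments(specs)

    def test_idempotence_and_partition_conservation(self):
        rng = np.random.default_rng(123)
        params = ScanParams()
        for _ in range(1000):
            segs = self._random_partition(rng)
            total_sites = sum(s.n_sites for s in segs)
            merged, _ = merge_and_flag(segs, params)
            # partition conserved
            assert sum(s.n_sites for s in merged) == total_sites
            assert merged[0].first == 0
            for a, b in zip(merged, merged[1:]):
                assert b.first == a.last + 1
            # idempotent
            again, _ = merge_and_flag(merged, params)
            assert [(s.first, s.last, s.mean) for s in again] == \
                [(s.first, s.last, s.mean) for s in merged]

    def test_threshold_monotonicity_on_fixed_segments(self):
        # For a fixed segmentation, raising the threshold can only demote
        # segments from HIGH to LOW.  (The count of *merged* flagged regions
        # is not monotone: raising T can split one merged HIGH block into
        # separate flags.)
        rng = np.random.default_rng(5)
        for _ in range(200):
            segs = self._random_partition(rng)
            counts = [sum(s.is_high(t) for s in segs)
                      for t in (1.2, 1.5, 1.8, 2.2)]
            assert counts == sorted(counts, reverse=True)

    def test_flagged_sites_shrink_when_threshold_rises(self):
        # the flagged genomic extent after merging shrinks (weakly) as the
        # threshold rises on a clean two-state profile
        segs = chain_segments([(1.0, 10, 5_000), (2.0, 10, 5_000),
                               (1.0, 10, 5_000), (2.6, 10, 5_000)])
        extents = []
        for t in (1.5, 2.2):
            _, flags = merge_and_flag(segs, ScanParams(threshold=t))
            extents.append(sum(f.end - f.start for f in flags))
        assert extents[0] >= extents[1]

    def test_non_partition_rejected(self):
        a = seg(1.0, 10, 1000)
        b = seg(2.0, 10, 1000, first=15)  # gap in site indices
        with pytest.raises(ValueError, match="partition"):
            merge_and_flag([a, b], ScanParams())
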