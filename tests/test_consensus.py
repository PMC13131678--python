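"""Consensus grid construction, merging semantics and the built-in caller."""

import numpy as np
import pytest

from epinorm import (
    GenomeIndex,
    Peak,
    RegionSet,
    SignalTrack,
    build_consensus_grid,
    call_peaks_builtin,
    filter_peaks_by_q,
    grid_summary,
    merge_regions,
    pool_condition_signal,
)
from epinorm.consensus import DEFAULT_MERGE_DISTANCES, DEFAULT_Q_THRESHOLDS

from conftest import oracle_merge


def peaks_with_q(qs):
    return [
        Peak("chrA", i * 100, i * 100 + 50, neg_log10_q=(None if q is None else -np.log10(q)))
        for i, q in enumerate(qs)
    ]


class TestFilterPeaks:
    def test_threshold_inclusive(self):
        peaks = peaks_with_q([0.2, 0.04, 0.001])
        assert len(filter_peaks_by_q(peaks, 0.05)) == 2

    def test_threshold_one_keeps_known_only(self):
        peaks = peaks_with_q([0.5, None, 0.9])
        assert len(filter_peaks_by_q(peaks, 1.0)) == 2

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            qs = [
                None if rng.random() < 0.2 else float(rng.uniform(1e-6, 1))
                for _ in range(30)
            ]
            thr = float(rng.uniform(1e-4, 1))
            peaks = peaks_with_q(qs)
            got = len(filter_peaks_by_q(peaks, thr))
            # brute force on the original q values, with float-log tolerance
            expect = sum(1 for q in qs if q is not None and q <= thr * (1 + 1e-12))
            assert got == expect


class TestMergeRegions:
    def test_gap_equal_d_merges(self):
        rs = RegionSet.from_intervals([("c", 0, 10), ("c", 15, 20)])
        assert merge_regions(rs, 5).intervals() == [("c", 0, 20)]

    def test_bookended_merge_at_zero(self):
        rs = RegionSet.from_intervals([("c", 0, 10), ("c", 10, 20)])
        assert merge_regions(rs, 0).intervals() == [("c", 0, 20)]

    def test_gap_exceeding_d_kept_separate(self):
        rs = RegionSet.from_intervals([("c", 0, 10), ("c", 16, 20)])
        assert merge_regions(rs, 5).intervals() == [("c", 0, 10), ("c", 16, 20)]

    def test_chromosomes_never_merge(self):
        rs = RegionSet.from_intervals([("c1", 0, 10), ("c2", 0, 10)])
        assert len(merge_regions(rs, 10_000)) == 2

    def test_idempotent_and_separated(self, rng):
        for _ in range(20):
            ivals = []
            for _ in range(int(rng.integers(1, 30))):
                s = int(rng.integers(0, 5000))
                ivals.append(("c", s, s + int(rng.integers(1, 200))))
            d = int(rng.integers(0, 100))
            rs = RegionSet.from_intervals(ivals)
            once = merge_regions(rs, d)
            assert merge_regions(once, d) == once
            prev_end = None
            for _, s, e in once.intervals():
                if prev_end is not None:
                    assert s - prev_end > d
                prev_end = e

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 40))
            ivals = []
            for _ in range(n):
                s = int(rng.integers(0, 3000))
                ivals.append((s, s + int(rng.integers(1, 150))))
            d = int(rng.integers(0, 120))
            rs = RegionSet.from_intervals([("c", s, e) for s, e in ivals])
            got = [(s, e) for _, s, e in merge_regions(rs, d).intervals()]
            assert got == oracle_merge(ivals, d)


class TestGrid:
    def test_default_grid_has_25_cells(self):
        peaks = {"A": peaks_with_q([0.001] * 5), "B": peaks_with_q([0.01] * 5)}
        grid = build_consensus_grid(peaks)
        assert len(grid) == 25
        assert grid.q_thresholds == DEFAULT_Q_THRESHOLDS
        assert grid.merge_distances == DEFAULT_MERGE_DISTANCES

    def test_empty_peak_inputs_give_25_empty_cells(self):
        grid = build_consensus_grid({"A": [], "B": []})
        assert len(grid) == 25
        assert all(len(rs) == 0 for rs in grid.cells.values())

    def test_degenerate_grid_equals_merge(self):
        peaks = {"A": peaks_with_q([0.5, 0.2, 0.9])}
        grid = build_consensus_grid(peaks, q_list=[1.0], d_list=[0])
        base = RegionSet.from_intervals(
            [(p.chrom, p.start, p.end) for p in peaks["A"]]
        )
        assert grid.cell(1.0, 0) == merge_regions(base, 0)

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            build_consensus_grid({"A": []}, q_list=[], d_list=[0])

    def test_monotone_in_q_and_d(self, rng):
        peaks = {}
        for cond in ("A", "B"):
            ps = []
            for _ in range(60):
                s = int(rng.integers(0, 20000))
                ps.append(
                    Peak("c", s, s + int(rng.integers(50, 400)),
                         neg_log10_q=float(rng.uniform(0, 6)))
                )
            peaks[cond] = ps
        grid = build_consensus_grid(peaks)
        qs, ds = grid.q_thresholds, grid.merge_distances
        for d in ds:
            bps = [grid.cell(q, d).total_bp() for q in qs]  # loosest -> strictest
            assert all(b1 >= b2 for b1, b2 in zip(bps, bps[1:]))
        for q in qs:
            ns = [len(grid.cell(q, d)) for d in ds]
            bps = [grid.cell(q, d).total_bp() for d in ds]
            assert all(n1 >= n2 for n1, n2 in zip(ns, ns[1:]))
            assert all(b1 <= b2 for b1, b2 in zip(bps, bps[1:]))

    def test_summary_stats(self):
        grid = build_consensus_grid(
            {"A": peaks_with_q([0.001])}, q_list=[0.05], d_list=[0]
        )
        df = grid_summary(grid)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["n_regions"] == 1
        assert row["width_median"] == 50
        assert row["total_bp"] == 50

    def test_summary_empty_cell_is_na(self):
        grid = build_consensus_grid({"A": []}, q_list=[0.05], d_list=[0])
        row = grid_summary(grid).iloc[0]
        assert row["n_regions"] == 0
        assert row["total_bp"] == 0
        assert row.isna()["width_median"]


class TestBuiltinCaller:
    def test_uniform_background_yields_no_peaks(self):
        genome = GenomeIndex([("chrA", 20000)])
        flat = SignalTrack({"chrA": ([0], [20000], [4.0])})
        assert call_peaks_builtin(flat, genome, window=200, max_q=0.1) == []

    def test_poisson_background_plus_block_found_exactly_once(self):
        rng = np.random.default_rng(5)
        genome = GenomeIndex([("chrA", 50000)])
        arr = rng.poisson(4.0, 50000).astype(float)
        arr[20000:21000] += 40.0  # 10x enrichment block of 1 kb
        track = SignalTrack.from_dense({"chrA": arr})
        peaks = call_peaks_builtin(track, genome, window=200, max_q=0.05)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.start <= 20000 and p.end >= 21000
        assert p.start >= 20000 - 200 and p.end <= 21000 + 200
        assert p.neg_log10_q > 2

    def test_empty_track_yields_no_peaks(self):
        genome = GenomeIndex([("chrA", 10000)])
        assert call_peaks_builtin(SignalTrack(), genome) == []

    def test_control_raises_local_lambda(self):
        rng = np.random.default_rng(6)
        genome = GenomeIndex([("chrA", 50000)])
        arr = rng.poisson(4.0, 50000).astype(float)
        arr[10000:11000] += 40.0
        track = SignalTrack.from_dense({"chrA": arr})
        # control with matching enrichment at the same spot cancels the peak
        ctl = np.full(50000, 4.0)
        ctl[10000:11000] += 40.0
        control = SignalTrack.from_dense({"chrA": ctl})
        with_ctl = call_peaks_builtin(track, genome, control=control, window=200)
        no_ctl = call_peaks_builtin(track, genome, window=200)
        assert len(no_ctl) == 1 and len(with_ctl) == 0

    def test_window_larger_than_genome_rejected(self):
        genome = GenomeIndex([("chrA", 100)])
        with pytest.raises(ValueError, match="window"):
            call_peaks_builtin(
                SignalTrack({"chrA": ([0], [100], [1.0])}), genome, window=500
            )


def test_pool_condition_signal_single_track_identity(rng):
    t = SignalTrack({"chrA": ([0], [10], [2.0])})
    assert pool_condition_signal([t]) == t
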