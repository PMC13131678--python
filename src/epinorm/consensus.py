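"""Consensus-region grid construction from per-condition peak sets.

Peaks are called per condition on pooled replicate signal (either ingested
from external narrowPeak/broadPeak files or via the built-in minimal
Poisson window caller), filtered at a grid of q-value thresholds,
concatenated across conditions, sorted, and merged at a grid of gap
distances — yielding |q| × |d| candidate consensus sets whose summary
statistics let the user pick the region set for differential testing.

The built-in caller is deliberately minimal: fixed non-overlapping
windows, a one-sided Poisson upper-tail test of each window's summed
signal against the genome-wide (or control-informed local) background
mean, and Benjamini–Hochberg adjustment across all windows.  It exists so
the pipeline is fully testable without external peak-caller binaries; the
faithful external path is narrowPeak/broadPeak ingestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomeIndex, Peak, RegionSet
from .tracks import SignalTrack, pool_tracks, _prefix_integral

__all__ = [
    "ConsensusGrid",
    "DEFAULT_Q_THRESHOLDS",
    "DEFAULT_MERGE_DISTANCES",
    "pool_condition_signal",
    "call_peaks_builtin",
    "filter_peaks_by_q",
    "merge_regions",
    "build_consensus_grid",
    "grid_summary",
]

DEFAULT_Q_THRESHOLDS = (0.1, 0.05, 0.01, 0.001, 0.0001)
DEFAULT_MERGE_DISTANCES = (0, 50, 100, 250, 500)


def pool_condition_signal(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-base sum of replicate tracks — one pooled track per condition."""
    return pool_tracks(tracks)


def call_peaks_builtin(
    pooled: SignalTrack,
    genome: GenomeIndex,
    control: SignalTrack | None = None,
    window: int = 200,
    mode: str = "narrow",
    max_q: float = 0.1,
    merge_gap: int | None = None,
) -> list[Peak]:
    """Minimal Poisson window caller.

    Tiles the genome into non-overlapping ``window``-bp windows, tests each
    window's (rounded) summed signal against a Poisson background whose
    mean is the genome-wide mean window signal — raised to the scaled
    control window mean where a control is given — and BH-adjusts across
    all windows.  Windows with q <= ``max_q`` (the loosest grid threshold)
    are merged into peaks when within ``merge_gap`` bp; each peak carries
    the max −log10(q) of its member windows.  ``mode='broad'`` defaults to
    a 500 bp window with a two-window merge gap, ``'narrow'`` to 200 bp
    with book-ended merging only.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode == "broad" and window == 200:
        window = 500
    if merge_gap is None:
        merge_gap = 2 * window if mode == "broad" else 0
    if all(genome[c] < window for c in genome.names):
        raise ValueError("window larger than every chromosome")
    if pooled.is_empty():
        return []

    win_chrom: list[str] = []
    win_start: list[np.ndarray] = []
    win_sum: list[np.ndarray] = []
    ctl_sum: list[np.ndarray] = []
    for chrom in genome.names:
        length = genome[chrom]
        edges = np.arange(0, length + window, window, dtype=np.int64)
        edges[-1] = min(edges[-1], length)
        edges = np.unique(edges)
        if edges.size < 2:
            continue
        F = _prefix_integral(pooled, chrom, edges)
        sums = np.diff(F)
        win_chrom.extend([chrom] * sums.size)
        win_start.append(edges[:-1])
        win_sum.append(sums)
        if control is not None:
            Fc = _prefix_integral(control, chrom, edges)
            ctl_sum.append(np.diff(Fc))
    starts = np.concatenate(win_start)
    sums = np.concatenate(win_sum)
    chroms = np.asarray(win_chrom)

    lam_global = float(sums.mean())
    if lam_global <= 0:
        return []
    lam = np.full(sums.size, lam_global)
    if control is not None and control.total() > 0:
        scale = pooled.total() / control.total()
        lam = np.maximum(lam, np.concatenate(ctl_sum) * scale)

    k = np.rint(sums).astype(np.int64)
    pvals = stats.poisson.sf(k - 1, lam)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    sig = qvals <= max_q
    peaks: list[Peak] = []
    neglogq = -np.log10(np.maximum(qvals, 1e-300))
    for chrom in genome.names:
        idx = np.flatnonzero(sig & (chroms == chrom))
        if idx.size == 0:
            continue
        s = starts[idx]
        e = np.minimum(s + window, genome[chrom])
        cur_s, cur_e = int(s[0]), int(e[0])
        cur_q, cur_score = float(neglogq[idx[0]]), float(sums[idx[0]])
        for j in range(1, idx.size):
            if s[j] - cur_e <= merge_gap:
                cur_e = int(e[j])
                cur_q = max(cur_q, float(neglogq[idx[j]]))
                cur_score += float(sums[idx[j]])
            else:
                peaks.append(
                    Peak(chrom, cur_s, cur_e, score=cur_score, neg_log10_q=cur_q)
                )
                cur_s, cur_e = int(s[j]), int(e[j])
                cur_q, cur_score = float(neglogq[idx[j]]), float(sums[idx[j]])
        peaks.append(Peak(chrom, cur_s, cur_e, score=cur_score, neg_log10_q=cur_q))
    return peaks


def filter_peaks_by_q(peaks: Sequence[Peak], q_threshold: float) -> list[Peak]:
    """Keep peaks with q <= threshold; unknown-q peaks are dropped."""
    if not (0 < q_threshold <= 1):
        raise ValueError("q threshold must be in (0, 1]")
    cutoff = -math.log10(q_threshold)
    return [
        p
        for p in peaks
        if p.neg_log10_q is not None and p.neg_log10_q >= cutoff
    ]


def merge_regions(regions: RegionSet, d: int = 0) -> RegionSet:
    """Transitively merge same-chromosome regions whose gap is <= d bp.

    d = 0 merges overlapping and book-ended regions (bedtools -d
    semantics; a gap exactly equal to d merges).
    """
    if d < 0:
        raise ValueError("merge distance must be non-negative")
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in regions.intervals():  # already canonically sorted
        if merged and merged[-1][0] == chrom and start - merged[-1][2] <= d:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return RegionSet.from_intervals(merged, genome=regions.genome)


@dataclass
class ConsensusGrid:
    """(q-threshold × merge-distance) grid of merged candidate region sets."""

    q_thresholds: tuple[float, ...]
    merge_distances: tuple[int, ...]
    cells: dict[tuple[float, int], RegionSet] = field(default_factory=dict)

    def cell(self, q: float, d: int) -> RegionSet:
        return self.cells[(q, d)]

    def __len__(self) -> int:
        return len(self.cells)


def build_consensus_grid(
    per_condition_peaks: Mapping[str, Sequence[Peak]],
    q_list: Sequence[float] = DEFAULT_Q_THRESHOLDS,
    d_list: Sequence[int] = DEFAULT_MERGE_DISTANCES,
    genome: GenomeIndex | None = None,
) -> ConsensusGrid:
    """For each (q, d): q-filter each condition's peaks, concatenate across
    conditions, sort, merge at gap d."""
    if not per_condition_peaks:
        raise ValueError("need at least one condition")
    if not q_list or not d_list:
        raise ValueError("q_list and d_list must be non-empty")
    grid = ConsensusGrid(tuple(q_list), tuple(int(d) for d in d_list))
    for q in q_list:
        kept: list[Peak] = []
        for cond in per_condition_peaks:
            kept.extend(filter_peaks_by_q(per_condition_peaks[cond], q))
        base = RegionSet.from_intervals(
            [(p.chrom, p.start, p.end) for p in kept], genome=genome
        )
        for d in d_list:
            grid.cells[(q, int(d))] = merge_regions(base, int(d))
    return grid


def grid_summary(grid: ConsensusGrid) -> pd.DataFrame:
    """One row per grid cell: region count, width quantiles, covered bp."""
    rows = []
    for q in grid.q_thresholds:
        for d in grid.merge_distances:
            rs = grid.cells[(q, d)]
            w = rs.widths()
            rows.append(
                {
                    "q_threshold": q,
                    "merge_distance": d,
                    "n_regions": len(rs),
                    "width_min": int(w.min()) if w.size else pd.NA,
                    "width_median": float(np.median(w)) if w.size else pd.NA,
                    "width_mean": float(w.mean()) if w.size else pd.NA,
                    "width_max": int(w.max()) if w.size else pd.NA,
                    "total_bp": int(w.sum()),
                }
            )
    return pd.DataFrame(rows)
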