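"""Shared fixtures and naive per-base oracle helpers.

The oracles deliberately use dense numpy arrays and O(n²) scans — the
simplest possible independent implementations — so that the RLE sweep
algorithms in the package are checked against brute force, never against
themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from epinorm import GenomeIndex, RegionSet, SampleRecord, SampleSheet, SignalTrack

CHROM_LEN = 2000


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dense(rng, length=CHROM_LEN, max_value=20, p_zero=0.4, n_blocks=12):
    """Random piecewise-constant non-negative array with zero stretches."""
    arr = np.zeros(length, dtype=np.float64)
    edges = np.sort(rng.choice(length, size=min(n_blocks, length - 1), replace=False))
    edges = np.concatenate(([0], edges, [length]))
    for i in range(len(edges) - 1):
        if rng.random() < p_zero:
            continue
        val = rng.integers(1, max_value) + (rng.random() < 0.3) * rng.random()
        arr[edges[i] : edges[i + 1]] = val
    return arr


def random_track(rng, chroms=("chrA",), length=CHROM_LEN, **kw) -> SignalTrack:
    return SignalTrack.from_dense(
        {c: random_dense(rng, length, **kw) for c in chroms}
    )


def dense_of(track: SignalTrack, chrom="chrA", length=CHROM_LEN) -> np.ndarray:
    return track.to_dense(chrom, length)


def oracle_local_maxima(arr: np.ndarray) -> list[tuple[int, int, float]]:
    """Plateau maxima of a dense array with zero-padded flanks (brute force)."""
    padded = np.concatenate(([0.0], arr, [0.0]))
    out = []
    i = 1
    while i <= len(arr):
        j = i
        while j + 1 <= len(arr) and padded[j + 1] == padded[i]:
            j += 1
        v = padded[i]
        if v > 0 and v > padded[i - 1] and v > padded[j + 1]:
            out.append((i - 1, j, float(v)))
        i = j + 1
    return out


def oracle_merge(intervals: list[tuple[int, int]], d: int) -> list[tuple[int, int]]:
    """O(n²) transitive merge of intervals on one chromosome."""
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                gap = max(a[0], b[0]) - min(a[1], b[1])
                if gap <= d:
                    items[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e) for s, e in items)


@pytest.fixture
def genome():
    return GenomeIndex([("chrA", CHROM_LEN), ("chrB", CHROM_LEN)])


@pytest.fixture
def sheet_2x2():
    return SampleSheet(
        [
            SampleRecord("A_1", "a1.bam", "A", "mark"),
            SampleRecord("A_2", "a2.bam", "A", "mark"),
            SampleRecord("B_1", "b1.bam", "B", "mark"),
            SampleRecord("B_2", "b2.bam", "B", "mark"),
        ]
    )


@pytest.fixture
def sheet_4x4():
    recs = [SampleRecord(f"A_{i}", f"a{i}.bam", "A", "mark") for i in range(1, 5)]
    recs += [SampleRecord(f"B_{i}", f"b{i}.bam", "B", "mark") for i in range(1, 5)]
    return SampleSheet(recs)


def regions_of(intervals, genome=None) -> RegionSet:
    return RegionSet.from_intervals(intervals, genome=genome)
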