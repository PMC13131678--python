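"""Run-length-encoded per-base genomic signal tracks.

A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping
half-open runs ``(start, end, value)`` with an implicit value of 0
everywhere else.  Canonical form stores no zero-valued runs and merges
adjacent (book-ended) equal-valued runs, which makes plateau-level
local-maxima detection well defined and output deterministic.

All interval arithmetic in the package (control subtraction, blacklist
masking, pooling, per-base medians, region quantification) is expressed
as a sweep over the union of run breakpoints, so it is exact — no binning
is involved anywhere.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SignalTrack",
    "combine",
    "pool_tracks",
    "median_tracks",
    "subtract_tracks",
    "mask_track",
    "region_sums",
]

_EMPTY_RUNS = (
    np.empty(0, dtype=np.int64),
    np.empty(0, dtype=np.int64),
    np.empty(0, dtype=np.float64),
)


def _canonicalize(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort, validate and normalise one chromosome's runs.

    Raises ``ValueError`` on empty/negative-length or overlapping runs.
    Zero-valued runs are dropped and contiguous equal-valued runs merged.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    values = np.asarray(values, dtype=np.float64)
    if not (starts.shape == ends.shape == values.shape):
        raise ValueError("starts, ends and values must have equal length")
    if starts.size == 0:
        return _EMPTY_RUNS
    if np.any(ends <= starts):
        raise ValueError("runs must satisfy start < end")
    if np.any(starts < 0):
        raise ValueError("negative coordinates are not allowed")
    if not np.all(np.isfinite(values)):
        raise ValueError("run values must be finite")
    order = np.argsort(starts, kind="stable")
    starts, ends, values = starts[order], ends[order], values[order]
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("overlapping runs")
    keep = values != 0.0
    starts, ends, values = starts[keep], ends[keep], values[keep]
    if starts.size == 0:
        return _EMPTY_RUNS
    # merge book-ended runs with identical value
    new_group = np.ones(starts.size, dtype=bool)
    new_group[1:] = (starts[1:] != ends[:-1]) | (values[1:] != values[:-1])
    gid = np.cumsum(new_group) - 1
    n = gid[-1] + 1
    out_s = np.empty(n, dtype=np.int64)
    out_e = np.empty(n, dtype=np.int64)
    first = np.flatnonzero(new_group)
    out_s[:] = starts[first]
    out_v = values[first]
    last = np.append(first[1:] - 1, starts.size - 1)
    out_e[:] = ends[last]
    return out_s, out_e, out_v


class SignalTrack:
    """Sparse per-base signal over a genome, in canonical RLE form."""

    __slots__ = ("runs",)

    def __init__(
        self,
        runs: Mapping[str, tuple[Sequence[int], Sequence[int], Sequence[float]]]
        | None = None,
    ):
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom in sorted(runs):
                s, e, v = _canonicalize(*runs[chrom])
                if s.size:
                    self.runs[chrom] = (s, e, v)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dense(cls, arrays: Mapping[str, np.ndarray]) -> "SignalTrack":
        """Build a track from dense per-base arrays (oracle/test helper)."""
        runs = {}
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            runs[chrom] = (starts, ends, arr[starts])
        return cls(runs)

    @classmethod
    def _from_canonical(cls, runs) -> "SignalTrack":
        t = cls()
        for chrom in sorted(runs):
            s, e, v = runs[chrom]
            if s.size:
                t.runs[chrom] = (s, e, v)
        return t

    # -- basic queries ------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.runs)

    def is_empty(self) -> bool:
        return not self.runs

    def total(self) -> float:
        """Integral of the signal: sum of value × run length."""
        return float(
            sum(np.sum(v * (e - s)) for s, e, v in self.runs.values())
        )

    def max_end(self, chrom: str) -> int:
        s, e, v = self.runs.get(chrom, _EMPTY_RUNS)
        return int(e[-1]) if e.size else 0

    def to_dense(self, chrom: str, length: int) -> np.ndarray:
        arr = np.zeros(length, dtype=np.float64)
        s, e, v = self.runs.get(chrom, _EMPTY_RUNS)
        for i in range(s.size):
            arr[s[i] : e[i]] = v[i]
        return arr

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self.runs) != set(other.runs):
            return False
        for chrom, (s, e, v) in self.runs.items():
            os, oe, ov = other.runs[chrom]
            if not (
                np.array_equal(s, os)
                and np.array_equal(e, oe)
                and np.array_equal(v, ov)
            ):
                return False
        return True

    def __hash__(self):  # pragma: no cover - tracks are not hashable
        raise TypeError("SignalTrack is unhashable")

    def allclose(self, other: "SignalTrack", rtol=1e-9, atol=1e-12) -> bool:
        if set(self.runs) != set(other.runs):
            return False
        for chrom, (s, e, v) in self.runs.items():
            os, oe, ov = other.runs[chrom]
            if not (
                np.array_equal(s, os)
                and np.array_equal(e, oe)
                and np.allclose(v, ov, rtol=rtol, atol=atol)
            ):
                return False
        return True

    def __repr__(self) -> str:
        n = sum(s.size for s, _, _ in self.runs.values())
        return f"SignalTrack({len(self.runs)} chroms, {n} runs)"

    # -- arithmetic ---------------------------------------------------

    def scale(self, multiplier: float) -> "SignalTrack":
        """Multiply every value by ``multiplier`` (> 0)."""
        if not (multiplier > 0):
            raise ValueError("multiplier must be positive")
        out = {}
        for chrom, (s, e, v) in self.runs.items():
            out[chrom] = (s.copy(), e.copy(), v * multiplier)
        return SignalTrack._from_canonical(out)


def _values_on_segments(
    track: SignalTrack, chrom: str, seg_starts: np.ndarray
) -> np.ndarray:
    """Signal value at each segment start (segments never straddle runs)."""
    s, e, v = track.runs.get(chrom, _EMPTY_RUNS)
    out = np.zeros(seg_starts.size, dtype=np.float64)
    if s.size == 0:
        return out
    idx = np.searchsorted(s, seg_starts, side="right") - 1
    valid = idx >= 0
    inside = np.zeros_like(valid)
    inside[valid] = seg_starts[valid] < e[idx[valid]]
    out[inside] = v[idx[inside]]
    return out


def combine(
    tracks: Sequence[SignalTrack],
    func: Callable[[np.ndarray], np.ndarray],
) -> SignalTrack:
    """Pointwise combination of tracks via a breakpoint sweep.

    ``func`` receives a (n_tracks, n_segments) array of per-segment values
    (0 where a track has no run) and returns one value per segment.  The
    result is re-canonicalized, so zero segments vanish and equal
    neighbours merge.
    """
    all_chroms = sorted({c for t in tracks for c in t.runs})
    out = {}
    for chrom in all_chroms:
        bps = [t.runs[chrom][0] for t in tracks if chrom in t.runs]
        bps += [t.runs[chrom][1] for t in tracks if chrom in t.runs]
        bp = np.unique(np.concatenate(bps))
        if bp.size < 2:
            continue
        seg_s, seg_e = bp[:-1], bp[1:]
        V = np.vstack([_values_on_segments(t, chrom, seg_s) for t in tracks])
        vals = np.asarray(func(V), dtype=np.float64)
        out[chrom] = _canonicalize(seg_s, seg_e, vals)
    return SignalTrack._from_canonical(out)


def pool_tracks(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-base sum of member tracks (condition pooling)."""
    if not tracks:
        raise ValueError("need at least one track")
    return combine(tracks, lambda V: V.sum(axis=0))


def median_tracks(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-base median across tracks; even counts average the middle two."""
    if not tracks:
        raise ValueError("need at least one track")
    return combine(tracks, lambda V: np.median(V, axis=0))


def subtract_tracks(
    ip: SignalTrack,
    control: SignalTrack,
    control_scale: float = 1.0,
    clamp: bool = True,
) -> SignalTrack:
    """``ip − control_scale × control`` per base; negatives optionally clamped."""

    def f(V: np.ndarray) -> np.ndarray:
        d = V[0] - control_scale * V[1]
        if clamp:
            d = np.maximum(d, 0.0)
        return d

    return combine([ip, control], f)


def mask_track(track: SignalTrack, regions: Iterable[tuple[str, int, int]]) -> SignalTrack:
    """Zero the signal inside the given regions (blacklist masking)."""
    mask_runs: dict[str, list] = {}
    for chrom, start, end in regions:
        mask_runs.setdefault(chrom, []).append((start, end))
    if not mask_runs:
        return track
    merged = {}
    for chrom, ivals in mask_runs.items():
        ivals.sort()
        ms, me = [], []
        for a, b in ivals:
            if ms and a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        merged[chrom] = (
            np.asarray(ms, dtype=np.int64),
            np.asarray(me, dtype=np.int64),
            np.ones(len(ms), dtype=np.float64),
        )
    mask = SignalTrack(merged)
    out = combine([track, mask], lambda V: np.where(V[1] > 0, 0.0, V[0]))
    # chromosomes fully outside the mask's breakpoints are untouched
    for chrom, (s, e, v) in track.runs.items():
        if chrom not in mask.runs and chrom not in out.runs:
            out.runs[chrom] = (s.copy(), e.copy(), v.copy())
    return SignalTrack._from_canonical(out.runs)


def _prefix_integral(track: SignalTrack, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Integral of the signal over [0, x) for each position x (vectorized)."""
    s, e, v = track.runs.get(chrom, _EMPTY_RUNS)
    if s.size == 0:
        return np.zeros(positions.size, dtype=np.float64)
    cum = np.concatenate(([0.0], np.cumsum(v * (e - s))))
    idx = np.searchsorted(s, positions, side="right") - 1
    out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
    has = idx >= 0
    part = np.zeros(positions.size, dtype=np.float64)
    i = idx[has]
    part[has] = v[i] * np.clip(positions[has] - s[i], 0, e[i] - s[i])
    return out + part


def region_sums(
    track: SignalTrack, regions: Iterable[tuple[str, int, int]]
) -> np.ndarray:
    """Exact per-base signal sum over each half-open region."""
    regs = list(regions)
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _, _) in enumerate(regs):
        by_chrom.setdefault(chrom, []).append(i)
    out = np.zeros(len(regs), dtype=np.float64)
    for chrom, idxs in by_chrom.items():
        starts = np.asarray([regs[i][1] for i in idxs], dtype=np.int64)
        ends = np.asarray([regs[i][2] for i in idxs], dtype=np.int64)
        sums = _prefix_integral(track, chrom, ends) - _prefix_integral(
            track, chrom, starts
        )
        out[np.asarray(idxs)] = sums
    return out
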