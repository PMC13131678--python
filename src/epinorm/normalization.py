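"""Percentile-of-local-maxima signal normalization.

The method: find every local maximum of a sample's coverage track, take
the 99th percentile (P99) of the maxima values as a robust summary of the
upper signal distribution, and rescale each sample so its P99 matches a
designated reference sample (the first sample of the target group in the
sample sheet).  This equalizes peak-height scales across samples without
assuming equal total chromatin occupancy and without exogenous spike-ins.

A local maximum is a maximal constant-value plateau whose value strictly
exceeds the adjacent signal on both sides, where the flank beyond the
first/last stored run — or across any zero-coverage gap — has value 0.
At true 1 bp resolution integer coverage forms flat plateaus, so the
strictly-greater rule is evaluated at the plateau level (it degenerates to
the per-bin rule when all runs are 1 bp wide).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SampleSheet
from .tracks import SignalTrack, median_tracks

__all__ = [
    "LocalMaximum",
    "NormalizationReport",
    "find_local_maxima",
    "p99_of_maxima",
    "compute_scaling",
    "scale_track",
    "median_track",
]


@dataclass(frozen=True)
class LocalMaximum:
    """A maximal constant-value plateau strictly above both flanks."""

    chrom: str
    start: int
    end: int
    value: float


def find_local_maxima(track: SignalTrack) -> list[LocalMaximum]:
    """All local maxima of a canonical track, sorted by (chrom, start).

    Canonical form guarantees each stored run is a maximal plateau within
    its contiguous stretch; a run's flank is the neighbouring run's value
    when book-ended with it and 0 otherwise (gap or chromosome end).
    """
    out: list[LocalMaximum] = []
    for chrom in sorted(track.runs):
        s, e, v = track.runs[chrom]
        if s.size == 0:
            continue
        left = np.zeros(s.size)
        right = np.zeros(s.size)
        contig_left = s[1:] == e[:-1]
        left[1:][contig_left] = v[:-1][contig_left]
        right[:-1][contig_left] = v[1:][contig_left]
        is_max = (v > left) & (v > right) & (v > 0)
        for i in np.flatnonzero(is_max):
            out.append(LocalMaximum(chrom, int(s[i]), int(e[i]), float(v[i])))
    return out


def p99_of_maxima(maxima: Sequence[LocalMaximum], p: float = 99.0) -> float:
    """p-th percentile (linear interpolation) of the maxima values.

    Each plateau contributes exactly one value, unweighted by its width.
    """
    if not maxima:
        raise ValueError("no signal maxima; sample unusable for normalization")
    values = np.asarray([m.value for m in maxima], dtype=np.float64)
    return float(np.percentile(values, p, method="linear"))


@dataclass
class NormalizationReport:
    """Per-sample P99 summary, printed scaling factors and applied multipliers.

    ``sf_printed`` is P99_sample / P99_reference; the applied multiplier is
    its reciprocal so that post-scaling P99s are equal across samples (the
    reference's multiplier is exactly 1).  With ``literal_sf`` the printed
    factor itself is applied instead.
    """

    table: pd.DataFrame
    reference_sample_id: str
    percentile: float = 99.0

    def multiplier(self, sample_id: str) -> float:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return float(row["multiplier"].iloc[0])

    def to_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def compute_scaling(
    p99_by_sample: Mapping[str, float],
    sheet: SampleSheet,
    target: str,
    n_maxima_by_sample: Mapping[str, int] | None = None,
    percentile: float = 99.0,
    literal_sf: bool = False,
) -> NormalizationReport:
    """Derive per-sample scaling multipliers against the group reference.

    The reference is the first sample of the target group in sheet order.
    Every sample's P99 must be positive.
    """
    group = sheet.target_group(target)
    missing = [r.sample_id for r in group if r.sample_id not in p99_by_sample]
    if missing:
        raise ValueError(f"no P99 provided for sample(s): {missing}")
    ref = group.records[0].sample_id
    p99_ref = float(p99_by_sample[ref])
    rows = []
    for rec in group:
        p99 = float(p99_by_sample[rec.sample_id])
        if not p99 > 0:
            raise ValueError(
                f"sample {rec.sample_id!r} has non-positive P{percentile:g} "
                f"({p99}); cannot normalize"
            )
        sf_printed = p99 / p99_ref
        multiplier = sf_printed if literal_sf else p99_ref / p99
        if rec.sample_id == ref:
            multiplier = 1.0
            sf_printed = 1.0
        rows.append(
            {
                "sample_id": rec.sample_id,
                "condition": rec.condition,
                "n_maxima": (
                    n_maxima_by_sample.get(rec.sample_id)
                    if n_maxima_by_sample
                    else pd.NA
                ),
                "p99": p99,
                "sf_printed": sf_printed,
                "multiplier": multiplier,
                "is_reference": rec.sample_id == ref,
            }
        )
    return NormalizationReport(
        table=pd.DataFrame(rows), reference_sample_id=ref, percentile=percentile
    )


def scale_track(track: SignalTrack, multiplier: float) -> SignalTrack:
    """Multiply every run value by a positive multiplier."""
    return track.scale(multiplier)


def median_track(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-base median of replicate tracks (even counts average the middle two)."""
    return median_tracks(tracks)
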