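"""Per-base fragment coverage from aligned reads, with control subtraction
and blacklist masking.

Coverage is computed at true 1 bp resolution.  In single-end mode every
primary, mapped, MAPQ-passing read contributes its aligned span (optionally
extended to a fixed fragment length from its 5' end, strand-aware).  In
paired-end mode each properly paired fragment is counted once, from the
leftmost mate, as [fragment_start, fragment_start + |TLEN|).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pysam

from .io import GenomeIndex, RegionSet
from .tracks import SignalTrack, mask_track, subtract_tracks

__all__ = [
    "CoverageOptions",
    "coverage_from_alignments",
    "subtract_control",
    "apply_blacklist",
    "track_from_spans",
]


@dataclass(frozen=True)
class CoverageOptions:
    """Read-filtering and counting knobs.

    mapq_min is a convenience only — input BAMs are expected to be
    pre-filtered to high-quality unique alignments.  se_extend is only
    meaningful in SE mode.
    """

    mapq_min: int = 0
    mode: Literal["SE", "PE"] = "PE"
    se_extend: int | None = None
    clamp_negative: bool = True


def track_from_spans(
    spans_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
    genome: GenomeIndex | None = None,
) -> SignalTrack:
    """Pileup of half-open spans into a canonical coverage track."""
    runs = {}
    for chrom, (starts, ends) in spans_by_chrom.items():
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.size == 0:
            continue
        bp = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(bp.size, dtype=np.int64)
        np.add.at(delta, np.searchsorted(bp, starts), 1)
        np.add.at(delta, np.searchsorted(bp, ends), -1)
        depth = np.cumsum(delta)[:-1].astype(np.float64)
        runs[chrom] = (bp[:-1], bp[1:], depth)
    return SignalTrack(runs)


def coverage_from_alignments(
    bam_path: str | Path,
    genome: GenomeIndex,
    opts: CoverageOptions = CoverageOptions(),
) -> tuple[SignalTrack, int]:
    """Build the per-base coverage track from a coordinate-sorted, indexed BAM.

    Returns ``(track, n_units)`` where ``n_units`` is the number of counted
    units (reads in SE mode, fragments in PE mode); the unit count is the
    depth total used to scale controls in :func:`subtract_control`.
    """
    bam_path = str(bam_path)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        try:
            has_index = bam.check_index()
        except (ValueError, AttributeError):
            has_index = False
        if not has_index:
            raise ValueError(f"{bam_path}: BAM index required (.bai missing)")
        offenders = [
            st.contig
            for st in bam.get_index_statistics()
            if st.mapped > 0 and st.contig not in genome
        ]
        if offenders:
            raise ValueError(
                f"{bam_path}: chromosomes with reads absent from genome: {offenders}"
            )
        spans: dict[str, tuple[list[int], list[int]]] = {}
        n_units = 0
        n_skipped_pairs = 0
        for chrom in genome.names:
            if chrom not in bam.references:
                continue
            s_list: list[int] = []
            e_list: list[int] = []
            length = genome[chrom]
            for read in bam.fetch(chrom):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.mapping_quality < opts.mapq_min
                ):
                    continue
                if opts.mode == "SE":
                    start, end = read.reference_start, read.reference_end
                    if opts.se_extend is not None:
                        if read.is_reverse:
                            start = end - opts.se_extend
                        else:
                            end = start + opts.se_extend
                    start = max(0, start)
                    end = min(length, end)
                    if end <= start:
                        continue
                    s_list.append(start)
                    e_list.append(end)
                    n_units += 1
                else:  # PE: count each fragment once, from the leftmost mate
                    if not read.is_proper_pair or read.template_length <= 0:
                        if read.is_paired and read.template_length == 0:
                            n_skipped_pairs += 1
                        continue
                    start = read.reference_start
                    end = min(length, start + read.template_length)
                    if end <= start:
                        continue
                    s_list.append(start)
                    e_list.append(end)
                    n_units += 1
            if s_list:
                spans[chrom] = (
                    np.asarray(s_list, dtype=np.int64),
                    np.asarray(e_list, dtype=np.int64),
                )
    return track_from_spans(spans, genome), n_units


def subtract_control(
    ip: SignalTrack,
    control: SignalTrack,
    ip_total: float,
    control_total: float,
    clamp: bool = True,
) -> SignalTrack:
    """Depth-matched control subtraction.

    The control is scaled to the IP depth (ip_total / control_total) before
    per-base subtraction; negatives are clamped to 0 by default because the
    downstream local-maxima percentile assumes non-negative coverage.
    """
    if control_total == 0:
        raise ValueError("control_total must be positive")
    scale = float(ip_total) / float(control_total)
    return subtract_tracks(ip, control, control_scale=scale, clamp=clamp)


def apply_blacklist(track: SignalTrack, blacklist: RegionSet) -> SignalTrack:
    """Zero all signal inside blacklist regions (idempotent)."""
    if len(blacklist) == 0:
        return track
    return mask_track(track, blacklist.intervals())
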