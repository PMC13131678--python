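"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the normalization method assumes: a
shared landscape of enriched peak regions over uniform background
fragment coverage, per-sample global scale/depth multipliers, and
condition-specific fold changes in a known subset of regions.  Fragment
counts per region are negative-binomially over-dispersed around their
expected depth; fragments are placed uniformly within their region and
emitted as properly paired SAM records (fixed dummy sequence/quality —
no read-sequence realism, mappability or GC structure is modelled).

Everything is deterministic given the config seed; per-sample streams are
derived with ``numpy.random.SeedSequence`` spawn keys so samples are
independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .coverage import track_from_spans
from .io import GenomeIndex, RegionSet
from .tracks import SignalTrack

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_truth",
    "simulate_fragments",
    "simulate_alignments",
    "simulate_scaled_cohort",
    "sam_text",
]

READ_LENGTH = 50


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe a realistic small benchmark: one 1 Mb chromosome,
    300 non-overlapping peaks of lognormal width (median 1 kb, sigma 0.4),
    background of 0.02 expected fragments/bp (~4x base coverage at 200 bp
    fragments), 10-fold peak enrichment, NB dispersion 0.05 on per-region
    fragment counts, and 20% of peaks carrying a 4-fold condition effect
    (split evenly between gains and losses).
    """

    genome: dict[str, int] = field(default_factory=lambda: {"chrSim": 1_000_000})
    n_peaks: int = 300
    peak_width_median: int = 1000
    peak_width_sigma: float = 0.4
    background_rate: float = 0.02
    enrichment: float = 10.0
    diff_fraction: float = 0.2
    diff_fold: float = 4.0
    nb_dispersion: float = 0.05
    fragment_length: int = 200
    seed: int = 0

    def genome_index(self) -> GenomeIndex:
        return GenomeIndex(self.genome.items())


@dataclass
class SimTruth:
    """Ground truth: peak regions and per-region condition fold changes."""

    peaks: RegionSet
    # region label -> fold applied in condition B (absent -> 1.0)
    condition_folds: dict[str, float]

    def fold_for(self, label: str) -> float:
        return self.condition_folds.get(label, 1.0)


def simulate_truth(config: SimConfig) -> SimTruth:
    """Place non-overlapping peaks uniformly at random; assign a seeded
    subset gain/loss folds (alternating) in condition B."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genome = config.genome_index()
    placed: list[tuple[str, int, int]] = []
    chrom_names = genome.names
    lengths = np.array([genome[c] for c in chrom_names], dtype=np.float64)
    probs = lengths / lengths.sum()
    min_gap = config.fragment_length  # keep peaks resolvable as separate maxima
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    attempts = 0
    max_attempts = max(1000, 50 * config.n_peaks)
    while len(placed) < config.n_peaks:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_peaks} non-overlapping peaks "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        ci = rng.choice(len(chrom_names), p=probs)
        chrom = chrom_names[ci]
        width = int(
            np.clip(
                np.rint(
                    config.peak_width_median
                    * np.exp(rng.normal(0.0, config.peak_width_sigma))
                ),
                50,
                genome[chrom],
            )
        )
        if genome[chrom] <= width:
            continue
        start = int(rng.integers(0, genome[chrom] - width))
        end = start + width
        ok = all(
            end + min_gap <= s or start >= e + min_gap for s, e in occupied[chrom]
        )
        if not ok:
            continue
        occupied[chrom].append((start, end))
        placed.append((chrom, start, end))
    peaks = RegionSet.from_intervals(placed, genome=genome)
    labels = peaks.labels()
    n_diff = int(round(config.diff_fraction * len(labels)))
    diff_idx = rng.choice(len(labels), size=n_diff, replace=False) if n_diff else []
    folds = {}
    for k, i in enumerate(sorted(int(i) for i in np.atleast_1d(diff_idx))):
        folds[labels[i]] = config.diff_fold if k % 2 == 0 else 1.0 / config.diff_fold
    return SimTruth(peaks=peaks, condition_folds=folds)


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) via gamma–Poisson mixture; Poisson when disp=0."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_fragments(
    config: SimConfig,
    truth: SimTruth,
    condition: str = "A",
    multiplier: float = 1.0,
    stream: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sample fragment spans for one sample.

    Per-peak fragment counts are NB with mean
    rate × width × enrichment × multiplier × condition_fold (fold applies
    in condition 'B' only); background fragment counts are NB around
    rate × chromosome_length × multiplier.  Returns per-chromosome sorted
    (starts, ends) arrays of half-open fragment spans.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(int(stream),))
    )
    genome = config.genome_index()
    frag = config.fragment_length
    spans: dict[str, list[np.ndarray]] = {c: [] for c in genome.names}
    # background
    for chrom in genome.names:
        length = genome[chrom]
        n_bg = int(
            _nb_counts(
                rng,
                np.array([config.background_rate * length * multiplier]),
                config.nb_dispersion,
            )[0]
        )
        if n_bg:
            starts = rng.integers(0, max(1, length - frag), size=n_bg)
            spans[chrom].append(np.sort(starts))
    # peaks
    labels = truth.peaks.labels()
    for label, (chrom, start, end) in zip(labels, truth.peaks.intervals()):
        fold = truth.fold_for(label) if condition == "B" else 1.0
        mean = (
            config.background_rate
            * (end - start)
            * config.enrichment
            * multiplier
            * fold
        )
        n = int(_nb_counts(rng, np.array([mean]), config.nb_dispersion)[0])
        if n:
            hi = max(start + 1, end - frag)
            starts = rng.integers(start, hi, size=n)
            spans[chrom].append(np.sort(starts))
    out = {}
    for chrom in genome.names:
        if not spans[chrom]:
            continue
        starts = np.sort(np.concatenate(spans[chrom])).astype(np.int64)
        ends = np.minimum(starts + frag, genome[chrom])
        out[chrom] = (starts, ends)
    return out


def sam_text(
    fragments: Mapping[str, tuple[np.ndarray, np.ndarray]],
    genome: GenomeIndex,
    sample_id: str = "sample",
) -> str:
    """Render fragments as properly paired SAM records (text).

    Each fragment yields two reads: the forward mate at the fragment start
    (flag 99) and the reverse mate ending at the fragment end (flag 147),
    with TLEN ±fragment length.  Sequence/quality are fixed dummies.
    """
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, length in genome.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    seq = "A" * READ_LENGTH
    qual = "I" * READ_LENGTH
    cigar = f"{READ_LENGTH}M"
    records = []
    counter = 0
    for chrom in genome.names:
        if chrom not in fragments:
            continue
        starts, ends = fragments[chrom]
        for s, e in zip(starts.tolist(), ends.tolist()):
            tlen = e - s
            name = f"{sample_id}.frag{counter}"
            counter += 1
            r1_pos = s
            r2_pos = max(s, e - READ_LENGTH)
            records.append(
                (chrom, r1_pos,
                 f"{name}\t99\t{chrom}\t{r1_pos + 1}\t60\t{cigar}\t=\t"
                 f"{r2_pos + 1}\t{tlen}\t{seq}\t{qual}")
            )
            records.append(
                (chrom, r2_pos,
                 f"{name}\t147\t{chrom}\t{r2_pos + 1}\t60\t{cigar}\t=\t"
                 f"{r1_pos + 1}\t{-tlen}\t{seq}\t{qual}")
            )
    order = {c: i for i, c in enumerate(genome.names)}
    records.sort(key=lambda r: (order[r[0]], r[1]))
    lines.extend(r[2] for r in records)
    return "\n".join(lines) + "\n"


def simulate_alignments(
    config: SimConfig,
    truth: SimTruth,
    condition: str = "A",
    multiplier: float = 1.0,
    sample_id: str = "sample",
    stream: int = 0,
) -> tuple[str, SignalTrack]:
    """One sample's paired SAM text plus its expected coverage track.

    The returned track is the exact pileup of the emitted fragments, so
    it equals ``coverage_from_alignments`` run on the converted BAM.
    """
    genome = config.genome_index()
    frags = simulate_fragments(config, truth, condition, multiplier, stream)
    text = sam_text(frags, genome, sample_id=sample_id)
    track = track_from_spans(frags, genome)
    return text, track


def simulate_scaled_cohort(
    config: SimConfig,
    factors: Mapping[str, float],
) -> tuple[SimTruth, dict[str, SignalTrack]]:
    """Cohort whose sample tracks are one shared latent track times
    per-sample scale factors.

    This isolates the global-scale structure the normalization method is
    built to remove: the latent fragment landscape is sampled once (from
    the config seed) and each sample's track is that landscape multiplied
    by its factor, so the true relative scale between samples is exactly
    known.  Use :func:`simulate_alignments` per sample for fully
    independent sampling instead.
    """
    truth = simulate_truth(config)
    frags = simulate_fragments(config, truth, condition="A", multiplier=1.0, stream=0)
    latent = track_from_spans(frags, config.genome_index())
    cohort = {
        sample: latent.scale(float(f)) for sample, f in factors.items()
    }
    return truth, cohort
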