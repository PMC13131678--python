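"""Genome-binned sample-similarity diagnostics (PCA and correlation).

Signal is averaged over fixed-width genome tiles (terminal bins keep
their true width), optionally log2(x+1)-transformed, and summarized by
centered PCA over bins and by pairwise sample correlation.  These are the
before/after-normalization QC views of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import GenomeIndex, RegionSet
from .tracks import SignalTrack, region_sums

__all__ = ["BinMatrix", "bin_signal", "pca_coordinates", "correlation_matrix"]

DEFAULT_BIN_WIDTH = 10_000


@dataclass
class BinMatrix:
    """Mean per-base signal per genome tile; rows = bins, columns = samples."""

    bins: RegionSet
    data: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def genome_bins(genome: GenomeIndex, bin_width: int) -> RegionSet:
    """Non-overlapping fixed-width tiles; terminal bins may be shorter."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    ivals = []
    for chrom, length in genome.items():
        edges = np.arange(0, length + bin_width, bin_width, dtype=np.int64)
        edges[-1] = min(edges[-1], length)
        edges = np.unique(edges)
        for i in range(edges.size - 1):
            ivals.append((chrom, int(edges[i]), int(edges[i + 1])))
    return RegionSet.from_intervals(ivals, genome=genome)


def bin_signal(
    tracks: Mapping[str, SignalTrack],
    genome: GenomeIndex,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> BinMatrix:
    """Mean per-base signal in each bin, per sample."""
    bins = genome_bins(genome, bin_width)
    widths = bins.widths().astype(np.float64)
    ivals = bins.intervals()
    cols = {
        sample: region_sums(track, ivals) / widths
        for sample, track in tracks.items()
    }
    return BinMatrix(bins=bins, data=pd.DataFrame(cols, index=bins.labels()))


def pca_coordinates(
    matrix: BinMatrix, log_transform: bool = True, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples over bins.

    Returns (coordinates, variance fractions); PC signs are fixed by
    forcing each component's largest-magnitude loading positive so output
    is deterministic.  log2(x+1) is applied by default.
    """
    X = matrix.data.to_numpy(dtype=np.float64).T  # samples × bins
    if X.shape[0] < 2:
        raise ValueError("PCA requires >= 2 samples")
    if log_transform:
        X = np.log2(X + 1.0)
    k = n_components or min(X.shape[0], X.shape[1])
    k = min(k, X.shape[0], X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero total variance -> NaN fractions
        coords = pca.fit_transform(X)
    for j in range(coords.shape[1]):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            pca.components_[j] *= -1
            coords[:, j] *= -1
    df = pd.DataFrame(
        coords,
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return df, pca.explained_variance_ratio_


def correlation_matrix(matrix: BinMatrix, method: str = "pearson") -> pd.DataFrame:
    """Pairwise sample correlation over bins (pearson or spearman).

    Zero-variance samples yield NA rows/columns (diagonal stays 1).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X = matrix.data.to_numpy(dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
    n = X.shape[1]
    sd = X.std(axis=0)
    out = np.full((n, n), np.nan)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
            elif sd[i] > 0 and sd[j] > 0:
                out[i, j] = C[i, j]
    return pd.DataFrame(out, index=matrix.samples, columns=matrix.samples)
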