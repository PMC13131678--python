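"""Experimental-design metadata and standard interval/signal file formats.

Handles the tab-separated sample sheet (sample_id, bam, condition, target,
optional bam_control), the two-column chrom.sizes file, BED3+ region files,
4-column bedGraph signal and ENCODE narrowPeak/broadPeak.  All coordinates
are 0-based half-open (the BED/bedGraph convention).  Chromosome ordering
for emitted files follows the chrom.sizes file, never the locale.

bedGraph is the bit-exact reference signal format; bigWig read/write is
available as an optional convenience when pyBigWig is installed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .tracks import SignalTrack

__all__ = [
    "SampleRecord",
    "SampleSheet",
    "GenomeIndex",
    "RegionSet",
    "Peak",
    "parse_sample_sheet",
    "read_sample_sheet",
    "parse_chrom_sizes",
    "read_chrom_sizes",
    "read_regions",
    "write_regions",
    "read_bedgraph",
    "write_bedgraph",
    "read_peaks",
    "read_bigwig",
    "write_bigwig",
]


class ValidationError(ValueError):
    """Raised when an input file violates its documented contract."""


# ---------------------------------------------------------------------------
# experimental design


@dataclass(frozen=True)
class SampleRecord:
    """One row of the sample sheet."""

    sample_id: str
    bam_path: str
    condition: str
    target: str
    control_path: str | None = None


@dataclass
class SampleSheet:
    """Ordered experimental design; row order is meaningful.

    The first sample of each target group is the normalization reference,
    so the order of records is preserved exactly as read.
    """

    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            if not r.sample_id:
                raise ValidationError("empty sample_id")
            if r.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {r.sample_id!r}")
            seen.add(r.sample_id)
            if not r.condition or not r.target:
                raise ValidationError(
                    f"sample {r.sample_id!r}: condition and target must be non-empty"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def targets(self) -> list[str]:
        out = []
        for r in self.records:
            if r.target not in out:
                out.append(r.target)
        return out

    def target_group(self, target: str) -> "SampleSheet":
        recs = [r for r in self.records if r.target == target]
        if not recs:
            raise ValidationError(f"no samples with target {target!r}")
        return SampleSheet(recs)

    def conditions(self) -> list[str]:
        out = []
        for r in self.records:
            if r.condition not in out:
                out.append(r.condition)
        return out

    def samples_for(self, condition: str) -> list[SampleRecord]:
        return [r for r in self.records if r.condition == condition]


_REQUIRED_COLUMNS = ("sample_id", "bam", "condition", "target")


def parse_sample_sheet(text: str) -> SampleSheet:
    """Parse the tab-separated sample sheet (header row required)."""
    df = pd.read_csv(
        _io.StringIO(text), sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        control = row.get("bam_control", "")
        control = control.strip() if isinstance(control, str) else ""
        records.append(
            SampleRecord(
                sample_id=row["sample_id"].strip(),
                bam_path=row["bam"].strip(),
                condition=row["condition"].strip(),
                target=row["target"].strip(),
                control_path=control or None,
            )
        )
    return SampleSheet(records)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return parse_sample_sheet(Path(path).read_text())


class GenomeIndex:
    """Ordered chromosome → length map (order as in the chrom.sizes file)."""

    def __init__(self, items: Iterable[tuple[str, int]] = ()):
        self._lengths: dict[str, int] = {}
        for name, length in items:
            if name in self._lengths:
                raise ValidationError(f"duplicate chromosome {name!r}")
            length = int(length)
            if length < 1:
                raise ValidationError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
            self._lengths[name] = length

    def __len__(self) -> int:
        return len(self._lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self):
        return iter(self._lengths)

    def items(self):
        return self._lengths.items()

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def rank(self, name: str) -> int:
        """Sort key implementing chrom.sizes file order."""
        return list(self._lengths).index(name)

    def __eq__(self, other):
        return isinstance(other, GenomeIndex) and list(self.items()) == list(
            other.items()
        )


def parse_chrom_sizes(text: str) -> GenomeIndex:
    """Parse a two-column name<TAB>length file (no header)."""
    items = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"chrom.sizes line {ln}: expected 2 columns")
        name = fields[0].strip()
        try:
            length = int(fields[1])
        except ValueError as exc:
            raise ValidationError(
                f"chrom.sizes line {ln}: non-integer length {fields[1]!r}"
            ) from exc
        items.append((name, length))
    return GenomeIndex(items)


def read_chrom_sizes(path: str | Path) -> GenomeIndex:
    return parse_chrom_sizes(Path(path).read_text())


# ---------------------------------------------------------------------------
# regions (BED)


class RegionSet:
    """Canonical sorted set of half-open genomic intervals.

    Extra BED columns are retained as opaque annotations and written back
    verbatim.  Sorting uses the genome's chromosome order when a
    :class:`GenomeIndex` is attached, lexicographic order otherwise.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        genome: GenomeIndex | None = None,
    ):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"RegionSet requires a {col!r} column")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"region {bad['chrom']}:{bad['start']}-{bad['end']} has start >= end"
            )
        if len(df) and (df["start"] < 0).any():
            raise ValidationError("negative region coordinates")
        if genome is not None and len(df):
            unknown = sorted(set(df["chrom"]) - set(genome.names))
            if unknown:
                raise ValidationError(f"chromosome(s) not in genome: {unknown}")
            too_far = df["end"] > df["chrom"].map(dict(genome.items()))
            if too_far.any():
                bad = df[too_far].iloc[0]
                raise ValidationError(
                    f"region {bad['chrom']}:{bad['start']}-{bad['end']} exceeds "
                    "chromosome length"
                )
        if genome is not None:
            key = df["chrom"].map({c: i for i, c in enumerate(genome.names)})
        else:
            key = df["chrom"]
        order = np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(), key.to_numpy()))
        self.df = df.iloc[order].reset_index(drop=True)
        self.genome = genome

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int]],
        genome: GenomeIndex | None = None,
    ) -> "RegionSet":
        rows = list(intervals)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        if not rows:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "start": pd.Series(dtype=np.int64),
                               "end": pd.Series(dtype=np.int64)})
        return cls(df, genome=genome)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> list[tuple[str, int, int]]:
        return list(
            zip(self.df["chrom"], self.df["start"].tolist(), self.df["end"].tolist())
        )

    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        return int(self.widths().sum())

    def labels(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in self.intervals()]

    def __eq__(self, other):
        return isinstance(other, RegionSet) and self.intervals() == other.intervals()

    def __repr__(self):
        return f"RegionSet({len(self)} regions, {self.total_bp()} bp)"


def read_regions(path: str | Path, genome: GenomeIndex | None = None) -> RegionSet:
    """Read a BED3+ file; columns beyond the third are kept as annotations."""
    rows = []
    n_extra = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}:{ln}: BED needs >= 3 columns")
        rows.append(fields)
        n_extra = max(n_extra, len(fields) - 3)
    cols = ["chrom", "start", "end"] + [f"extra{i}" for i in range(n_extra)]
    norm_rows = [r + [""] * (3 + n_extra - len(r)) for r in rows]
    df = pd.DataFrame(norm_rows, columns=cols)
    if not rows:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
    return RegionSet(df, genome=genome)


def write_regions(
    regions: RegionSet,
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write a sorted BED file; ``header`` becomes leading '#' comment lines."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for _, row in regions.df.iterrows():
            fields = [str(row["chrom"]), str(row["start"]), str(row["end"])]
            extras = [str(row[c]) for c in regions.df.columns if c.startswith("extra")]
            while extras and extras[-1] == "":
                extras.pop()
            fh.write("\t".join(fields + extras) + "\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, genome: GenomeIndex | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a canonical :class:`SignalTrack`.

    Overlapping intervals and out-of-genome coordinates are errors; zero
    runs are dropped and book-ended equal values merged on the way in.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise ValidationError(f"{path}:{ln}: bedGraph needs 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if genome is not None:
            if chrom not in genome:
                raise ValidationError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if end > genome[chrom]:
                raise ValidationError(
                    f"{path}:{ln}: interval exceeds chromosome length"
                )
        by_chrom.setdefault(chrom, []).append((start, end, value))
    runs = {}
    for chrom, triples in by_chrom.items():
        s, e, v = zip(*triples)
        runs[chrom] = (np.asarray(s), np.asarray(e), np.asarray(v))
    try:
        return SignalTrack(runs)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_bedgraph(
    track: SignalTrack,
    path: str | Path,
    genome: GenomeIndex | None = None,
    header: str | None = None,
) -> None:
    """Write a canonical bedGraph; value formatting round-trips exactly."""
    chroms = track.chroms
    if genome is not None:
        chroms = sorted(chroms, key=genome.rank)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for chrom in chroms:
            s, e, v = track.runs[chrom]
            for i in range(s.size):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{_fmt(v[i])}\n")


def _fmt(x: float) -> str:
    """Shortest exact decimal representation (float repr round-trips)."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


# ---------------------------------------------------------------------------
# ENCODE peaks


@dataclass(frozen=True)
class Peak:
    """A called peak; ``neg_log10_q`` is None when the caller left q at -1."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    neg_log10_q: float | None = None

    @property
    def qvalue(self) -> float | None:
        if self.neg_log10_q is None:
            return None
        return 10.0 ** (-self.neg_log10_q)


def read_peaks(path: str | Path) -> list[Peak]:
    """Read ENCODE narrowPeak (10 col) or broadPeak (9 col).

    Column 9 holds −log10(q); the MACS convention of −1 marks an
    uncomputed q, which we map to ``neg_log10_q=None`` so such peaks are
    excluded from every q-filtered set downstream.
    """
    peaks = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise ValidationError(
                f"{path}:{ln}: narrowPeak/broadPeak needs >= 9 columns"
            )
        q = float(f[8])
        peaks.append(
            Peak(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                name=f[3] if len(f) > 3 else ".",
                score=float(f[4]) if len(f) > 4 else 0.0,
                neg_log10_q=None if q < 0 else q,
            )
        )
    for p in peaks:
        if p.start >= p.end:
            raise ValidationError(f"{path}: peak {p.chrom}:{p.start}-{p.end} invalid")
    return peaks


# ---------------------------------------------------------------------------
# optional bigWig support


def read_bigwig(path: str | Path) -> SignalTrack:
    """Read a bigWig into a SignalTrack (requires pyBigWig)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("bigWig support requires the pyBigWig package") from exc
    runs = {}
    with pyBigWig.open(str(path)) as bw:
        for chrom in bw.chroms():
            ivals = bw.intervals(chrom)
            if not ivals:
                continue
            s, e, v = zip(*ivals)
            runs[chrom] = (np.asarray(s), np.asarray(e), np.asarray(v))
    return SignalTrack(runs)


def write_bigwig(track: SignalTrack, path: str | Path, genome: GenomeIndex) -> None:
    """Write a SignalTrack to bigWig (requires pyBigWig)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("bigWig support requires the pyBigWig package") from exc
    bw = pyBigWig.open(str(path), "w")
    chroms = [c for c in genome.names if c in track.runs]
    bw.addHeader([(c, genome[c]) for c in genome.names])
    for chrom in chroms:
        s, e, v = track.runs[chrom]
        bw.addEntries(
            [chrom] * s.size, s.tolist(), ends=e.tolist(), values=v.tolist()
        )
    bw.close()
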