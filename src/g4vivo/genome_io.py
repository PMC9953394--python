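"""Genomic coordinate primitives and readers for BED, FASTA and signal tracks.

All coordinates are BED-native: 0-based, half-open ``[start, end)``.
Intervals read from files always have ``start >= 0``; intervals produced by
flank extension may have a negative start or run past the chromosome end, and
the fetch functions resolve those positions by padding (``N`` for sequence,
``0.0`` for signal) rather than raising.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GenomeSequence",
    "FastaGenome",
    "DictGenome",
    "SignalTrack",
    "ArrayTrack",
    "BedGraphTrack",
    "BigWigTrack",
    "BedParseError",
    "UnknownChromosomeError",
    "read_bed",
    "write_bed",
    "fetch_sequence",
    "fetch_signal",
    "open_genome",
    "open_signal_track",
]


class BedParseError(ValueError):
    """A BED line that cannot be interpreted; message names the line number."""


class UnknownChromosomeError(KeyError):
    """Chromosome name absent from a genome or signal track."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open.

    ``start`` may be negative for computed flank regions near a chromosome
    origin; file readers never produce such intervals.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor midpoint: ``start + length // 2``."""
        return self.start + self.length // 2


class PeakSet:
    """A collection of :class:`GenomicInterval` kept sorted by (chrom, start, end)."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})


def read_bed(path: str | os.PathLike, min_columns: int = 3) -> PeakSet:
    """Read a BED file into a sorted :class:`PeakSet`.

    Strand is taken from column 6 when present (``.`` otherwise), name from
    column 4 and score from column 5. ``track``/``browser``/``#`` lines and
    blank lines are skipped. Malformed coordinates raise :class:`BedParseError`
    naming the offending line; unknown chromosome names are not checked here.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < max(min_columns, 3):
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= {max(min_columns, 3)} "
                    f"columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise BedParseError(
                    f"{path}: line {lineno}: invalid strand {strand!r}"
                )
            intervals.append(
                GenomicInterval(fields[0], start, end, strand, name, score)
            )
    return PeakSet(intervals)


def write_bed(peaks: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED6 (BED3 when neither name/score/strand is set)."""
    with open(path, "w") as fh:
        for iv in peaks:
            if iv.name is None and iv.score is None and iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = "0" if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# Genome sequence backends


class GenomeSequence:
    """Base class: per-chromosome sequence access plus a sizes table."""

    sizes: Mapping[str, int]

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        raise NotImplementedError

    def fetch(self, iv: GenomicInterval) -> str:
        return fetch_sequence(self, iv)


class DictGenome(GenomeSequence):
    """In-memory genome backed by a ``{chrom: sequence}`` mapping."""

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}
        self.sizes = {c: len(s) for c, s in self._seqs.items()}

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]


class FastaGenome(GenomeSequence):
    """Genome backed by an indexed FASTA file (pyfaidx)."""

    def __init__(self, path: str | os.PathLike):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        self.sizes = {name: len(rec) for name, rec in self._fasta.items()}

    def _raw_fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start:end])


def fetch_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Fetch exactly ``iv.length`` uppercase bases, padding out-of-bounds with N."""
    if iv.chrom not in genome.sizes:
        raise UnknownChromosomeError(
            f"chromosome {iv.chrom!r} not in genome ({sorted(genome.sizes)})"
        )
    size = genome.sizes[iv.chrom]
    lo, hi = max(iv.start, 0), min(iv.end, size)
    core = genome._raw_fetch(iv.chrom, lo, hi) if lo < hi else ""
    left, right = lo - iv.start, iv.end - hi
    if left or right:
        log.warning(
            "interval %s:%d-%d extends outside [0, %d); padding %d bp with N",
            iv.chrom, iv.start, iv.end, size, left + right,
        )
    return "N" * left + core.upper() + "N" * right


# ---------------------------------------------------------------------------
# Signal track backends


class SignalTrack:
    """Per-base float coverage; unstored or out-of-bounds positions read 0.0."""

    sizes: Mapping[str, int]

    def _raw_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over ``[start, end)`` already clipped to the chromosome."""
        raise NotImplementedError

    def values(self, iv: GenomicInterval) -> np.ndarray:
        return fetch_signal(self, iv)


class ArrayTrack(SignalTrack):
    """In-memory track: one dense float array per chromosome."""

    def __init__(self, arrays: Mapping[str, np.ndarray]):
        self._arrays = {c: np.asarray(a, dtype=np.float64) for c, a in arrays.items()}
        self.sizes = {c: len(a) for c, a in self._arrays.items()}

    def _raw_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self._arrays[chrom][start:end]


class BedGraphTrack(SignalTrack):
    """Track parsed from a 4-column bedGraph into dense per-chromosome arrays.

    bedGraph carries no chromosome-sizes header; sizes default to the maximal
    end coordinate seen per chromosome unless supplied explicitly.
    """

    def __init__(self, path: str | os.PathLike, sizes: Mapping[str, int] | None = None):
        import pandas as pd

        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "value": np.float64},
        )
        if sizes is None:
            sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
        self.sizes = dict(sizes)
        self._arrays: dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=np.float64) for c, n in self.sizes.items()
        }
        for chrom, sub in df.groupby("chrom", sort=False):
            arr = self._arrays[chrom]
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                arr[max(s, 0):min(e, len(arr))] = v

    def _raw_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self._arrays[chrom][start:end]


class BigWigTrack(SignalTrack):
    """Track backed by a bigWig file (pyBigWig); NaN runs read as 0.0."""

    def __init__(self, path: str | os.PathLike):
        import pyBigWig

        self._bw = pyBigWig.open(str(path))
        self.sizes = dict(self._bw.chroms())

    def _raw_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        if start >= end:
            return np.zeros(0)
        vals = np.asarray(self._bw.values(chrom, start, end), dtype=np.float64)
        return np.nan_to_num(vals, nan=0.0)

    def close(self) -> None:
        self._bw.close()


def fetch_signal(track: SignalTrack, iv: GenomicInterval) -> np.ndarray:
    """Fetch exactly ``iv.length`` floats, zero-filling out-of-bounds positions."""
    if iv.chrom not in track.sizes:
        raise UnknownChromosomeError(
            f"chromosome {iv.chrom!r} not in signal track ({sorted(track.sizes)})"
        )
    size = track.sizes[iv.chrom]
    out = np.zeros(iv.length, dtype=np.float64)
    lo, hi = max(iv.start, 0), min(iv.end, size)
    if lo < hi:
        out[lo - iv.start : hi - iv.start] = track._raw_values(iv.chrom, lo, hi)
    return out


def open_genome(path: str | os.PathLike) -> GenomeSequence:
    """Open a FASTA genome (creates the .fai index if missing)."""
    return FastaGenome(path)


_BIGWIG_EXT = {".bw", ".bigwig"}
_BEDGRAPH_EXT = {".bedgraph", ".bg", ".bdg"}


def open_signal_track(
    path: str | os.PathLike,
    fmt: str | None = None,
    sizes: Mapping[str, int] | None = None,
) -> SignalTrack:
    """Open a signal track, sniffing bigWig vs bedGraph from the extension.

    ``fmt`` ("bigwig" or "bedgraph") overrides the sniff.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        if ext in _BIGWIG_EXT:
            fmt = "bigwig"
        elif ext in _BEDGRAPH_EXT:
            fmt = "bedgraph"
        else:
            raise ValueError(
                f"cannot sniff signal-track format from {path!r}; pass fmt="
            )
    if fmt == "bigwig":
        return BigWigTrack(path)
    if fmt == "bedgraph":
        return BedGraphTrack(path, sizes=sizes)
    raise ValueError(f"unknown signal-track format {fmt!r}")
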