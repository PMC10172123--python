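"""Run-length depth tracks, coverage histograms and fitting windows.

The substrate of the whole pipeline is the per-base read depth of the
assembly.  Internally every track is kept in maximal run-length form:
per contig, sorted half-open blocks ``(start, end, depth)`` that tile
``[0, contig_length)`` exactly.  All coordinates are 0-based half-open;
the samtools-depth dialect (1-based positions) and the ``.cov`` dialect
(1-based inclusive ranges) are converted at the I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

MAX_DEPTH = 2**31 - 1


def rle_encode(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal run-length encoding of a 1-D array.

    Returns (starts, ends, values) with half-open runs.
    """
    values = np.asarray(values)
    if values.size == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z.copy()
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change)).astype(np.int64)
    ends = np.concatenate((change, [values.size])).astype(np.int64)
    return starts, ends, values[starts].astype(np.int64)


class CoverageTrack:
    """Run-length per-base depth over a set of contigs.

    Blocks for each contig are sorted, non-overlapping, maximal (adjacent
    blocks differ in depth) and tile ``[0, contig_length)`` exactly; a
    contig with no data is represented as a single depth-0 block.
    """

    def __init__(self, lengths: Mapping[str, int]):
        self.lengths: dict[str, int] = {str(c): int(n) for c, n in lengths.items()}
        for c, n in self.lengths.items():
            if n <= 0:
                raise ParseError(f"contig {c!r} has non-positive length {n}")
        self._blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {
            c: (
                np.array([0], dtype=np.int64),
                np.array([n], dtype=np.int64),
                np.array([0], dtype=np.int64),
            )
            for c, n in self.lengths.items()
        }

    # -- construction -----------------------------------------------------

    def set_blocks(
        self,
        contig: str,
        starts: Sequence[int],
        ends: Sequence[int],
        depths: Sequence[int],
    ) -> None:
        """Install blocks for ``contig``, validating and canonicalizing.

        The blocks must tile ``[0, length)``; equal-depth neighbours are
        merged so the stored form is maximal.
        """
        if contig not in self.lengths:
            raise ParseError(f"unknown contig {contig!r}")
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        d = np.asarray(depths, dtype=np.int64)
        if not (s.shape == e.shape == d.shape):
            raise ParseError(f"contig {contig!r}: ragged block arrays")
        if s.size == 0:
            raise ParseError(f"contig {contig!r}: empty block list")
        if np.any(e <= s):
            raise ParseError(f"contig {contig!r}: empty or inverted block")
        if np.any(d < 0) or np.any(d > MAX_DEPTH):
            raise ParseError(f"contig {contig!r}: depth out of range")
        if s[0] != 0 or e[-1] != self.lengths[contig] or np.any(s[1:] != e[:-1]):
            raise ParseError(
                f"contig {contig!r}: blocks do not tile [0, {self.lengths[contig]})"
            )
        # merge equal-depth neighbours -> maximal form
        keep = np.concatenate(([True], d[1:] != d[:-1]))
        s = s[keep]
        d = d[keep]
        e = np.concatenate((s[1:], [self.lengths[contig]]))
        self._blocks[contig] = (s, e, d)

    def set_per_base(self, contig: str, depths: np.ndarray) -> None:
        if contig not in self.lengths:
            raise ParseError(f"unknown contig {contig!r}")
        if len(depths) != self.lengths[contig]:
            raise ParseError(
                f"contig {contig!r}: {len(depths)} depths for length "
                f"{self.lengths[contig]}"
            )
        s, e, d = rle_encode(depths)
        if np.any(d < 0):
            raise ParseError(f"contig {contig!r}: negative depth")
        self._blocks[contig] = (s, e, d)

    # -- access ------------------------------------------------------------

    def contigs(self) -> list[str]:
        return list(self.lengths)

    def arrays(self, contig: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._blocks[contig]

    def blocks(self, contig: str) -> list[tuple[int, int, int]]:
        s, e, d = self._blocks[contig]
        return list(zip(s.tolist(), e.tolist(), d.tolist()))

    def total_bases(self) -> int:
        return sum(self.lengths.values())

    def slice_arrays(
        self, contig: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Blocks clipped to [start, end) with coordinates preserved."""
        if contig not in self.lengths:
            raise ParseError(f"unknown contig {contig!r}")
        if not (0 <= start < end <= self.lengths[contig]):
            raise ParseError(
                f"region {contig}:{start}-{end} outside contig of length "
                f"{self.lengths[contig]}"
            )
        s, e, d = self._blocks[contig]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        s = s[lo:hi].copy()
        e = e[lo:hi].copy()
        d = d[lo:hi]
        if s.size:
            s[0] = max(s[0], start)
            e[-1] = min(e[-1], end)
        return s, e, d

    def per_base(self, contig: str, start: int = 0, end: int | None = None) -> np.ndarray:
        if end is None:
            end = self.lengths[contig]
        s, e, d = self.slice_arrays(contig, start, end)
        return np.repeat(d, e - s)

    def min_depth_in(self, contig: str, start: int, end: int) -> int:
        _, _, d = self.slice_arrays(contig, start, end)
        return int(d.min())

    def mean_depth(self) -> float:
        total = 0.0
        for c in self.lengths:
            s, e, d = self._blocks[c]
            total += float(np.dot(d, e - s))
        return total / self.total_bases()

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.lengths != other.lengths:
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._blocks[c], other._blocks[c]))
            for c in self.lengths
        )


class CoverageHistogram:
    """Depth -> base-count table.

    ``counts[k]`` is the number of bases with depth ``k``; the array is
    dense from depth 0 up to the maximum observed depth.
    """

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ValueError("counts must be a 1-D non-negative array")
        # trim trailing zeros but keep at least depth 0
        nz = np.flatnonzero(counts)
        if nz.size:
            counts = counts[: nz[-1] + 1]
        else:
            counts = counts[:1] if counts.size else np.zeros(1, dtype=np.int64)
        self.counts = counts
        self.total_bases = int(counts.sum())

    @classmethod
    def from_pairs(cls, depths: Iterable[int], ncounts: Iterable[int]) -> "CoverageHistogram":
        depths = np.asarray(list(depths), dtype=np.int64)
        ncounts = np.asarray(list(ncounts), dtype=np.int64)
        if depths.size == 0:
            return cls(np.zeros(1, dtype=np.int64))
        if np.any(depths < 0):
            raise ValueError("negative depth in histogram")
        counts = np.zeros(int(depths.max()) + 1, dtype=np.int64)
        np.add.at(counts, depths, ncounts)
        return cls(counts)

    @property
    def max_depth(self) -> int:
        return len(self.counts) - 1

    def n_distinct(self) -> int:
        return int(np.count_nonzero(self.counts))

    def mean(self) -> float:
        if self.total_bases == 0:
            return 0.0
        return float(np.dot(np.arange(len(self.counts)), self.counts)) / self.total_bases

    def as_dict(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in enumerate(self.counts) if v > 0}

    def __add__(self, other: "CoverageHistogram") -> "CoverageHistogram":
        n = max(len(self.counts), len(other.counts))
        counts = np.zeros(n, dtype=np.int64)
        counts[: len(self.counts)] += self.counts
        counts[: len(other.counts)] += other.counts
        return CoverageHistogram(counts)

    def write_counts(self, out) -> None:
        """Two-column TSV: depth, number of bases (zero rows omitted)."""
        close = False
        if isinstance(out, (str, bytes)):
            out = open(out, "w")
            close = True
        try:
            for k, v in enumerate(self.counts):
                if v > 0:
                    out.write(f"{k}\t{v}\n")
        finally:
            if close:
                out.close()

    @classmethod
    def read_counts(cls, stream) -> "CoverageHistogram":
        close = False
        if isinstance(stream, (str, bytes)):
            stream = open(stream)
            close = True
        depths, ncounts = [], []
        try:
            for i, line in enumerate(stream, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError("expected two columns (depth, count)", line=i)
                try:
                    depths.append(int(parts[0]))
                    ncounts.append(int(parts[1]))
                except ValueError:
                    raise ParseError(f"non-integer field in {line!r}", line=i) from None
        finally:
            if close:
                stream.close()
        return cls.from_pairs(depths, ncounts)


@dataclass(frozen=True)
class Window:
    """A fitting window: contiguous span of one contig (or the pooled genome)."""

    contig: str
    start: int
    end: int
    source: str = "window"  # "window" | "whole_genome"


# ---------------------------------------------------------------------------
# FASTA index / depth-table / .cov I/O
# ---------------------------------------------------------------------------


def read_fai(path_or_stream) -> dict[str, int]:
    """Contig lengths from a FASTA index (first two columns)."""
    close = False
    stream = path_or_stream
    if isinstance(path_or_stream, (str, bytes)):
        stream = open(path_or_stream)
        close = True
    lengths: dict[str, int] = {}
    try:
        for i, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected >=2 tab-separated columns", line=i)
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer length {parts[1]!r}", line=i) from None
    finally:
        if close:
            stream.close()
    return lengths


def read_depth_table(stream, contig_index: Mapping[str, int]) -> CoverageTrack:
    """Parse a samtools-depth table (contig, 1-based position, depth).

    Bases present in ``contig_index`` but absent from the stream get depth
    0, so both ``-aa`` (all bases reported) and sparse tables round-trip to
    a full tiling.  Positions must be strictly increasing within a contig
    and each contig must form one contiguous run of lines.
    """
    if isinstance(stream, (str, bytes)):
        with open(stream) as fh:
            return read_depth_table(fh, contig_index)

    track = CoverageTrack(contig_index)
    try:
        df = pd.read_csv(
            stream,
            sep="\t",
            header=None,
            names=["contig", "pos", "depth"],
            dtype={"contig": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        return track
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"malformed depth table: {exc}") from None
    if len(df) == 0:
        return track

    # factorize codes are assigned in order of first appearance, so a contig
    # split across non-adjacent runs shows up as a non-monotone code sequence
    codes = pd.factorize(df["contig"])[0]
    if np.any(np.diff(codes) < 0):
        bad = int(np.flatnonzero(np.diff(codes) < 0)[0]) + 2
        raise ParseError("contig appears in multiple non-adjacent runs", line=bad)

    boundaries = np.concatenate(
        (np.flatnonzero(np.diff(codes)) + 1, [len(df)])
    )
    lo = 0
    pos = df["pos"].to_numpy()
    depth = df["depth"].to_numpy()
    names = df["contig"].to_numpy()
    for hi in boundaries:
        contig = names[lo]
        if contig not in contig_index:
            raise ParseError(f"unknown contig {contig!r}", line=lo + 1)
        p = pos[lo:hi]
        d = depth[lo:hi]
        dp = np.diff(p)
        if np.any(dp <= 0):
            bad = lo + int(np.flatnonzero(dp <= 0)[0]) + 2
            raise ParseError(
                f"non-monotone position on contig {contig!r}", line=bad
            )
        n = contig_index[contig]
        if p[0] < 1 or p[-1] > n:
            raise ParseError(
                f"position outside contig {contig!r} of length {n}", line=lo + 1
            )
        if np.any(d < 0):
            raise ParseError(f"negative depth on contig {contig!r}", line=lo + 1)
        full = np.zeros(n, dtype=np.int64)
        full[p - 1] = d
        track.set_per_base(contig, full)
        lo = hi
    return track


def write_cov(track: CoverageTrack, out=None) -> str | None:
    """Serialize a track to the run-length ``.cov`` dialect.

    Header line ``>contig length`` followed by ``start end depth`` records,
    1-based inclusive, tab separated.  Consecutive equal-depth bases take a
    single record.
    """
    buf = out
    return_text = out is None
    close = False
    if return_text:
        buf = io.StringIO()
    elif isinstance(out, (str, bytes)):
        buf = open(out, "w")
        close = True
    try:
        for contig in track.contigs():
            buf.write(f">{contig} {track.lengths[contig]}\n")
            s, e, d = track.arrays(contig)
            for a, b, v in zip(s, e, d):
                buf.write(f"{a + 1}\t{b}\t{v}\n")
        if return_text:
            return buf.getvalue()
        return None
    finally:
        if close:
            buf.close()


def read_cov(stream) -> CoverageTrack:
    """Parse the ``.cov`` dialect back into a track (inverse of write_cov)."""
    if isinstance(stream, (str, bytes)):
        with open(stream) as fh:
            return read_cov(fh)
    lengths: dict[str, int] = {}
    per_contig: dict[str, list[tuple[int, int, int]]] = {}
    contig = None
    for i, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            parts = line[1:].split()
            if len(parts) != 2:
                raise ParseError("header must be '>contig length'", line=i)
            contig = parts[0]
            try:
                lengths[contig] = int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer contig length {parts[1]!r}", line=i) from None
            per_contig[contig] = []
        else:
            if contig is None:
                raise ParseError("record before any contig header", line=i)
            parts = line.split()
            if len(parts) != 3:
                raise ParseError("expected 'start end depth'", line=i)
            try:
                a, b, v = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"non-integer field in {line!r}", line=i) from None
            if a < 1 or b < a:
                raise ParseError(f"bad range {a}-{b}", line=i)
            per_contig[contig].append((a - 1, b, v))
    track = CoverageTrack(lengths)
    for contig, blocks in per_contig.items():
        if not blocks:
            raise ParseError(f"contig {contig!r} has a header but no records")
        s, e, d = (np.array(x, dtype=np.int64) for x in zip(*blocks))
        track.set_blocks(contig, s, e, d)
    return track


# ---------------------------------------------------------------------------
# Histograms and windows
# ---------------------------------------------------------------------------


def track_to_histogram(
    track: CoverageTrack,
    region: Iterable[tuple[str, int, int]] | None = None,
) -> CoverageHistogram:
    """Depth histogram of a track, optionally restricted to intervals.

    ``region`` is an iterable of ``(contig, start, end)`` half-open
    intervals; they must lie on contigs of the track.
    """
    all_depths: list[np.ndarray] = []
    all_lens: list[np.ndarray] = []
    if region is None:
        for contig in track.contigs():
            s, e, d = track.arrays(contig)
            all_depths.append(d)
            all_lens.append(e - s)
    else:
        for contig, start, end in region:
            s, e, d = track.slice_arrays(contig, start, end)
            all_depths.append(d)
            all_lens.append(e - s)
    if not all_depths:
        return CoverageHistogram(np.zeros(1, dtype=np.int64))
    depths = np.concatenate(all_depths)
    lens = np.concatenate(all_lens)
    if depths.size == 0:
        return CoverageHistogram(np.zeros(1, dtype=np.int64))
    counts = np.bincount(depths, weights=lens).astype(np.int64)
    return CoverageHistogram(counts)


def split_track_by_window(
    track: CoverageTrack, window_size: int, min_contig: int
) -> list[tuple[Window, CoverageHistogram]]:
    """Tile long contigs into fitting windows and histogram each window.

    Contigs no longer than ``min_contig`` yield no windows; downstream
    they are labeled with the whole-genome model instead.  The last
    window of a contig may be shorter than ``window_size``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    out: list[tuple[Window, CoverageHistogram]] = []
    for contig in track.contigs():
        n = track.lengths[contig]
        if n <= min_contig:
            continue
        for start in range(0, n, window_size):
            end = min(start + window_size, n)
            hist = track_to_histogram(track, region=[(contig, start, end)])
            out.append((Window(contig, start, end, "window"), hist))
    return out


def depth_from_alignments(
    records: Iterable, contig_index: Mapping[str, int], min_mapq: int = 0
) -> CoverageTrack:
    """Per-base count of alignments overlapping each base.

    Records need ``contig``, ``start`` (0-based), ``ref_span`` and ``mapq``
    attributes.  When ``min_mapq > 0``, alignments with MAPQ below it are
    excluded — e.g. ``min_mapq=21`` keeps only MAPQ>20 alignments for the
    high-confidence auxiliary track.
    """
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in contig_index.items()}
    for rec in records:
        if min_mapq > 0 and rec.mapq < min_mapq:
            continue
        if rec.contig not in diffs:
            raise ParseError(f"alignment on unknown contig {rec.contig!r}")
        end = rec.start + rec.ref_span
        if rec.start < 0 or end > contig_index[rec.contig]:
            raise ParseError(
                f"alignment {rec.read_id!r} at {rec.contig}:{rec.start}-{end} "
                f"exceeds contig bounds"
            )
        diffs[rec.contig][rec.start] += 1
        diffs[rec.contig][end] -= 1
    track = CoverageTrack(contig_index)
    for contig, diff in diffs.items():
        track.set_per_base(contig, np.cumsum(diff[:-1]))
    return track


def read_bed(path_or_stream) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader: (contig, start, end, name); name '' if absent."""
    close = False
    stream = path_or_stream
    if isinstance(path_or_stream, (str, bytes)):
        stream = open(path_or_stream)
        close = True
    out = []
    try:
        for i, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED needs >=3 columns", line=i)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"non-integer BED coordinates in {line!r}", line=i) from None
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], start, end, name))
    finally:
        if close:
            stream.close()
    return out
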