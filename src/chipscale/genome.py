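"""Genome layout, fixed-width bin grids, and fragment-to-bin coverage.

Everything downstream of alignment operates on a fixed grid of genomic
bins (default 500 bp) tiling each sequence without gaps or overlaps.
Coverage is the *mean per-base fragment depth* per bin: total fragment
bases overlapping the bin divided by the bin length, so that summing
``value * bin_length`` over the grid recovers the total sequenced
fragment bases exactly.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chipscale")

__all__ = [
    "FormatError",
    "GridMismatchError",
    "EstimationError",
    "GenomeLayout",
    "BinGrid",
    "FragmentSet",
    "BinnedCoverage",
    "load_genome_layout",
    "make_bin_grid",
    "fragment_coverage",
    "read_fragments_bed",
    "write_fragments_bed",
    "write_bedgraph",
    "read_bedgraph",
]


class FormatError(ValueError):
    """A file or record violates the expected on-disk format."""


class GridMismatchError(ValueError):
    """Two binned tracks that must share a grid do not."""


class EstimationError(RuntimeError):
    """A statistic cannot be computed from the given data (e.g. no usable bins)."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes/sequences of a genome assembly.

    The order given at construction is canonical and preserved by every
    derived structure (bin grids, coverage tracks, region sets).
    """

    sequences: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sequences]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise FormatError(f"duplicate sequence name: {dup!r}")
        for name, length in self.sequences:
            if length <= 0:
                raise FormatError(f"non-positive length for sequence {name!r}: {length}")

    @cached_property
    def lengths(self) -> dict[str, int]:
        return dict(self.sequences)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


def load_genome_layout(path: str | Path) -> GenomeLayout:
    """Parse a two-column chrom.sizes file (name<TAB>length) in file order."""
    seqs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>length, got {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: length is not an integer: {parts[1]!r}") from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            if any(name == n for n, _ in seqs):
                raise FormatError(f"{path}:{lineno}: duplicate sequence name {name!r}")
            seqs.append((name, length))
    if not seqs:
        raise FormatError(f"{path}: empty chrom.sizes file")
    return GenomeLayout(tuple(seqs))


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.sequences:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Bin grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling a genome layout.

    Each sequence is tiled with ``ceil(length / bin_size)`` bins; the final
    bin of a sequence may be shorter and keeps its true length (used as the
    denominator when averaging coverage, so edge bins are not inflated).
    """

    layout: GenomeLayout
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {self.bin_size}")

    @cached_property
    def bins_per_sequence(self) -> dict[str, int]:
        return {n: -(-l // self.bin_size) for n, l in self.layout.sequences}

    @cached_property
    def offsets(self) -> dict[str, int]:
        """Global index of the first bin of each sequence."""
        out, acc = {}, 0
        for name, _ in self.layout.sequences:
            out[name] = acc
            acc += self.bins_per_sequence[name]
        return out

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_sequence.values())

    @cached_property
    def bin_lengths(self) -> np.ndarray:
        """Length in bp of every bin, in global order."""
        parts = []
        for name, length in self.layout.sequences:
            n = self.bins_per_sequence[name]
            lens = np.full(n, self.bin_size, dtype=np.int64)
            lens[-1] = length - (n - 1) * self.bin_size
            parts.append(lens)
        return np.concatenate(parts)

    def bins(self) -> Iterator[tuple[str, int, int]]:
        """Yield (sequence, start, end) for every bin in global order."""
        for name, length in self.layout.sequences:
            for start in range(0, length, self.bin_size):
                yield name, start, min(start + self.bin_size, length)

    def sequence_slice(self, name: str) -> slice:
        """Slice of the global value array covering one sequence's bins."""
        off = self.offsets[name]
        return slice(off, off + self.bins_per_sequence[name])

    def bin_index(self, name: str, pos: int) -> int:
        """Global bin index containing position ``pos`` on sequence ``name``."""
        if name not in self.layout:
            raise KeyError(f"unknown sequence {name!r}")
        return self.offsets[name] + pos // self.bin_size


def make_bin_grid(layout: GenomeLayout, bin_size: int = 500) -> BinGrid:
    return BinGrid(layout, bin_size)


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


@dataclass
class FragmentSet:
    """Aligned DNA fragments as half-open intervals, grouped per sequence.

    ``by_sequence`` maps sequence name to (starts, ends) int64 arrays.
    One record corresponds to one sequenced DNA fragment (the span of a
    properly paired read pair).
    """

    by_sequence: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for name, (starts, ends) in self.by_sequence.items():
            if len(starts) != len(ends):
                raise ValueError(f"{name}: starts/ends length mismatch")
            if np.any(ends <= starts):
                raise FormatError(f"{name}: fragment with end <= start")

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, int, int]]) -> "FragmentSet":
        by: dict[str, list[tuple[int, int]]] = {}
        for seq, s, e in records:
            by.setdefault(seq, []).append((s, e))
        out = {}
        for seq, ivs in by.items():
            arr = np.asarray(ivs, dtype=np.int64)
            out[seq] = (arr[:, 0].copy(), arr[:, 1].copy())
        return cls(out)

    @property
    def n_fragments(self) -> int:
        return sum(len(s) for s, _ in self.by_sequence.values())

    @property
    def total_bases(self) -> int:
        return int(sum((e - s).sum() for s, e in self.by_sequence.values()))


def read_fragments_bed(path: str | Path, fmt: str = "auto") -> FragmentSet:
    """Read fragments from BED3 (one record per fragment) or BEDPE.

    BEDPE records are converted to the full fragment span
    (min start .. max end of the two ends); mates on different sequences
    are rejected.  ``fmt`` is "bed", "bedpe" or "auto" (sniff: a BEDPE line
    has a sequence name in column 4 and integers in columns 5-6, while BED6
    has a numeric score in column 5 and a strand in column 6).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need at least 3 columns, found {df.shape[1]}")
    if fmt == "auto":
        fmt = "bed"
        if df.shape[1] >= 6:
            c4, c5 = df.iloc[0, 4], df.iloc[0, 5]
            try:
                int(c4), int(c5)
                fmt = "bedpe"
            except (TypeError, ValueError):
                fmt = "bed"
    if fmt == "bedpe":
        if df.shape[1] < 6:
            raise FormatError(f"{path}: BEDPE needs 6 columns")
        if not (df[0] == df[3]).all():
            raise FormatError(f"{path}: BEDPE mates on different sequences")
        s = np.minimum(df[1].astype(np.int64), df[4].astype(np.int64))
        e = np.maximum(df[2].astype(np.int64), df[5].astype(np.int64))
        out_df = pd.DataFrame({"seq": df[0], "start": s, "end": e})
    elif fmt == "bed":
        out_df = pd.DataFrame(
            {"seq": df[0], "start": df[1].astype(np.int64), "end": df[2].astype(np.int64)}
        )
    else:
        raise ValueError(f"unknown fragment format {fmt!r}")
    by = {
        str(seq): (g["start"].to_numpy(), g["end"].to_numpy())
        for seq, g in out_df.groupby("seq", sort=False)
    }
    return FragmentSet(by)


def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq, (starts, ends) in frags.by_sequence.items():
            for s, e in zip(starts.tolist(), ends.tolist()):
                fh.write(f"{seq}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Binned coverage
# ---------------------------------------------------------------------------


@dataclass
class BinnedCoverage:
    """Mean per-base fragment depth on a bin grid.

    Invariant: ``sum(values * grid.bin_lengths) == total_bases`` (the
    fragment bases accumulated into the track), up to float tolerance.
    """

    grid: BinGrid
    values: np.ndarray
    total_bases: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.grid.n_bins:
            raise ValueError(
                f"values length {len(self.values)} != grid n_bins {self.grid.n_bins}"
            )
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    def same_grid(self, other: "BinnedCoverage") -> bool:
        return self.grid == other.grid

    def require_same_grid(self, other: "BinnedCoverage") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("coverage tracks are on different bin grids")


def fragment_coverage(fragments: FragmentSet, grid: BinGrid) -> BinnedCoverage:
    """Accumulate fragments into mean per-base depth per bin.

    Fragments extending past their sequence end are clipped (with a
    warning); fragments on sequences absent from the layout are an error.
    Implementation: per-base depth via a difference array and cumulative
    sum, then per-bin sums with ``add.reduceat`` — exact integer
    accumulation before the final division by bin length.
    """
    layout = grid.layout
    values = np.zeros(grid.n_bins, dtype=np.float64)
    total_bases = 0
    for seq, (starts, ends) in fragments.by_sequence.items():
        if seq not in layout:
            raise FormatError(f"fragment on unknown sequence {seq!r}")
        seqlen = layout.lengths[seq]
        s = np.clip(starts, 0, seqlen)
        e = np.clip(ends, 0, seqlen)
        n_clipped = int(np.count_nonzero((starts != s) | (ends != e)))
        if n_clipped:
            logger.warning("%s: clipped %d fragments to sequence bounds", seq, n_clipped)
        keep = e > s
        s, e = s[keep], e[keep]
        diff = np.zeros(seqlen + 1, dtype=np.int64)
        np.add.at(diff, s, 1)
        np.add.at(diff, e, -1)
        depth = np.cumsum(diff[:-1])
        bin_starts = np.arange(0, seqlen, grid.bin_size, dtype=np.int64)
        per_bin_bases = np.add.reduceat(depth, bin_starts)
        sl = grid.sequence_slice(seq)
        values[sl] = per_bin_bases / grid.bin_lengths[sl]
        total_bases += int((e - s).sum())
    return BinnedCoverage(grid, values, float(total_bases))


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------


def write_bedgraph(cov: BinnedCoverage, path: str | Path, zero_suppress: bool = True) -> None:
    """Write coverage as bedGraph; zero-valued bins are omitted by default."""
    with open(path, "w") as fh:
        i = 0
        for seq, start, end in cov.grid.bins():
            v = cov.values[i]
            i += 1
            if zero_suppress and v == 0.0:
                continue
            fh.write(f"{seq}\t{start}\t{end}\t{v:.10g}\n")


def read_bedgraph(path: str | Path, grid: BinGrid) -> BinnedCoverage:
    """Read a bedGraph written on ``grid``; records must align to grid bins.

    Bins absent from the file are restored as zeros (zero-suppressed
    output round-trips).  A record straddling a bin boundary is a format
    error.
    """
    values = np.zeros(grid.n_bins, dtype=np.float64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            seq, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if seq not in grid.layout:
                raise FormatError(f"{path}:{lineno}: unknown sequence {seq!r}")
            seqlen = grid.layout.lengths[seq]
            if start % grid.bin_size != 0:
                raise FormatError(f"{path}:{lineno}: record start {start} not on a bin boundary")
            expected_end = min(start + grid.bin_size, seqlen)
            if end != expected_end:
                raise FormatError(
                    f"{path}:{lineno}: record [{start},{end}) does not match grid bin "
                    f"[{start},{expected_end})"
                )
            values[grid.bin_index(seq, start)] = val
    total = float((values * grid.bin_lengths).sum())
    return BinnedCoverage(grid, values, total)
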