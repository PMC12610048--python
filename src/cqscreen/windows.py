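"""Genome tiling and filtered per-window read counting.

Windows are 0-based half-open and laid down per contig from position 0 at a
fixed step.  Counting supports two assignment modes: ``start`` (a read is
assigned to every window containing its leftmost aligned position — with a
non-overlapping tiling each read is counted exactly once) and ``overlap``
(a read is assigned to every window its aligned span intersects).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "Window",
    "WindowCount",
    "CountFilters",
    "WindowGapWarning",
    "make_windows",
    "count_reads",
    "counts_to_tsv",
    "read_counts_tsv",
]


class WindowGapWarning(UserWarning):
    """Raised when step > window, which leaves untiled gaps between windows."""


@dataclass(frozen=True, order=True)
class Window:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end}) on {self.contig!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowCount:
    window: Window
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


_KNOWN_EXCLUDE = frozenset({"unmapped", "secondary", "supplementary", "duplicate"})


@dataclass(frozen=True)
class CountFilters:
    """Read filters applied before window assignment.

    Defaults drop unmapped, secondary, supplementary and duplicate records
    and apply no mapping-quality cut.
    """

    min_mapq: int = 0
    exclude: frozenset[str] = _KNOWN_EXCLUDE
    assignment_mode: str = "start"

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        unknown = set(self.exclude) - _KNOWN_EXCLUDE
        if unknown:
            raise ValueError(f"unknown exclude flags: {sorted(unknown)}")
        if self.assignment_mode not in ("start", "overlap"):
            raise ValueError(f"assignment_mode must be 'start' or 'overlap', got {self.assignment_mode!r}")

    def passes(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False  # no coordinate to assign regardless of the flag set
        if "secondary" in self.exclude and read.is_secondary:
            return False
        if "supplementary" in self.exclude and read.is_supplementary:
            return False
        if "duplicate" in self.exclude and read.is_duplicate:
            return False
        return read.mapping_quality >= self.min_mapq


def make_windows(
    contig_lengths: Mapping[str, int] | Sequence[tuple[str, int]],
    window: int = 500,
    step: int = 1000,
) -> list[Window]:
    """Tile contigs with fixed-size windows.

    Windows start at 0 and every ``step`` bp thereafter; the last window of
    a contig is truncated at the contig end.  When ``step`` exceeds
    ``window`` the tiling leaves (step - window)-bp gaps; this is allowed —
    it reproduces a published parameterization — but a
    :class:`WindowGapWarning` is emitted.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if step > window:
        warnings.warn(
            f"step ({step}) > window ({window}): {step - window} bp between "
            "consecutive windows is never tiled and windows can never overlap",
            WindowGapWarning,
            stacklevel=2,
        )
    items = contig_lengths.items() if isinstance(contig_lengths, Mapping) else contig_lengths
    out: list[Window] = []
    for contig, length in items:
        for start in range(0, length, step):
            out.append(Window(contig, start, min(start + window, length)))
    return out


def _iter_alignments(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def count_reads(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    windows: Sequence[Window],
    filters: CountFilters | None = None,
) -> list[WindowCount]:
    """Count filtered reads per window from a coordinate-sorted alignment stream.

    In ``start`` mode a read increments every window containing its leftmost
    aligned position; in ``overlap`` mode every window intersecting its
    aligned reference span.  Output order matches the window order.  The
    stream must be coordinate-sorted (grouped by contig, non-decreasing
    positions); violation raises ``ValueError`` naming the first offending
    record, as does a read on a contig absent from the window list.
    """
    filters = filters or CountFilters()
    counts = [0] * len(windows)

    # Per-contig window geometry, preserving global output order.
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    index: dict[str, list[int]] = {}
    span: dict[str, int] = {}
    for i, w in enumerate(windows):
        starts.setdefault(w.contig, []).append(w.start)
        ends.setdefault(w.contig, []).append(w.end)
        index.setdefault(w.contig, []).append(i)
        span[w.contig] = max(span.get(w.contig, 0), len(w))
    for contig, ss in starts.items():
        if any(a > b for a, b in zip(ss, ss[1:])):
            raise ValueError(f"windows on {contig!r} are not sorted by start")

    overlap_mode = filters.assignment_mode == "overlap"
    seen: set[str] = set()
    last_contig: str | None = None
    last_pos = -1
    for read in _iter_alignments(alignments):
        if not filters.passes(read):
            continue
        contig = read.reference_name
        pos = read.reference_start
        if contig != last_contig:
            if contig in seen:
                raise ValueError(
                    f"input not coordinate-sorted: contig {contig!r} reappears at "
                    f"record {read.query_name!r}"
                )
            seen.add(contig)
            last_contig, last_pos = contig, -1
        if pos < last_pos:
            raise ValueError(
                f"input not coordinate-sorted: record {read.query_name!r} at "
                f"{contig}:{pos} after position {last_pos}"
            )
        last_pos = pos
        if contig not in starts:
            raise ValueError(f"record {read.query_name!r} maps to unknown contig {contig!r}")

        c_starts, c_ends, c_index, c_span = starts[contig], ends[contig], index[contig], span[contig]
        if overlap_mode:
            read_end = read.reference_end or (pos + (read.query_length or 1))
            j = bisect_right(c_starts, read_end - 1) - 1
            while j >= 0 and c_starts[j] + c_span > pos:
                if c_ends[j] > pos:
                    counts[c_index[j]] += 1
                j -= 1
        else:
            j = bisect_right(c_starts, pos) - 1
            while j >= 0 and c_starts[j] + c_span > pos:
                if c_ends[j] > pos:
                    counts[c_index[j]] += 1
                j -= 1

    return [WindowCount(w, c) for w, c in zip(windows, counts)]


def counts_to_tsv(counts: Sequence[WindowCount], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tcount\n")
        for wc in counts:
            w = wc.window
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{wc.count}\n")


def read_counts_tsv(path: str | Path) -> list[WindowCount]:
    df = pd.read_csv(path, sep="\t")
    return [
        WindowCount(Window(str(r.contig), int(r.start), int(r.end)), int(r.count))
        for r in df.itertuples()
    ]
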