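"""Merging retained windows into candidate regions and flank extraction.

Regions are 0-based half-open internally (BED convention); report writers
that mirror the 1-based inclusive style used in genome-browser coordinates
convert at the boundary.  Both length conventions are implemented because
published coordinate spans mix them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cq import CQRecord

__all__ = [
    "Region",
    "merge_windows",
    "region_length",
    "extract_flanks",
    "regions_to_bed",
    "regions_to_tsv",
    "read_regions",
]


@dataclass(frozen=True)
class Region:
    """A merged candidate male-specific interval with aggregate statistics."""

    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    n_windows: int = 1
    min_cq: float = float("nan")
    sum_hm: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end}) on {self.contig!r}")

    def __len__(self) -> int:
        return self.end - self.start


def merge_windows(retained: Sequence[CQRecord], merge_gap: int = 0) -> list[Region]:
    """Union retained windows whose separation is at most ``merge_gap`` bp.

    With the default ``merge_gap = 0`` only overlapping or bookended windows
    coalesce (the literal merge-overlapping rule).  A 500-bp window / 1000-bp
    step tiling can never produce overlapping windows, so reproducing that
    parameterization with coalescing regions requires ``merge_gap >= 500``;
    see the regions docs.  Input must be sorted by (contig, start); output
    regions are sorted and pairwise disjoint, and the merge is idempotent.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    for a, b in zip(retained, retained[1:]):
        if a.window.contig == b.window.contig and a.window.start > b.window.start:
            raise ValueError(
                f"retained windows not sorted: {a.window} precedes {b.window}"
            )

    out: list[Region] = []
    cur: dict | None = None
    for rec in retained:
        w = rec.window
        if cur is not None and w.contig == cur["contig"] and w.start - cur["end"] <= merge_gap:
            cur["end"] = max(cur["end"], w.end)
            cur["n"] += 1
            cur["sum_hm"] += rec.hm
            if rec.cq_defined:
                cur["min_cq"] = min(cur["min_cq"], rec.cq)
        else:
            if cur is not None:
                out.append(_close(cur))
            cur = {
                "contig": w.contig,
                "start": w.start,
                "end": w.end,
                "n": 1,
                "sum_hm": rec.hm,
                "min_cq": rec.cq if rec.cq_defined else float("inf"),
            }
    if cur is not None:
        out.append(_close(cur))
    return out


def _close(cur: dict) -> Region:
    min_cq = cur["min_cq"] if cur["min_cq"] != float("inf") else float("nan")
    return Region(cur["contig"], cur["start"], cur["end"], cur["n"], min_cq, cur["sum_hm"])


def region_length(start: int, end: int, convention: str = "half_open") -> int:
    """Interval length under an explicit coordinate convention.

    ``half_open``: [start, end) -> end - start (BED style).
    ``inclusive``: [start, end] -> end - start + 1 (browser style).
    """
    if convention not in ("half_open", "inclusive"):
        raise ValueError(f"convention must be 'half_open' or 'inclusive', got {convention!r}")
    if end < start:
        raise ValueError(f"negative length: start {start} > end {end}")
    return end - start if convention == "half_open" else end - start + 1


def extract_flanks(
    region: Region,
    reference: Mapping[str, str],
    flank: int = 1000,
) -> SeqRecord:
    """Region sequence extended by ``flank`` bp on each side, for primer design.

    The extension is clamped at the contig boundaries.  ``reference`` is any
    mapping from contig name to sequence (a plain dict, a ``pyfaidx.Fasta``,
    ...).  The record id encodes the extended interval as 1-based inclusive
    coordinates, ``contig:start-end``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if region.contig not in reference:
        raise KeyError(f"unknown contig {region.contig!r} in reference")
    seq = str(reference[region.contig])
    clen = len(seq)
    if region.end > clen:
        raise ValueError(
            f"region [{region.start}, {region.end}) exceeds contig {region.contig!r} "
            f"length {clen}"
        )
    s = max(0, region.start - flank)
    e = min(clen, region.end + flank)
    return SeqRecord(
        Seq(seq[s:e]),
        id=f"{region.contig}:{s + 1}-{e}",
        description=f"region={region.contig}:{region.start + 1}-{region.end} flank={flank}",
    )


def regions_to_bed(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tregion_{i:03d}\n")


def regions_to_tsv(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart_1based\tend\tlength\tn_windows\tmin_CQ\tsum_Hm\n")
        for r in regions:
            fh.write(
                f"{r.contig}\t{r.start + 1}\t{r.end}\t{len(r)}\t{r.n_windows}\t"
                f"{r.min_cq:.4g}\t{r.sum_hm}\n"
            )


def read_regions(path: str | Path) -> list[Region]:
    """Read regions from a BED file (name column optional, aggregates not restored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(Region(parts[0], int(parts[1]), int(parts[2])))
    return out
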