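"""Model/Results interface to the chromosome-quotient screen.

:class:`ChromosomeQuotientScreen` is built from per-window male and female
pool counts (or directly from two coordinate-sorted alignment files) and a
:class:`~cqscreen.cq.ScreenConfig`; :meth:`~ChromosomeQuotientScreen.fit`
runs the quotient computation, retention filtering and window merging and
returns a :class:`ScreenResults` carrying the per-window table, the merged
candidate regions and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .cq import CQRecord, ScreenConfig, compute_cq, records_to_frame, select_windows
from .regions import Region, merge_windows, regions_to_bed, regions_to_tsv
from .windows import CountFilters, WindowCount, count_reads, make_windows

__all__ = ["ChromosomeQuotientScreen", "ScreenResults"]


class ChromosomeQuotientScreen:
    """Screen a male-derived reference for male-specific windows.

    Parameters
    ----------
    male_counts, female_counts
        Per-window read counts for the XY and XX pool, covering identical
        windows in identical order (use :func:`cqscreen.windows.count_reads`
        or :meth:`from_alignments`).
    config
        Screen thresholds and merge gap; defaults follow the published
        parameterization (window 500, step 1000, CQ < 0.2, Hm > 30).
    """

    def __init__(
        self,
        male_counts: Sequence[WindowCount],
        female_counts: Sequence[WindowCount],
        config: ScreenConfig | None = None,
    ):
        self.male_counts = list(male_counts)
        self.female_counts = list(female_counts)
        self.config = config or ScreenConfig()

    @classmethod
    def from_alignments(
        cls,
        male: str | Path | pysam.AlignmentFile,
        female: str | Path | pysam.AlignmentFile,
        config: ScreenConfig | None = None,
        filters: CountFilters | None = None,
        contig_lengths: dict[str, int] | None = None,
    ) -> "ChromosomeQuotientScreen":
        """Build the model by windowing and counting two SAM/BAM files.

        Contig lengths default to the male file's @SQ header lines; both
        pools are counted over the identical window set.
        """
        config = config or ScreenConfig()
        if contig_lengths is None:
            with pysam.AlignmentFile(str(male), check_sq=False) as fh:
                contig_lengths = dict(zip(fh.references, fh.lengths))
        windows = make_windows(contig_lengths, config.window, config.step)
        mc = count_reads(male, windows, filters)
        fc = count_reads(female, windows, filters)
        return cls(mc, fc, config)

    def fit(self) -> "ScreenResults":
        records = compute_cq(self.male_counts, self.female_counts, self.config)
        retained = select_windows(records)
        regions = merge_windows(retained, self.config.merge_gap)
        return ScreenResults(self, records, retained, regions)


@dataclass
class ScreenResults:
    """Fitted screen: per-window quotients, retained windows, merged regions."""

    model: ChromosomeQuotientScreen
    records: list[CQRecord]
    retained: list[CQRecord]
    regions: list[Region]

    @property
    def config(self) -> ScreenConfig:
        return self.model.config

    @property
    def frame(self) -> pd.DataFrame:
        """Per-window table: contig, start, end, Hm, Hf, CQ, retained."""
        return records_to_frame(self.records)

    def median_cq(self) -> float:
        vals = [r.cq for r in self.records if r.cq_defined]
        return float(np.median(vals)) if vals else float("nan")

    def summary(self) -> str:
        cfg = self.config
        total_m = sum(r.hm for r in self.records)
        total_f = sum(r.hf for r in self.records)
        lines = [
            "Chromosome Quotient Screen Results",
            "=" * 44,
            f"windows                {len(self.records):>12}",
            f"window / step (bp)     {cfg.window:>6} / {cfg.step}",
            f"male pool reads (Hm)   {total_m:>12}",
            f"female pool reads (Hf) {total_f:>12.0f}",
            f"depth normalization    {str(cfg.normalize_depth):>12}",
            f"median CQ              {self.median_cq():>12.3f}",
            f"retention              CQ < {cfg.cq_max}, Hm > {cfg.hm_min}",
            f"retained windows       {len(self.retained):>12}",
            f"merge gap (bp)         {cfg.merge_gap:>12}",
            f"candidate regions      {len(self.regions):>12}",
            f"candidate span (bp)    {sum(len(r) for r in self.regions):>12}",
            "=" * 44,
        ]
        for i, r in enumerate(self.regions[:20], 1):
            lines.append(
                f"  region_{i:03d}  {r.contig}:{r.start + 1}-{r.end}  "
                f"len={len(r)}  windows={r.n_windows}  minCQ={r.min_cq:.3g}  sumHm={r.sum_hm}"
            )
        if len(self.regions) > 20:
            lines.append(f"  ... {len(self.regions) - 20} more regions")
        return "\n".join(lines)

    def to_bed(self, path: str | Path) -> None:
        regions_to_bed(self.regions, path)

    def to_tsv(self, path: str | Path) -> None:
        regions_to_tsv(self.regions, path)

    def plot(self, contig: str | None = None, ax=None):
        """CQ along one contig with the retention threshold; windows with
        undefined CQ (Hm = 0) are omitted."""
        import matplotlib.pyplot as plt

        df = self.frame
        if contig is None:
            contig = df["contig"].iloc[0]
        sub = df[(df["contig"] == contig) & df["CQ"].notna()]
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        ax.scatter(sub["start"], sub["CQ"], s=4, c=np.where(sub["retained"], "crimson", "steelblue"))
        ax.axhline(self.config.cq_max, ls="--", lw=1, color="gray")
        ax.set_xlabel(f"{contig} position (bp)")
        ax.set_ylabel("CQ = Hf / Hm")
        ax.set_title(f"chromosome quotient, {contig}")
        return ax
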