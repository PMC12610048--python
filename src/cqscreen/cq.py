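"""The chromosome quotient (CQ) statistic and retention filtering.

For each window the screen compares the number of female-pool reads (Hf)
with the number of male-pool reads (Hm) mapped to a male-derived reference:
CQ = Hf / Hm.  Sequence present only on the Y haplotype receives no female
reads, so male-specific windows show CQ near 0 while shared sequence sits
near the pool depth ratio.  Windows with CQ strictly below ``cq_max`` and
Hm strictly above ``hm_min`` are retained as candidates.

Threshold comparisons on raw counts are made in exact rational arithmetic
(Hf/Hm versus the decimal threshold), so behaviour at the boundary —
CQ exactly 0.2 is rejected — is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from .windows import Window, WindowCount

__all__ = ["ScreenConfig", "CQRecord", "compute_cq", "select_windows", "records_to_frame", "records_to_tsv"]


@dataclass(frozen=True)
class ScreenConfig:
    """Screen parameters.

    window/step in bp; ``cq_max`` and ``hm_min`` are the strict retention
    thresholds (defaults 0.2 and 30); ``normalize_depth`` rescales Hf by the
    male/female total read ratio before division (off by default — the
    published screen applies no depth correction despite unequal pool
    depths); ``merge_gap`` is the maximum separation in bp at which retained
    windows are unioned into one region.
    """

    window: int = 500
    step: int = 1000
    cq_max: float = 0.2
    hm_min: int = 30
    normalize_depth: bool = False
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.cq_max <= 0:
            raise ValueError("cq_max must be > 0")
        if self.hm_min < 0:
            raise ValueError("hm_min must be >= 0")
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be > 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass(frozen=True)
class CQRecord:
    """Per-window counts and quotient.

    ``hf`` may be fractional when depth normalization is applied; ``cq`` is
    NaN when undefined (Hm = 0), in which case the window is never retained.
    """

    window: Window
    hm: int
    hf: float
    cq: float
    retained: bool

    @property
    def cq_defined(self) -> bool:
        return not math.isnan(self.cq)


def _retain(hm: int, hf: float, config: ScreenConfig) -> bool:
    if hm <= config.hm_min or hm == 0:
        return False
    if isinstance(hf, int) or float(hf).is_integer():
        # exact rational comparison: Hf/Hm < cq_max with the threshold read
        # as printed decimal, so e.g. 20/100 is rejected by the strict <
        return Fraction(int(hf), hm) < Fraction(str(config.cq_max))
    return hf / hm < config.cq_max


def compute_cq(
    male_counts: Sequence[WindowCount],
    female_counts: Sequence[WindowCount],
    config: ScreenConfig | None = None,
) -> list[CQRecord]:
    """Compute CQ = Hf/Hm per window and flag retained windows.

    Both count lists must cover identical windows in identical order.  With
    ``normalize_depth`` the female counts are scaled by
    (total male reads / total female reads) before division.
    """
    config = config or ScreenConfig()
    if len(male_counts) != len(female_counts):
        raise ValueError(
            f"pools cover different numbers of windows: {len(male_counts)} male vs "
            f"{len(female_counts)} female"
        )
    scale = 1.0
    if config.normalize_depth:
        total_m = sum(c.count for c in male_counts)
        total_f = sum(c.count for c in female_counts)
        if total_f > 0:
            scale = total_m / total_f

    records: list[CQRecord] = []
    for m, f in zip(male_counts, female_counts):
        if m.window != f.window:
            raise ValueError(
                f"window mismatch between pools: male {m.window} vs female {f.window}"
            )
        hm = m.count
        hf = f.count * scale if config.normalize_depth else f.count
        if hm == 0:
            records.append(CQRecord(m.window, hm, float(hf), float("nan"), False))
        else:
            records.append(
                CQRecord(m.window, hm, float(hf), hf / hm, _retain(hm, hf, config))
            )
    return records


def select_windows(
    records: Sequence[CQRecord], config: ScreenConfig | None = None
) -> list[CQRecord]:
    """Return the retained records, in coordinate order.

    With a ``config``, retention is re-evaluated against its thresholds
    (strict CQ < cq_max and Hm > hm_min), so records computed once can be
    re-screened at different cutoffs; without one the stored flags are used.
    """
    if config is None:
        return [r for r in records if r.retained]
    out = []
    for r in records:
        keep = r.hm > 0 and _retain(r.hm, r.hf, config)
        if keep:
            out.append(replace(r, retained=True))
    return out


def records_to_frame(records: Sequence[CQRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [r.window.contig for r in records],
            "start": [r.window.start for r in records],
            "end": [r.window.end for r in records],
            "Hm": [r.hm for r in records],
            "Hf": [r.hf for r in records],
            "CQ": [r.cq for r in records],
            "retained": [r.retained for r in records],
        }
    )


def records_to_tsv(records: Sequence[CQRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> list[CQRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CQRecord(
            Window(str(r.contig), int(r.start), int(r.end)),
            int(r.Hm),
            float(r.Hf),
            float(r.CQ),
            bool(r.retained),
        )
        for r in df.itertuples()
    ]
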