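"""In-silico PCR: amplicon prediction, gel band patterns, marker calls.

A primer pair amplifies wherever the forward primer matches the plus strand
and the reverse primer's reverse complement occurs downstream on the same
strand; the amplicon spans both primer footprints.  Matching is exact by
default; an optional mismatch tolerance still requires the three terminal
3' bases of each primer to match exactly (polymerase extension is
3'-anchored).  No thermodynamic model is attempted — the purpose is band
*pattern* prediction, not efficiency.

Band patterns collapse amplicon lengths that a gel cannot resolve: with the
default 20-bp resolution (1% agarose scale) any two reported bands differ
by more than 20 bp.  A marker is sex-informative in an XX/XY system when
the male genotype shows every female band plus at least one extra — the
two-bands-in-males / one-band-in-females readout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PrimerPair",
    "Amplicon",
    "BandPattern",
    "MarkerCall",
    "reverse_complement",
    "find_amplicons",
    "genotype_bands",
    "classify_marker",
    "read_primers",
    "load_bundled_primers",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A marker assay: forward and reverse primers, both written 5'->3'."""

    name: str
    forward: str
    reverse: str
    expected_size: int | None = None  # designer's expected product, metadata only
    tm: float | None = None  # annealing temperature, metadata only

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())
        for role, seq in (("forward", self.forward), ("reverse", self.reverse)):
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"primer {self.name!r} {role} contains non-ACGT symbols: {sorted(bad)}"
                )
            if len(seq) < 15:
                raise ValueError(
                    f"primer {self.name!r} {role} is {len(seq)} bp; minimum is 15"
                )


@dataclass(frozen=True)
class Amplicon:
    """A predicted product on the plus strand of one template, half-open."""

    template_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BandPattern:
    """Distinct gel bands (bp) for one genotype at a given resolution."""

    bands: tuple[int, ...]
    resolution: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(sorted(self.bands)))


class MarkerCall(Enum):
    MALE_EXTRA_BAND = "male_extra_band"
    UNINFORMATIVE = "uninformative"
    NO_AMPLIFICATION = "no_amplification"
    AMBIGUOUS = "ambiguous"


def _find_sites(template: str, probe: str, max_mismatch: int, anchor: str) -> list[int]:
    """Start positions where ``probe`` matches ``template``.

    ``anchor`` is 'right' when the probe's 3' end is its last base (forward
    primer) or 'left' when, after reverse complementation, the 3' end maps
    to the first base (reverse primer site on the plus strand); the three
    anchored bases must match exactly.
    """
    n, m = len(template), len(probe)
    if max_mismatch == 0:
        sites, i = [], template.find(probe)
        while i != -1:
            sites.append(i)
            i = template.find(probe, i + 1)
        return sites
    sites = []
    anchor_range = range(m - 3, m) if anchor == "right" else range(0, 3)
    for i in range(n - m + 1):
        mism = 0
        ok = True
        for j in range(m):
            if template[i + j] != probe[j]:
                if j in anchor_range:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            sites.append(i)
    return sites


def find_amplicons(
    template: str,
    pair: PrimerPair,
    max_len: int = 5000,
    max_mismatch: int = 0,
    template_id: str = "template",
) -> list[Amplicon]:
    """All products of ``pair`` on ``template``, up to ``max_len`` bp.

    Every pairing of a forward site with a downstream reverse-complement
    site is reported (product length includes both primer footprints).  The
    default 5000-bp ceiling corresponds to what a standard 2-minute
    extension step can amplify.
    """
    if not template:
        raise ValueError("template is empty")
    template = template.upper()
    f_sites = _find_sites(template, pair.forward, max_mismatch, anchor="right")
    rc = reverse_complement(pair.reverse)
    r_sites = _find_sites(template, rc, max_mismatch, anchor="left")
    out = []
    for f in f_sites:
        for r in r_sites:
            if r < f:
                continue
            length = r + len(rc) - f
            if 0 < length <= max_len:
                out.append(Amplicon(template_id, f, r + len(rc)))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def collapse_lengths(lengths: Iterable[int], resolution: int) -> tuple[int, ...]:
    """Collapse amplicon lengths into gel-distinguishable bands.

    Sorted unique lengths are clustered greedily: a length joins the current
    band while it is within ``resolution`` bp of the band's smallest member,
    and each band is reported as that smallest member.
    """
    bands: list[int] = []
    for length in sorted(set(lengths)):
        if bands and length - bands[-1] <= resolution:
            continue
        bands.append(length)
    return tuple(bands)


def genotype_bands(
    haplotypes: Sequence[str],
    pair: PrimerPair,
    resolution: int = 20,
    max_len: int = 5000,
    max_mismatch: int = 0,
) -> BandPattern:
    """Predicted gel pattern for a genotype given its haplotype sequences.

    An XX genotype carries two X haplotypes, an XY genotype one X and one
    Y-inclusive haplotype; the pattern is the union of amplicon lengths
    across haplotypes collapsed at the gel resolution.
    """
    if not 1 <= len(haplotypes) <= 2:
        raise ValueError(f"expected 1-2 haplotypes, got {len(haplotypes)}")
    lengths: list[int] = []
    for k, hap in enumerate(haplotypes):
        lengths.extend(
            a.length
            for a in find_amplicons(hap, pair, max_len, max_mismatch, template_id=f"hap{k}")
        )
    return BandPattern(collapse_lengths(lengths, resolution), resolution)


def _matches(band: int, others: Sequence[int], resolution: int) -> bool:
    return any(abs(band - o) <= resolution for o in others)


def classify_marker(male: BandPattern, female: BandPattern) -> MarkerCall:
    """Call a marker from its per-sex band patterns.

    ``male_extra_band`` — the sex-informative outcome — requires every
    female band to appear in the male pattern plus at least one extra male
    band; identical non-empty patterns are ``uninformative``; no product in
    either sex is ``no_amplification``; anything else (a female-only band,
    male dropout) is ``ambiguous``.
    """
    if male.resolution != female.resolution:
        raise ValueError(
            f"patterns computed at different resolutions: {male.resolution} vs {female.resolution}"
        )
    res = male.resolution
    if not male.bands and not female.bands:
        return MarkerCall.NO_AMPLIFICATION
    female_in_male = all(_matches(b, male.bands, res) for b in female.bands)
    male_in_female = all(_matches(b, female.bands, res) for b in male.bands)
    if female_in_male and male_in_female and len(male.bands) == len(female.bands):
        return MarkerCall.UNINFORMATIVE
    if female.bands and female_in_male and not male_in_female:
        return MarkerCall.MALE_EXTRA_BAND
    return MarkerCall.AMBIGUOUS


def read_primers(path: str | Path) -> list[PrimerPair]:
    """Read a primer table (TSV with columns name, forward, reverse and
    optional size/tm/position columns, case-insensitive)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "forward", "reverse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer table {path} lacks columns: {sorted(missing)}")
    pairs = []
    for row in df.itertuples():
        pairs.append(
            PrimerPair(
                name=str(row.name),
                forward=str(row.forward),
                reverse=str(row.reverse),
                expected_size=int(row.size) if "size" in df.columns and pd.notna(row.size) else None,
                tm=float(row.tm) if "tm" in df.columns and pd.notna(row.tm) else None,
            )
        )
    return pairs


def load_bundled_primers() -> dict[str, PrimerPair]:
    """The published O. bidens sex-marker candidate primer panel (50 pairs),
    bundled as package data; keyed by primer name (Mar1..Mar50)."""
    ref = importlib.resources.files("cqscreen").joinpath("data/obidens_primers.tsv")
    with importlib.resources.as_file(ref) as path:
        return {p.name: p for p in read_primers(path)}
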