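"""Synthetic XY genome construction and pooled, pre-aligned read simulation.

The simulator emulates sex-pooled resequencing of a male-heterogametic
(XX/XY) species mapped against a male-derived, Y-inclusive reference
assembly.  Y-specific sequence is modelled as planted insertions: intervals
present in the reference but absent from the X haplotype.  A female (XX)
pool therefore never produces reads that originate inside those intervals,
while a male (XY) pool covers them at roughly half its overall depth —
exactly the coverage signature the chromosome-quotient screen detects.

Reads are emitted as ungapped, coordinate-sorted single-end alignment
records in reference coordinates, so the downstream window counter never
needs an external mapper.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

__all__ = [
    "SexGenomeSpec",
    "SexGenome",
    "ReadSimParams",
    "SimulatedRead",
    "build_genome",
    "simulate_pool",
    "make_marker_fixture",
    "write_reference_fasta",
    "write_truth_bed",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return codes.tobytes().decode("ascii")


@dataclass(frozen=True)
class SexGenomeSpec:
    """Blueprint for a synthetic XY genome.

    Parameters
    ----------
    contigs
        ``(name, length)`` pairs giving reference contig sizes in bp.
    insertions
        ``(contig, start, length)`` triples marking Y-specific intervals in
        0-based reference coordinates.  They must be non-overlapping and lie
        strictly inside their contig.
    base_seed
        Seed for the reference-sequence RNG; construction is fully
        deterministic given the spec.
    gc_fraction
        GC content of the simulated reference (default 0.39, a typical
        cyprinid fish value).
    """

    contigs: tuple[tuple[str, int], ...]
    insertions: tuple[tuple[str, int, int], ...] = ()
    base_seed: int = 0
    gc_fraction: float = 0.39

    def __post_init__(self) -> None:
        object.__setattr__(self, "contigs", tuple((str(n), int(l)) for n, l in self.contigs))
        object.__setattr__(
            self, "insertions", tuple((str(c), int(s), int(l)) for c, s, l in self.insertions)
        )
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction must be in [0, 1], got {self.gc_fraction}")
        lengths = dict(self.contigs)
        if len(lengths) != len(self.contigs):
            raise ValueError("duplicate contig names in spec")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, length in self.insertions:
            if contig not in lengths:
                raise ValueError(f"insertion on unknown contig {contig!r}")
            if length <= 0:
                raise ValueError(f"insertion ({contig}, {start}, {length}): length must be > 0")
            if start <= 0 or start + length >= lengths[contig]:
                raise ValueError(
                    f"insertion ({contig}, {start}, {length}) is not strictly inside "
                    f"contig {contig!r} of length {lengths[contig]}"
                )
            by_contig.setdefault(contig, []).append((start, start + length))
        for contig, ivals in by_contig.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"insertions on {contig!r} overlap: "
                        f"[{s1}, {e1}) and [{s2}, {e2})"
                    )


class _Liftover:
    """Bijective position map between X-haplotype and reference coordinates
    for one contig, outside the deleted (Y-specific) intervals."""

    def __init__(self, edits: Sequence[tuple[int, int]]):
        self.edits = sorted(edits)
        lens = [e - s for s, e in self.edits]
        self.cum = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
        # X-coordinate cut points: position in X space where each deleted
        # reference interval would sit.
        self.xcuts = np.array(
            [s - c for (s, _), c in zip(self.edits, self.cum[:-1])], dtype=np.int64
        )
        self.ref_starts = np.array([s for s, _ in self.edits], dtype=np.int64)
        self.ref_ends = np.array([e for _, e in self.edits], dtype=np.int64)

    @property
    def deleted(self) -> int:
        return int(self.cum[-1])

    def ref_to_x(self, pos: int) -> int:
        i = bisect_right(self.ref_starts.tolist(), pos)
        if i > 0 and pos < self.ref_ends[i - 1]:
            s, e = self.edits[i - 1]
            raise ValueError(f"reference position {pos} lies inside deleted interval [{s}, {e})")
        return int(pos - self.cum[i])

    def x_to_ref(self, pos: int) -> int:
        i = bisect_right(self.xcuts.tolist(), pos)
        return int(pos + self.cum[i])

    def x_to_ref_array(self, pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.xcuts, pos, side="right")
        return pos + self.cum[idx]

    def spans_cut(self, start: np.ndarray, length: int) -> np.ndarray:
        """True where the X-space interval [start, start+length) crosses a
        deletion junction (such a read has no ungapped reference placement)."""
        lo = np.searchsorted(self.xcuts, start, side="right")  # cuts <= start
        hi = np.searchsorted(self.xcuts, start + length, side="left")  # cuts < end
        return hi > lo


@dataclass
class SexGenome:
    """A male-derived (Y-inclusive) reference plus the edit list defining the
    X haplotype, with exact coordinate liftover.

    ``reference`` holds the full assembly including Y-specific insertions;
    ``x_edits`` lists the reference intervals deleted on X; ``truth_regions``
    records the planted male-specific intervals in reference coordinates.
    """

    reference: dict[str, str]
    x_edits: dict[str, list[tuple[int, int]]]
    truth_regions: list[tuple[str, int, int]]
    spec: SexGenomeSpec | None = None
    _lift: dict[str, _Liftover] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for contig in self.reference:
            self._lift[contig] = _Liftover(self.x_edits.get(contig, []))

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.reference.items()}

    def x_length(self, contig: str) -> int:
        return len(self.reference[contig]) - self._lift[contig].deleted

    def x_haplotype(self, contig: str) -> str:
        seq = self.reference[contig]
        parts, prev = [], 0
        for s, e in self._lift[contig].edits:
            parts.append(seq[prev:s])
            prev = e
        parts.append(seq[prev:])
        return "".join(parts)

    def x_slice(self, contig: str, start: int, end: int) -> str:
        """X-haplotype sequence of a reference interval (deleted parts removed)."""
        seq = self.reference[contig]
        parts, prev = [], start
        for s, e in self._lift[contig].edits:
            if e <= start or s >= end:
                continue
            parts.append(seq[prev:max(s, start)])
            prev = min(e, end)
        parts.append(seq[prev:end])
        return "".join(parts)

    def ref_to_x(self, contig: str, pos: int) -> int:
        return self._lift[contig].ref_to_x(pos)

    def x_to_ref(self, contig: str, pos: int) -> int:
        return self._lift[contig].x_to_ref(pos)


def build_genome(spec: SexGenomeSpec) -> SexGenome:
    """Realize a :class:`SexGenomeSpec` into concrete sequence.

    The reference is drawn base-by-base at the requested GC content; the X
    haplotype is the reference with every insertion interval excised, so the
    X length equals the reference length minus the summed insertion lengths.
    Deterministic for a fixed ``base_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.base_seed)
    reference = {
        name: _random_sequence(rng, length, spec.gc_fraction) for name, length in spec.contigs
    }
    x_edits: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in spec.contigs}
    truth: list[tuple[str, int, int]] = []
    for contig, start, length in sorted(spec.insertions):
        x_edits[contig].append((start, start + length))
        truth.append((contig, start, start + length))
    return SexGenome(reference=reference, x_edits=x_edits, truth_regions=truth, spec=spec)


@dataclass(frozen=True)
class ReadSimParams:
    """Per-pool sequencing parameters.

    depth is the mean fold-coverage of the whole pool; read_length is fixed
    (single-end); error_rate is the per-base substitution probability.
    """

    depth: float
    read_length: int = 150
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.read_length <= 0:
            raise ValueError(f"read_length must be > 0, got {self.read_length}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")


@dataclass(frozen=True)
class SimulatedRead:
    contig: str
    start: int  # 0-based leftmost reference position
    sequence: str
    flag: int  # 0 forward, 16 reverse strand
    source: str  # "X" or "Y" (Y = the Y-inclusive reference haplotype)


def _apply_errors(seq_codes: np.ndarray, rng: np.random.Generator, n_err: int) -> np.ndarray:
    pos = rng.choice(len(seq_codes), size=n_err, replace=False)
    out = seq_codes.copy()
    for p in pos:
        # substitute with one of the three other bases
        alt = _BASES[_BASES != out[p]]
        out[p] = alt[rng.integers(0, 3)]
    return out


def simulate_pool(
    genome: SexGenome, sex: str, params: ReadSimParams
) -> list[SimulatedRead]:
    """Simulate one sex pool as coordinate-sorted aligned reads.

    Females draw all reads from the X haplotype (their two X copies are
    identical here); males split depth evenly between one X and one
    Y-inclusive (reference) haplotype.  Read starts are uniform over each
    haplotype; the per-(contig, haplotype) read count is Poisson with mean
    ``depth * haplotype_length / read_length``.  X-derived reads whose
    X-space interval crosses a deletion junction are dropped — they have no
    ungapped placement on the reference — which leaves a small, documented
    coverage dip at insertion junctions.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    params.__post_init__()
    rng = np.random.default_rng([params.seed, 0 if sex == "female" else 1])
    L = params.read_length
    sources: list[tuple[str, float]] = (
        [("X", params.depth)] if sex == "female" else [("X", params.depth / 2.0), ("Y", params.depth / 2.0)]
    )

    reads: list[SimulatedRead] = []
    for contig in genome.reference:
        lift = genome._lift[contig]
        contig_reads: list[tuple[int, str, int, str]] = []
        for source, depth in sources:
            hap = genome.x_haplotype(contig) if source == "X" else genome.reference[contig]
            hap_len = len(hap)
            if hap_len < L or depth == 0:
                continue
            n = int(rng.poisson(depth * hap_len / L))
            if n == 0:
                continue
            starts = rng.integers(0, hap_len - L + 1, size=n)
            starts.sort()
            if source == "X" and len(lift.edits):
                keep = ~lift.spans_cut(starts, L)
                starts = starts[keep]
            ref_starts = lift.x_to_ref_array(starts) if source == "X" else starts
            strands = rng.integers(0, 2, size=len(starts))
            n_err = (
                rng.binomial(L, params.error_rate, size=len(starts))
                if params.error_rate > 0
                else np.zeros(len(starts), dtype=int)
            )
            hap_codes = np.frombuffer(hap.encode("ascii"), dtype=np.uint8)
            for s, rs, strand, ne in zip(starts, ref_starts, strands, n_err):
                codes = hap_codes[s : s + L]
                if ne:
                    codes = _apply_errors(codes, rng, int(ne))
                contig_reads.append(
                    (int(rs), codes.tobytes().decode("ascii"), 16 if strand else 0, source)
                )
        contig_reads.sort(key=lambda r: r[0])
        reads.extend(
            SimulatedRead(contig, rs, seq, flag, source)
            for rs, seq, flag, source in contig_reads
        )
    return reads


def _sam_header(genome: SexGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in genome.contig_lengths.items()
            ],
        }
    )


def write_sam(
    reads: Iterable[SimulatedRead], genome: SexGenome, path: str, sample: str = "pool"
) -> int:
    """Write simulated reads as an uncompressed, coordinate-sorted SAM file."""
    header = _sam_header(genome)
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, read in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = f"{sample}_{i:07d}"
            a.flag = read.flag
            a.reference_id = out.get_tid(read.contig)
            a.reference_start = read.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.sequence)}M"
            a.query_sequence = read.sequence
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.sequence))
            out.write(a)
            n += 1
    return n


def write_reference_fasta(genome: SexGenome, path: str, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_truth_bed(genome: SexGenome, path: str) -> None:
    with open(path, "w") as fh:
        for contig, start, end in genome.truth_regions:
            fh.write(f"{contig}\t{start}\t{end}\tY_specific\n")


def make_marker_fixture(
    forward: str,
    reverse: str,
    x_amplicon_length: int = 509,
    insertion_length: int = 305,
    contig: str = "chr8",
    contig_length: int = 20_000,
    locus_start: int | None = None,
    seed: int = 2024,
    gc_fraction: float = 0.39,
) -> SexGenome:
    """Construct a genome carrying one insertion-junction marker locus.

    The reference contains, at ``locus_start``: the forward primer site, a
    stretch of random filler split by a planted Y-specific insertion of
    ``insertion_length`` bp strictly between the two primer footprints, then
    the reverse-complemented reverse primer site.  On the X haplotype the
    insertion is absent, so the two primer sites delimit an amplicon of
    exactly ``x_amplicon_length`` bp; on the Y-inclusive reference the same
    sites delimit ``x_amplicon_length + insertion_length`` bp.  This is the
    classic two-bands-in-males / one-band-in-females marker geometry.
    """
    from .pcr import reverse_complement

    forward = forward.upper()
    reverse = reverse.upper()
    filler = x_amplicon_length - len(forward) - len(reverse)
    if filler < 2:
        raise ValueError(
            "x_amplicon_length leaves no room for an interior insertion "
            f"(filler would be {filler} bp)"
        )
    if insertion_length <= 0:
        raise ValueError("insertion_length must be > 0")
    rng = np.random.default_rng(seed)
    if locus_start is None:
        locus_start = (contig_length - x_amplicon_length - insertion_length) // 2
    locus_len = x_amplicon_length + insertion_length
    if not 0 < locus_start < contig_length - locus_len:
        raise ValueError("marker locus does not fit strictly inside the contig")

    left = filler // 2
    right = filler - left
    locus = (
        forward
        + _random_sequence(rng, left, gc_fraction)
        + _random_sequence(rng, insertion_length, gc_fraction)
        + _random_sequence(rng, right, gc_fraction)
        + reverse_complement(reverse)
    )
    pre = _random_sequence(rng, locus_start, gc_fraction)
    post = _random_sequence(rng, contig_length - locus_start - locus_len, gc_fraction)
    reference = pre + locus + post

    ins_start = locus_start + len(forward) + left
    ins_end = ins_start + insertion_length
    return SexGenome(
        reference={contig: reference},
        x_edits={contig: [(ins_start, ins_end)]},
        truth_regions=[(contig, ins_start, ins_end)],
    )
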