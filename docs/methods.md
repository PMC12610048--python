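# Methods

## Model

`cqscreen` targets male-heterogametic (XX/XY) systems in which the
reference assembly derives from a male and therefore contains Y-specific
sequence. Y-specific loci are modelled as **insertions**: intervals present
on the reference (Y) haplotype and absent from X. Mapping pooled female
(XX) and male (XY) resequencing reads to such a reference produces a
characteristic coverage signature — females drop to zero over the
insertions while males retain roughly half their genome-wide depth (only
their single Y copy covers the locus).

The screen quantifies this per window as the chromosome quotient
CQ = Hf/Hm, the ratio of female-pool to male-pool read counts. Windows
with CQ < 0.2 and Hm > 30 are retained; both are strict inequalities and
on raw integer counts the comparison is done in exact rational arithmetic
(`Fraction(Hf, Hm) < Fraction("0.2")`), so boundary cases (CQ exactly 0.2,
Hm exactly 30) are rejected reproducibly, bit for bit. The Hm floor
suppresses windows whose quotient is dominated by sampling noise or that
are unmappable in both pools.

Retained windows are unioned into candidate regions when their separation
is at most `merge_gap` (default 0: only overlapping or bookended windows
coalesce). Regions carry aggregates (window count, minimum CQ, summed Hm)
and are written as 0-based half-open BED plus a 1-based human-readable
report. The marker stage predicts PCR products per haplotype: a product
exists wherever the forward primer matches the plus strand and the reverse
primer's reverse complement occurs downstream, length including both
primer footprints. Per genotype the product lengths of the constituent
haplotypes (XX: X+X, XY: X+Y) are pooled and collapsed at the gel
resolution into a band pattern, and a marker is called sex-informative
(`male_extra_band`) when the male pattern contains every female band plus
at least one extra — the two-bands-in-males / one-band-in-females readout
of an insertion-junction marker, where the Y product exceeds the X product
by exactly the insertion length.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window` | 500 | bp | published screen parameter |
| `step` | 1000 | bp | published screen parameter (see note below) |
| `cq_max` | 0.2 | – | published retention threshold, strict `<` |
| `hm_min` | 30 | reads | published retention threshold, strict `>` |
| `normalize_depth` | off | – | the published screen applies no correction despite unequal pool depths; the switch rescales Hf by (ΣHm/ΣHf) because unequal depths bias CQ by the depth ratio |
| `merge_gap` | 0 | bp | literal merge-overlapping-windows rule |
| `min_mapq` | 0 | – | no mapping-quality cut is stated for the original analysis |
| counting mode | `start` | – | see below |
| flank | 1000 | bp | published primer-design flank |
| PCR `max_len` | 5000 | bp | what a standard 2-min extension step amplifies |
| gel `resolution` | 20 | bp | ~1% agarose resolving power near 500 bp |
| `max_mismatch` | 0 | bases | exact primer matching; optional tolerance keeps the 3 terminal 3′ bases exact because extension is 3′-anchored |

**The step/window tension.** The literal published parameters (window
500 bp, step 1000 bp) tile only half the genome and can never produce
overlapping windows, yet the original procedure merges "overlapping"
windows — the two statements are mutually inconsistent, most plausibly a
transposed window/step. We reproduce the literal parameters as defaults
(with a `WindowGapWarning`), support the transposed reading, and document
that coalescing regions under the literal tiling requires
`merge_gap >= 500`. The end-to-end recovery fixture uses a denser step
(100 bp) so that the planted-region recovery property is sharp.

**Counting mode.** "Reads per window" is ambiguous; by default a read is
assigned to every window containing its leftmost aligned position, which
makes counts conserved under a non-overlapping tiling and gives a clean
brute-force oracle. `overlap` mode (any intersection of the aligned span)
is provided for sensitivity analysis.

**Coordinate conventions.** Internally everything is 0-based half-open.
Published coordinate spans mix conventions (a browser-style region span
that is half-open, a primer-table product size that is inclusive), so
`region_length` implements both explicitly rather than guessing.

## The synthetic-data generator

`simulate` emulates the structure of sex-pooled resequencing against a
male-derived reference: a reference drawn at ~39% GC (a typical cyprinid
value, matching the pools it stands in for), planted Y-specific insertions
with exact interval bookkeeping, and single-end 150-bp reads at ~24× male
and ~31× female pool depth in the paper-scale configuration (test fixtures
use smaller genomes and depths of the same order). Females sample reads
from the X haplotype only; males split depth evenly between one X and one
Y-inclusive haplotype. Per (contig, haplotype) the read count is Poisson
with mean depth·length/read-length, starts are uniform, substitution
errors are applied at 0.2%/base, and records are emitted pre-aligned
(ungapped, MAPQ 60, coordinate-sorted SAM) with an explicit integer seed;
identical inputs give byte-identical output files.

X-derived reads whose X-space interval crosses a deletion junction are
**dropped**, not soft-clipped: they have no ungapped reference placement.
This keeps the counting contract simple at the cost of a small female (and
male X-half) coverage dip within one read length of each junction — which
mimics, qualitatively, what a real mapper does with junction-spanning
reads.

What the simulator deliberately does not model: X/Y divergence outside the
planted insertions (SNVs, small indels), paired-end structure, quality
scores beyond a constant placeholder, PCR duplicates (the duplicate filter
flag exists but duplicates are never simulated), mapping ambiguity or
repeats. Passing tests on this generator therefore demonstrate the
correctness of the counting, screening, merging and marker logic under an
idealized mapping process — not robustness to repetitive genomes,
cross-mapping between gametologs, or library artifacts in real data.

## Numerical and design choices

- **Thresholds** are compared exactly (rationals) on raw counts; with
  depth normalization enabled the scaled Hf is a float and comparisons are
  in floating point.
- **Undefined CQ** (Hm = 0) is stored as NaN and never retained.
- **Band representative**: after collapsing lengths at the gel resolution
  the smallest member represents each band (any single choice in the
  cluster is equally defensible; the smallest makes the collapse greedy
  and order-free).
- **Region merging** is greedy left-to-right over sorted windows, which
  for interval union is exact, idempotent, and leaves any two output
  regions separated by more than `merge_gap`.
- **Marker fixture geometry**: the insertion is placed strictly between
  the primer footprints, splitting the inter-primer filler, so the X
  amplicon length is an input and the Y length emerges as X + insertion.
- **Seeds**: every stochastic component takes an explicit integer seed; the
  two pools of one run derive independent streams from one seed
  (`default_rng([seed, pool_index])`). No global RNG state is used.
- **Truth evaluation**: sensitivity = fraction of planted intervals
  overlapped by ≥1 reported region; precision = fraction of reported
  regions overlapping ≥1 planted interval (any-overlap, not reciprocal).
  Reported regions are expected to be slightly smaller than the planted
  interval because junction-adjacent windows mix covered and uncovered
  sequence.

## Problem sizes

The end-to-end recovery check runs on a 500-kb single-contig genome with
one 3-kb insertion at 20×/26× pool depths (~150 k reads), which the screen
resolves with sensitivity and precision 1.0; the null configuration (no
insertion) yields zero regions. Unit and property tests use genomes of
30–200 kb. These sizes exercise every code path at full read density; the
algorithms are linear in reads and windows and have been run unchanged at
megabase scale.

## Known limitations

- The screen detects presence/absence (insertion-type) Y-specific
  sequence; diverged-but-present gametologs reduce female mapping only
  partially and may not pass CQ < 0.2.
- No statistical model of window counts is fitted; thresholds are the
  published hard cutoffs, so no FDR or confidence statement attaches to a
  reported region.
- In-silico PCR is purely sequence-based (no melting temperature, primer
  dimers, or efficiency); a primer pair that passes here can still fail on
  the bench.
- With the bundled real primer panel, validation against the real genome
  is impossible here (the reference assembly and pooled reads are not
  desk-scale); the panel is exercised against constructed templates whose
  geometry follows the published marker description. Whether the real
  reference locus carries the X-like or Y-like allele at that marker is
  not resolvable from the published description alone; the fixture models
  the Y-inclusive reading, which is the only one under which a low-CQ
  screen on the reference finds the locus.
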