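"""In-silico PCR: site search, band patterns, marker classification."""

import numpy as np
import pytest

from cqscreen.pcr import (
    BandPattern,
    MarkerCall,
    PrimerPair,
    classify_marker,
    collapse_lengths,
    find_amplicons,
    genotype_bands,
    load_bundled_primers,
    read_primers,
    reverse_complement,
)
from cqscreen.simulate import make_marker_fixture

PAIR = PrimerPair("toy", "ACGTACGTACGTACGTAC", "TGCATGCATGCATGCA")


def build_template(rng, pair, inner, pre=40, post=40):
    bases = np.array(list("ACGT"))
    flank = lambda n: "".join(rng.choice(bases, size=n))
    return flank(pre) + pair.forward + inner + reverse_complement(pair.reverse) + flank(post)


class TestFindAmplicons:
    def test_single_product_length_includes_primer_footprints(self):
        rng = np.random.default_rng(0)
        template = build_template(rng, PAIR, inner="A" * 100)
        (amp,) = find_amplicons(template, PAIR)
        assert amp.length == len(PAIR.forward) + 100 + len(PAIR.reverse)
        assert template[amp.start : amp.start + len(PAIR.forward)] == PAIR.forward

    def test_template_lacking_a_site_yields_nothing(self):
        assert find_amplicons("ACGT" * 100, PAIR) == []

    def test_max_len_ceiling(self):
        rng = np.random.default_rng(1)
        template = build_template(rng, PAIR, inner="A" * 300)
        assert find_amplicons(template, PAIR, max_len=200) == []

    def test_reverse_site_upstream_of_forward_is_ignored(self):
        rng = np.random.default_rng(2)
        template = reverse_complement(PAIR.reverse) + "A" * 50 + PAIR.forward + "A" * 50
        assert find_amplicons(template, PAIR) == []

    def test_exact_matching_equals_substring_scan_oracle(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(30):
            template = "".join(rng.choice(bases, size=400))
            # plant 0-2 copies of each site
            for site in (PAIR.forward, reverse_complement(PAIR.reverse)):
                for _ in range(int(rng.integers(0, 3))):
                    p = int(rng.integers(0, 380))
                    template = template[:p] + site + template[p + len(site):]
            got = {(a.start, a.end) for a in find_amplicons(template, PAIR, max_len=10_000)}
            # oracle: brute-force substring positions, all pairings
            fwd = [i for i in range(len(template)) if template.startswith(PAIR.forward, i)]
            rc = reverse_complement(PAIR.reverse)
            rev = [i for i in range(len(template)) if template.startswith(rc, i)]
            want = {
                (f, r + len(rc)) for f in fwd for r in rev if r >= f and r + len(rc) - f > 0
            }
            assert got == want

    def test_mismatch_tolerance_respects_three_prime_anchor(self):
        rng = np.random.default_rng(4)
        template = build_template(rng, PAIR, inner="A" * 60)
        # one mismatch in the forward primer interior: found only with tolerance
        f = PAIR.forward
        mutated = template.replace(f, f[:5] + ("A" if f[5] != "A" else "C") + f[6:])
        assert find_amplicons(mutated, PAIR, max_mismatch=0) == []
        assert len(find_amplicons(mutated, PAIR, max_mismatch=1)) == 1
        # the same substitution in the 3 terminal 3' bases is never tolerated
        anchored = template.replace(f, f[:-1] + ("A" if f[-1] != "A" else "C"))
        assert find_amplicons(anchored, PAIR, max_mismatch=3) == []

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(5)
        template = build_template(rng, PAIR, inner="GATTACA" * 12)
        forward_lengths = sorted(a.length for a in find_amplicons(template, PAIR))
        swapped = PrimerPair("swap", PAIR.reverse, PAIR.forward)
        flipped_lengths = sorted(
            a.length for a in find_amplicons(reverse_complement(template), swapped)
        )
        assert forward_lengths == flipped_lengths

    def test_non_acgt_primer_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            PrimerPair("bad", "ACGTNACGTACGTACGT", "ACGTACGTACGTACGT")
        with pytest.raises(ValueError, match="minimum"):
            PrimerPair("short", "ACGTACG", "ACGTACGTACGTACGT")
        with pytest.raises(ValueError, match="empty"):
            find_amplicons("", PAIR)


class TestBands:
    def test_collapse_below_resolution(self):
        assert collapse_lengths([509, 514], resolution=20) == (509,)
        assert collapse_lengths([509, 814], resolution=20) == (509, 814)
        assert collapse_lengths([], resolution=20) == ()

    def test_band_pattern_distinctness_invariant(self):
        bands = collapse_lengths([500, 515, 530, 800], resolution=20)
        assert all(b - a > 20 for a, b in zip(bands, bands[1:]))

    def test_genotype_bands_union_across_haplotypes(self, mar28, marker_genome):
        x = marker_genome.x_haplotype("chr8")
        y = marker_genome.reference["chr8"]
        assert genotype_bands([x, y], mar28).bands == (509, 814)
        assert genotype_bands([x, x], mar28).bands == (509,)

    def test_haplotype_count_validated(self, mar28):
        with pytest.raises(ValueError, match="1-2 haplotypes"):
            genotype_bands([], mar28)


class TestClassify:
    def pattern(self, *bands, resolution=20):
        return BandPattern(tuple(bands), resolution)

    def test_male_extra_band(self):
        call = classify_marker(self.pattern(509, 814), self.pattern(509))
        assert call is MarkerCall.MALE_EXTRA_BAND

    def test_uninformative_when_patterns_match(self):
        assert classify_marker(self.pattern(509), self.pattern(509)) is MarkerCall.UNINFORMATIVE

    def test_no_amplification(self):
        assert classify_marker(self.pattern(), self.pattern()) is MarkerCall.NO_AMPLIFICATION

    def test_female_only_band_is_ambiguous(self):
        assert classify_marker(self.pattern(509), self.pattern(509, 900)) is MarkerCall.AMBIGUOUS
        assert classify_marker(self.pattern(), self.pattern(400)) is MarkerCall.AMBIGUOUS

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            classify_marker(self.pattern(509), BandPattern((509,), 40))


class TestJunctionAdditivity:
    def test_y_amplicon_is_x_plus_insertion(self, mar28):
        rng = np.random.default_rng(7)
        for i in rng.integers(10, 2000, size=20):
            genome = make_marker_fixture(
                mar28.forward, mar28.reverse,
                x_amplicon_length=509, insertion_length=int(i),
                contig_length=6000, seed=int(rng.integers(0, 2**31)),
            )
            (x_amp,) = find_amplicons(genome.x_haplotype("chr8"), mar28)
            (y_amp,) = find_amplicons(genome.reference["chr8"], mar28)
            assert y_amp.length == x_amp.length + int(i)
            assert x_amp.length == 509


def test_bundled_primer_panel(tmp_path):
    panel = load_bundled_primers()
    assert len(panel) == 50
    mar28 = panel["Mar28"]
    assert mar28.expected_size == 509
    assert set("".join(p.forward + p.reverse for p in panel.values())) <= set("ACGT")
    # read_primers round-trips a minimal user table
    path = tmp_path / "primers.tsv"
    path.write_text("name\tforward\treverse\nP1\tACGTACGTACGTACGTA\tTGCATGCATGCATGCAT\n")
    (pair,) = read_primers(path)
    assert pair.name == "P1" and pair.expected_size is None
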