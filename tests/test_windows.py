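"""Window tiling and filtered read counting against a brute-force oracle."""

import numpy as np
import pytest

from cqscreen.windows import (
    CountFilters,
    Window,
    WindowGapWarning,
    count_reads,
    counts_to_tsv,
    make_windows,
    read_counts_tsv,
)

from conftest import brute_force_counts, make_header, make_read


class TestMakeWindows:
    def test_published_parameters_leave_gaps(self):
        with pytest.warns(WindowGapWarning):
            ws = make_windows({"c": 3000}, window=500, step=1000)
        assert [(w.start, w.end) for w in ws] == [(0, 500), (1000, 1500), (2000, 2500)]

    def test_non_overlapping_tiling(self):
        ws = make_windows({"c": 1000}, window=500, step=500)
        assert [(w.start, w.end) for w in ws] == [(0, 500), (500, 1000)]

    def test_final_window_truncated_at_contig_end(self):
        with pytest.warns(WindowGapWarning):
            ws = make_windows({"c": 300}, window=500, step=1000)
        assert [(w.start, w.end) for w in ws] == [(0, 300)]

    def test_multiple_contigs_in_order(self):
        ws = make_windows([("a", 600), ("b", 400)], window=300, step=300)
        assert [(w.contig, w.start, w.end) for w in ws] == [
            ("a", 0, 300),
            ("a", 300, 600),
            ("b", 0, 300),
            ("b", 300, 400),
        ]

    @pytest.mark.parametrize("window,step", [(0, 100), (100, 0), (-5, 100)])
    def test_invalid_parameters(self, window, step):
        with pytest.raises(ValueError):
            make_windows({"c": 1000}, window=window, step=step)


class TestCountReads:
    header = make_header([("c", 10_000), ("d", 10_000)])

    def test_empty_stream_gives_all_zero(self):
        ws = make_windows({"c": 2000}, 500, 500)
        assert [wc.count for wc in count_reads([], ws)] == [0, 0, 0, 0]

    def test_start_mode_boundary(self):
        # leftmost positions 10 and 499 fall in [0, 500); 500 does not
        reads = [make_read(self.header, "c", p, name=f"r{p}") for p in (10, 499, 500)]
        ws = [Window("c", 0, 500)]
        assert count_reads(reads, ws)[0].count == 2

    def test_duplicate_flag_excluded(self):
        reads = [
            make_read(self.header, "c", 10, name="keep"),
            make_read(self.header, "c", 20, flag=0x400, name="dup"),
        ]
        assert count_reads(reads, [Window("c", 0, 500)])[0].count == 1
        loose = CountFilters(exclude=frozenset({"unmapped"}))
        assert count_reads(reads, [Window("c", 0, 500)], loose)[0].count == 2

    def test_mapq_filter(self):
        reads = [make_read(self.header, "c", 5, mapq=q, name=f"q{q}") for q in (0, 10, 60)]
        filters = CountFilters(min_mapq=20)
        assert count_reads(reads, [Window("c", 0, 100)], filters)[0].count == 1

    def test_overlap_mode_counts_spanning_reads(self):
        # a 100-bp read starting at 450 overlaps both [0,500) and [500,1000)
        reads = [make_read(self.header, "c", 450, length=100)]
        ws = make_windows({"c": 1000}, 500, 500)
        start_counts = [wc.count for wc in count_reads(reads, ws)]
        overlap_counts = [
            wc.count
            for wc in count_reads(reads, ws, CountFilters(assignment_mode="overlap"))
        ]
        assert start_counts == [1, 0]
        assert overlap_counts == [1, 1]

    def test_unsorted_input_names_offending_record(self):
        reads = [
            make_read(self.header, "c", 100, name="first"),
            make_read(self.header, "c", 50, name="out_of_order"),
        ]
        with pytest.raises(ValueError, match="out_of_order"):
            count_reads(reads, [Window("c", 0, 500)])

    def test_unknown_contig_rejected(self):
        reads = [make_read(self.header, "d", 10, name="stray")]
        with pytest.raises(ValueError, match="stray"):
            count_reads(reads, [Window("c", 0, 500)])

    def test_conservation_under_non_overlapping_tiling(self):
        rng = np.random.default_rng(0)
        ws = make_windows({"c": 5000}, 500, 500)
        positions = np.sort(rng.integers(0, 4900, size=300))
        reads = [make_read(self.header, "c", int(p), name=f"r{i}") for i, p in enumerate(positions)]
        counts = count_reads(reads, ws)
        assert sum(wc.count for wc in counts) == len(reads)

    def test_adding_a_read_never_decreases_counts(self):
        rng = np.random.default_rng(1)
        positions = np.sort(rng.integers(0, 900, size=40))
        reads = [make_read(self.header, "c", int(p), name=f"r{i}") for i, p in enumerate(positions)]
        ws = make_windows({"c": 1000}, 400, 200)
        base = [wc.count for wc in count_reads(reads, ws)]
        more = [wc.count for wc in count_reads(reads + [make_read(self.header, "c", 950)], ws)]
        assert all(b <= m for b, m in zip(base, more))

    @pytest.mark.parametrize("mode", ["start", "overlap"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(25):
            clen = int(rng.integers(500, 5000))
            window = int(rng.integers(50, 800))
            step = int(rng.integers(50, 800))
            n = int(rng.integers(0, 300))
            positions = np.sort(rng.integers(0, max(1, clen - 100), size=n))
            flags = rng.choice([0, 16, 0x400, 0x100], size=n, p=[0.6, 0.2, 0.1, 0.1])
            mapqs = rng.integers(0, 61, size=n)
            reads = [
                make_read(self.header, "c", int(p), length=100, mapq=int(q), flag=int(f), name=f"r{i}")
                for i, (p, q, f) in enumerate(zip(positions, mapqs, flags))
            ]
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", WindowGapWarning)
                ws = make_windows({"c": clen}, window, step)
            filters = CountFilters(min_mapq=int(rng.integers(0, 30)), assignment_mode=mode)
            got = [wc.count for wc in count_reads(reads, ws, filters)]
            assert got == brute_force_counts(reads, ws, filters)


def test_counts_tsv_round_trip(tmp_path):
    ws = make_windows({"c": 1000}, 500, 500)
    reads = [make_read(make_header([("c", 1000)]), "c", 10)]
    counts = count_reads(reads, ws)
    path = tmp_path / "counts.tsv"
    counts_to_tsv(counts, path)
    assert read_counts_tsv(path) == counts
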